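"""Visualisation of consensus quality.

Four displays: offset aligned-signal panels, warp-path plots (standard /
normalized / difference-from-identity), warp-line connectors between
unwarped signals, and amplitude-difference traces with outlier flags.
All functions are pure renderings of their inputs and write a figure file.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .squiggle_io import GoldModel
from .warp import WarpPath, dtw, dfi, normalize_path

__all__ = [
    "plot_alignment_panels",
    "plot_warp_paths",
    "plot_warp_lines",
    "plot_amplitude_diff",
]

_COLORS = ["black", "green", "red", "purple"]


def _levels(x) -> np.ndarray:
    return x.levels if hasattr(x, "levels") else np.asarray(x, float)


def _label(x, i: int) -> str:
    return getattr(x, "algorithm", None) or f"consensus {i}"


def plot_alignment_panels(gold: GoldModel, consensuses, out: str | Path, window: int = 400):
    """Two-panel display: unwarped signals vertically offset above; a short
    window of the warped, aligned signals below.  The title carries the
    consensus/gold length ratios."""
    if not consensuses:
        raise ValueError("need at least one consensus")
    if window < 1:
        raise ValueError("window must be >= 1")
    fig, (ax_top, ax_bot) = plt.subplots(2, 1, figsize=(10, 7))
    g = gold.levels
    offset = 1.5 * (g.max() - g.min())
    ax_top.plot(g, color="tab:blue", lw=0.6, label="gold")
    ratios = []
    for i, c in enumerate(consensuses):
        lv = _levels(c)
        ax_top.plot(lv + (i + 1) * offset, color=_COLORS[i % 4], lw=0.6, label=_label(c, i))
        ratios.append(lv.size / gold.gold_length)
        path = dtw(g, lv).path
        w = slice(0, min(window, len(path)))
        ax_bot.plot(g[path.a_indices[w]] + 0, color="tab:blue", lw=0.6)
        ax_bot.plot(lv[path.b_indices[w]] + (i + 1) * offset, color=_COLORS[i % 4], lw=0.6)
    ax_top.set_title(
        "length ratio consensus/gold: " + ", ".join(f"{r:.2f}" for r in ratios)
    )
    ax_top.set_ylabel("level (pA, offset)")
    ax_bot.set_xlabel("warp step (windowed)")
    ax_bot.set_ylabel("aligned level (pA, offset)")
    ax_top.legend(fontsize=8)
    fig.savefig(out)
    plt.close(fig)
    return Path(out)


def plot_warp_paths(
    paths: list[tuple[WarpPath, int, int]],
    mode: str,
    out: str | Path,
    labels: list[str] | None = None,
):
    """Render warp paths; each entry is (path, len_a, len_b) with A = gold.

    ``standard`` plots raw indices, ``normalized`` plots fractional
    coordinates with the identity line, ``dfi`` plots the
    difference-from-identity series.
    """
    fig, ax = plt.subplots(figsize=(7, 5))
    for i, (path, la, lb) in enumerate(paths):
        label = labels[i] if labels else f"path {i}"
        color = _COLORS[i % 4]
        if mode == "standard":
            ax.plot(path.a_indices, path.b_indices, color=color, lw=0.8, label=label)
        elif mode == "normalized":
            norm = normalize_path(path, la, lb)
            ax.plot(norm[:, 0], norm[:, 1], color=color, lw=0.8, label=label)
        elif mode == "dfi":
            series = dfi(path, la, lb)
            ax.plot(np.linspace(0, 1, series.size), series, color=color, lw=0.8, label=label)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if mode == "normalized":
        ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8, label="identity")
    if mode == "dfi":
        ax.axhline(0.0, ls=":", color="grey", lw=0.8)
        ax.set_ylabel("difference from identity")
        ax.set_xlabel("normalized gold warp position")
    else:
        ax.set_xlabel("gold index" if mode == "standard" else "normalized gold position")
        ax.set_ylabel("consensus index" if mode == "standard" else "normalized consensus position")
    ax.legend(fontsize=8)
    fig.savefig(out)
    plt.close(fig)
    return Path(out)


def plot_warp_lines(signals, out: str | Path, window: int = 400, every: int = 10, labels=None):
    """Stack 2-4 unwarped signals and join equivalent warp positions of
    adjacent pairs with dashed connectors; vertical connectors mean the
    pair is locally undistorted, slanted ones mark stretching."""
    if not 2 <= len(signals) <= 4:
        raise ValueError("need between 2 and 4 signals")
    arrays = [_levels(s) for s in signals]
    fig, ax = plt.subplots(figsize=(10, 6))
    offset = 1.5 * max(a.max() - a.min() for a in arrays)
    for i, a in enumerate(arrays):
        lab = labels[i] if labels else f"signal {i}"
        ax.plot(a[:window] + i * offset, color=_COLORS[i % 4], lw=0.6, label=lab)
    for i in range(len(arrays) - 1):
        path = dtw(arrays[i], arrays[i + 1]).path
        for t in range(0, len(path), every):
            ia, ib = path.steps[t]
            if ia >= window or ib >= window:
                break
            ax.plot(
                [ia, ib],
                [arrays[i][ia] + i * offset, arrays[i + 1][ib] + (i + 1) * offset],
                ls="--", color="grey", lw=0.5,
            )
    ax.set_xlabel("event index (unwarped)")
    ax.set_ylabel("level (pA, offset)")
    ax.legend(fontsize=8)
    fig.savefig(out)
    plt.close(fig)
    return Path(out)


def plot_amplitude_diff(diffs_and_flags, out: str | Path, labels=None):
    """One trace per consensus of gold-minus-consensus differences along the
    warp path; flagged steps (higher-than-average disagreement) are marked
    as spikes."""
    fig, ax = plt.subplots(figsize=(10, 5))
    for i, (diffs, flags) in enumerate(diffs_and_flags):
        lab = labels[i] if labels else f"consensus {i}"
        x = np.arange(diffs.size)
        ax.plot(x, diffs, color=_COLORS[i % 4], lw=0.5, label=lab)
        if flags.any():
            ax.vlines(x[flags], 0, diffs[flags], color="tab:blue", lw=1.0)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("warp step")
    ax.set_ylabel("gold - consensus (pA)")
    ax.legend(fontsize=8)
    fig.savefig(out)
    plt.close(fig)
    return Path(out)
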