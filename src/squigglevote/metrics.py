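"""Quantitative comparison of consensus, ensemble and gold standard.

Core quantities (smaller is better for every distance):

* mean DTW distance from a signal to an ensemble and its sample standard
  deviation,
* the gold-to-consensus DTW distance,
* normalised twins of each metric, raw / gold_length, which make studies
  with different gold standards directly comparable,
* the consensus/gold length ratio, and
* signed amplitude differences between gold and consensus along their warp
  path, with outlier flags marking positions of higher-than-average
  disagreement (candidate systematic deviations, e.g. chemical
  modification sites).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .squiggle_io import Ensemble, GoldModel
from .warp import dtw, dtw_distance

__all__ = [
    "MetricsReport",
    "dist_to_ensemble",
    "normalize",
    "evaluate",
    "amplitude_differences",
]


@dataclass
class MetricsReport:
    """All distances are accumulated |.| DTW costs in pA; smaller is better.
    ``n*`` fields are the raw metric divided by the gold length."""

    dist_consensus_to_ensemble_mean: float
    dist_consensus_to_ensemble_sd: float
    dist_gold_to_ensemble_mean: float
    dist_gold_to_ensemble_sd: float
    dist_gold_to_consensus: float
    ndist_consensus_to_ensemble_mean: float
    ndist_consensus_to_ensemble_sd: float
    ndist_gold_to_ensemble_mean: float
    ndist_gold_to_ensemble_sd: float
    ndist_gold_to_consensus: float
    consensus_length: int
    gold_length: int
    length_ratio: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_row(self) -> dict:
        return asdict(self)


def dist_to_ensemble(signal, ensemble: Ensemble) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of the DTW distances from
    ``signal`` to each ensemble read; sd is NaN for a singleton."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    signal = signal.levels if hasattr(signal, "levels") else np.asarray(signal, float)
    dists = np.array([dtw_distance(signal, s.levels) for s in ensemble])
    sd = float(dists.std(ddof=1)) if dists.size > 1 else float("nan")
    return float(dists.mean()), sd


def normalize(metric: float, gold_length: int) -> float:
    """nMetric = metric / gold_length."""
    if gold_length <= 0:
        raise ValueError("gold_length must be positive")
    return metric / gold_length


def evaluate(consensus, ensemble: Ensemble, gold: GoldModel) -> MetricsReport:
    """Populate the full report for one consensus against its ensemble and
    gold standard."""
    cons = consensus.levels if hasattr(consensus, "levels") else np.asarray(consensus, float)
    c_mean, c_sd = dist_to_ensemble(cons, ensemble)
    g_mean, g_sd = dist_to_ensemble(gold.levels, ensemble)
    g2c = dtw_distance(gold.levels, cons)
    L = gold.gold_length
    return MetricsReport(
        dist_consensus_to_ensemble_mean=c_mean,
        dist_consensus_to_ensemble_sd=c_sd,
        dist_gold_to_ensemble_mean=g_mean,
        dist_gold_to_ensemble_sd=g_sd,
        dist_gold_to_consensus=g2c,
        ndist_consensus_to_ensemble_mean=normalize(c_mean, L),
        ndist_consensus_to_ensemble_sd=normalize(c_sd, L),
        ndist_gold_to_ensemble_mean=normalize(g_mean, L),
        ndist_gold_to_ensemble_sd=normalize(g_sd, L),
        ndist_gold_to_consensus=normalize(g2c, L),
        consensus_length=int(cons.size),
        gold_length=int(L),
        length_ratio=cons.size / L,
    )


def amplitude_differences(gold: GoldModel, consensus) -> tuple[np.ndarray, np.ndarray]:
    """Signed gold-minus-consensus level differences along the optimal warp
    path, plus flags for steps whose |difference| exceeds
    mean(|diff|) + 2 sd(|diff|) — locations of higher-than-average
    disagreement."""
    cons = consensus.levels if hasattr(consensus, "levels") else np.asarray(consensus, float)
    path = dtw(gold.levels, cons).path
    diffs = gold.levels[path.a_indices] - cons[path.b_indices]
    mags = np.abs(diffs)
    cut = mags.mean() + 2.0 * (mags.std(ddof=1) if mags.size > 1 else 0.0)
    flags = mags > cut
    return diffs, flags
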