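"""Ensemble cleaning cascade.

Before any consensus averaging, grossly distorted reads are discarded and
the variable-length enzyme-adapter leader is stripped from each squiggle.
The cascade runs, in order:

1. gross-length rejection (length < 20% of the ensemble mean),
2. leader detection and removal,
3. gross-length rejection again on the stripped reads,
4. a global 3-sigma filter on per-read mean level, level sigma and length,
5. a sectional 2-sigma filter on within-read intensity spread, aimed at
   chimeric reads whose internal statistics are inconsistent.

Ensemble statistics are computed once per stage on that stage's input, so
each filter is independent of removal order.  Sample (n-1) standard
deviations are used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .squiggle_io import Ensemble, GoldModel, Squiggle

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "StageRecord",
    "filter_short",
    "detect_leader",
    "strip_leaders",
    "filter_global",
    "filter_sectional",
    "snr_ratio",
    "snr_length",
    "distortion_level",
    "clean_pipeline",
]


class EmptyEnsembleError(ValueError):
    """A cleaning stage removed every read."""


@dataclass(frozen=True)
class CleaningConfig:
    short_fraction: float = 0.2
    leader_k_sigma: float = 3.0
    leader_window: int = 10
    global_k_sigma: float = 3.0
    n_sections: int = 10
    sectional_k_sigma: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.short_fraction < 1.0:
            raise ValueError("short_fraction must lie in (0, 1)")
        if min(self.leader_k_sigma, self.leader_window, self.global_k_sigma,
               self.n_sections, self.sectional_k_sigma) <= 0:
            raise ValueError("all cleaning thresholds must be positive")


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_out: int
    removed_ids: list[str]


@dataclass
class CleaningReport:
    stages: list[StageRecord] = field(default_factory=list)
    length_mean_before: float = float("nan")
    length_sd_before: float = float("nan")
    length_mean_after: float = float("nan")
    length_sd_after: float = float("nan")
    snr_length_before: float = float("nan")
    snr_length_after: float = float("nan")
    distortion_level: float | None = None

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "n_in": s.n_in, "n_out": s.n_out, "removed_ids": s.removed_ids}
                for s in self.stages
            ],
            "length_mean_before": self.length_mean_before,
            "length_sd_before": self.length_sd_before,
            "length_mean_after": self.length_mean_after,
            "length_sd_after": self.length_sd_after,
            "snr_length_before": self.snr_length_before,
            "snr_length_after": self.snr_length_after,
            "distortion_level": self.distortion_level,
        }

    @property
    def removed_ids(self) -> list[str]:
        return [rid for s in self.stages for rid in s.removed_ids]


def filter_short(ensemble: Ensemble, fraction: float = 0.2) -> Ensemble:
    """Drop reads shorter than ``fraction`` of the mean input length."""
    if len(ensemble) < 2:
        raise ValueError("need at least 2 reads")
    lengths = ensemble.lengths()
    threshold = fraction * lengths.mean()
    keep = [s for s in ensemble if len(s) >= threshold]
    if not keep:
        raise EmptyEnsembleError("short-read filter removed every read")
    return Ensemble(keep, label=ensemble.label)


def detect_leader(squiggle: Squiggle, cfg: CleaningConfig = CleaningConfig()) -> int:
    """Locate the end of the leader, scanning fixed windows from the start.

    The trailing quarter of the read supplies the reference statistics; a
    window is leader-like iff its mean deviates from the tail mean by more
    than ``leader_k_sigma`` tail sigmas, or its own sigma exceeds
    ``leader_k_sigma`` times the tail sigma.  The boundary is the end of the
    initial contiguous run of leader-like windows, capped at half the read
    (a read cannot be mostly leader).  Returns 0 when the first window
    already conforms.
    """
    w = cfg.leader_window
    x = squiggle.levels
    n = x.size
    if n < 4 * w:
        warnings.warn(f"read {squiggle.read_id!r} too short for leader detection", stacklevel=2)
        return 0
    tail = x[-(n // 4):]
    tail_mean = tail.mean()
    tail_sd = tail.std(ddof=1)
    boundary = 0
    for start in range(0, n - w + 1, w):
        win = x[start : start + w]
        mean_dev = abs(win.mean() - tail_mean) > cfg.leader_k_sigma * tail_sd
        sd_dev = win.std(ddof=1) > cfg.leader_k_sigma * tail_sd
        if mean_dev or sd_dev:
            boundary = start + w
        else:
            break
    return min(boundary, n // 2)


def strip_leaders(ensemble: Ensemble, cfg: CleaningConfig = CleaningConfig()) -> Ensemble:
    """Truncate each read at its detected leader boundary; drop emptied reads."""
    out = []
    for s in ensemble:
        b = detect_leader(s, cfg)
        if b >= len(s):
            continue
        out.append(Squiggle(s.read_id, s.levels[b:], truth=s.truth))
    if not out:
        raise EmptyEnsembleError("leader stripping removed every read")
    return Ensemble(out, label=ensemble.label)


def filter_global(ensemble: Ensemble, k_sigma: float = 3.0) -> Ensemble:
    """Reject reads whose mean level, level sigma or length is an ensemble
    outlier beyond ``k_sigma`` ensemble sigmas.  A statistic with zero
    ensemble spread is skipped."""
    if len(ensemble) < 3:
        raise ValueError("need at least 3 reads for stable ensemble statistics")
    stats = np.array(
        [[s.levels.mean(), s.levels.std(ddof=1), len(s)] for s in ensemble]
    )
    centre = stats.mean(axis=0)
    spread = stats.std(axis=0, ddof=1)
    keep = []
    for s, row in zip(ensemble, stats):
        ok = True
        for v, c, sd in zip(row, centre, spread):
            if sd > 0 and abs(v - c) > k_sigma * sd:
                ok = False
                break
        if ok:
            keep.append(s)
    if not keep:
        raise EmptyEnsembleError("global filter removed every read")
    return Ensemble(keep, label=ensemble.label)


def _section_sd_mean(levels: np.ndarray, n_sections: int) -> float:
    # first n-1 sections of floor(L/n) events; the last absorbs the remainder
    base = levels.size // n_sections
    sds = []
    for i in range(n_sections):
        lo = i * base
        hi = (i + 1) * base if i < n_sections - 1 else levels.size
        sec = levels[lo:hi]
        sds.append(sec.std(ddof=1) if sec.size > 1 else 0.0)
    return float(np.mean(sds))


def filter_sectional(
    ensemble: Ensemble, n_sections: int = 10, k_sigma: float = 2.0
) -> Ensemble:
    """Reject reads whose mean sectional intensity sigma is an ensemble
    outlier — the signature of chimeric or internally inconsistent reads."""
    if len(ensemble) < 3:
        raise ValueError("need at least 3 reads for stable ensemble statistics")
    stats = {}
    too_short = set()
    for s in ensemble:
        if len(s) < n_sections:
            too_short.add(s.read_id)
        else:
            stats[s.read_id] = _section_sd_mean(s.levels, n_sections)
    values = np.array(list(stats.values()))
    centre = values.mean()
    spread = values.std(ddof=1)
    keep = []
    for s in ensemble:
        if s.read_id in too_short:
            continue
        if spread > 0 and abs(stats[s.read_id] - centre) > k_sigma * spread:
            continue
        keep.append(s)
    if not keep:
        raise EmptyEnsembleError("sectional filter removed every read")
    return Ensemble(keep, label=ensemble.label)


def snr_ratio(mean: float, sd: float) -> float:
    """Length signal-to-noise ratio from summary statistics: mean / sigma."""
    if sd == 0:
        warnings.warn("zero length spread: SNR_LENGTH is infinite", stacklevel=2)
        return float("inf")
    return mean / sd


def snr_length(lengths) -> float:
    """SNR_LENGTH of a set of read lengths: mean / sample standard deviation.

    Higher values indicate more consistent lengths across the ensemble.
    """
    lengths = np.asarray(lengths, dtype=np.float64)
    if lengths.size < 2:
        raise ValueError("need at least 2 lengths")
    return snr_ratio(float(lengths.mean()), float(lengths.std(ddof=1)))


def distortion_level(mean_cleaned_length: float, gold_length: float) -> float:
    """Segmentation distortion level: mean cleaned read length / gold length."""
    if gold_length <= 0:
        raise ValueError("gold_length must be positive")
    return mean_cleaned_length / gold_length


def clean_pipeline(
    ensemble: Ensemble,
    cfg: CleaningConfig = CleaningConfig(),
    gold: GoldModel | None = None,
) -> tuple[Ensemble, CleaningReport]:
    """Run the full cascade and return the cleaned ensemble plus a report.

    Stage counts telescope (each stage's output is the next stage's input);
    any stage that empties the ensemble raises :class:`EmptyEnsembleError`
    naming the stage.
    """
    if len(ensemble) < 3:
        raise ValueError("need at least 3 reads")
    report = CleaningReport()
    lengths0 = ensemble.lengths()
    report.length_mean_before = float(lengths0.mean())
    report.length_sd_before = float(lengths0.std(ddof=1))
    report.snr_length_before = snr_length(lengths0)

    stages = [
        ("filter_short", lambda e: filter_short(e, cfg.short_fraction)),
        ("strip_leaders", lambda e: strip_leaders(e, cfg)),
        ("filter_short_post_leader", lambda e: filter_short(e, cfg.short_fraction)),
        ("filter_global", lambda e: filter_global(e, cfg.global_k_sigma)),
        ("filter_sectional", lambda e: filter_sectional(e, cfg.n_sections, cfg.sectional_k_sigma)),
    ]
    current = ensemble
    for name, fn in stages:
        before_ids = set(current.read_ids)
        try:
            nxt = fn(current)
        except EmptyEnsembleError as exc:
            raise EmptyEnsembleError(f"stage {name!r}: {exc}") from None
        removed = sorted(before_ids - set(nxt.read_ids))
        report.stages.append(StageRecord(name, len(current), len(nxt), removed))
        current = nxt

    lengths1 = current.lengths()
    report.length_mean_after = float(lengths1.mean())
    report.length_sd_after = float(lengths1.std(ddof=1)) if lengths1.size > 1 else 0.0
    report.snr_length_after = (
        snr_length(lengths1) if lengths1.size > 1 else float("inf")
    )
    if gold is not None:
        report.distortion_level = distortion_level(report.length_mean_after, gold.gold_length)
    return current, report
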