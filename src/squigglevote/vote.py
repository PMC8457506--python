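"""Ensemble voting on warp-path stretch runs.

A DTWA consensus of ~1.7x-inflated squiggles retains most of the segmental
duplications present in its inputs.  Aligning each ensemble member back to
the consensus exposes them: wherever a single squiggle event pairs with a
run of k >= 2 consecutive consensus positions, that part of the squiggle
was stretched to match the consensus, i.e. the consensus is locally
duplicated.  Each voter contributes one duplication vote to every position
of such a run *except the first* (deleting all-but-first makes a pure
duplication collapse exactly to its source).  Positions whose vote fraction
reaches a threshold are deleted in a single pass.

The mirror signal — a consensus position stretched against several squiggle
events — indicates an event *missing* from the consensus.  Those insertion
votes are tallied for diagnostics but never modify the consensus: what
value to insert is not answerable from the warp path alone.

Sweeping the agreement threshold from 100% down to 10% and picking the
variant with the minimum mean DTW distance back to the voters selects a
final consensus without ever consulting the gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .average import Consensus
from .squiggle_io import Ensemble, GoldModel
from .warp import dtw, dtw_distance, stretch_runs

__all__ = [
    "VoteTable",
    "VotingSweep",
    "default_thresholds",
    "duplication_votes",
    "insertion_votes",
    "tally_votes",
    "apply_votes",
    "vote_sweep",
    "select_final",
]


@dataclass
class VoteTable:
    """Per-consensus-position vote counts from ``n_voters`` squiggles."""

    n_voters: int
    dup_votes: np.ndarray
    ins_votes: np.ndarray

    def __post_init__(self) -> None:
        self.dup_votes = np.asarray(self.dup_votes, dtype=np.int64)
        self.ins_votes = np.asarray(self.ins_votes, dtype=np.int64)
        for arr in (self.dup_votes, self.ins_votes):
            if arr.min(initial=0) < 0 or arr.max(initial=0) > self.n_voters:
                raise ValueError("vote counts must lie in [0, n_voters]")

    @property
    def dup_fractions(self) -> np.ndarray:
        return self.dup_votes / self.n_voters


@dataclass
class VotingSweep:
    """Results of a descending-threshold voting sweep."""

    thresholds: np.ndarray
    lengths: np.ndarray
    mean_dist: np.ndarray          # mean DTW distance to the voters
    sd_dist: np.ndarray
    gold_dist: np.ndarray | None   # DTW distance to the gold model, if given
    voted_levels: list[np.ndarray] = field(default_factory=list)
    selected_threshold: float | None = None

    def to_records(self) -> list[dict]:
        rows = []
        for i, t in enumerate(self.thresholds):
            row = {
                "threshold": float(t),
                "length": int(self.lengths[i]),
                "mean_dist": float(self.mean_dist[i]),
                "sd_dist": float(self.sd_dist[i]),
            }
            if self.gold_dist is not None:
                row["gold_dist"] = float(self.gold_dist[i])
            rows.append(row)
        return rows


def default_thresholds() -> np.ndarray:
    """100% agreement down to 10% in steps of 5%."""
    return np.round(np.arange(1.0, 0.0999, -0.05), 2)


def _levels(consensus) -> np.ndarray:
    return consensus.levels if hasattr(consensus, "levels") else np.asarray(consensus, float)


def tally_votes(consensus, voters: Ensemble) -> VoteTable:
    """Align every voter to the consensus and tally both vote kinds.

    Voter-side stretch runs (one voter event paired with several consensus
    positions) yield duplication votes on all-but-first run positions;
    consensus-side runs yield insertion votes on the stretched consensus
    position.  A voter contributes at most one vote of each kind per
    position; a voter identical to the consensus contributes none.
    """
    cons = _levels(consensus)
    if len(voters) == 0:
        raise ValueError("empty voter ensemble")
    dup = np.zeros(cons.size, dtype=np.int64)
    ins = np.zeros(cons.size, dtype=np.int64)
    for voter in voters:
        path = dtw(cons, voter.levels).path
        dup_hits: set[int] = set()
        ins_hits: set[int] = set()
        # voter index fixed, consensus indices advance -> consensus duplicated
        for _, cons_run in stretch_runs(path, side="B"):
            dup_hits.update(int(p) for p in cons_run[1:])
        # consensus index fixed, voter indices advance -> consensus missing events
        for cons_pos, _ in stretch_runs(path, side="A"):
            ins_hits.add(cons_pos)
        for p in dup_hits:
            dup[p] += 1
        for p in ins_hits:
            ins[p] += 1
    return VoteTable(n_voters=len(voters), dup_votes=dup, ins_votes=ins)


def duplication_votes(consensus, voters: Ensemble) -> VoteTable:
    """Vote table for duplicated consensus positions (V_DUPLICATED)."""
    return tally_votes(consensus, voters)


def insertion_votes(consensus, voters: Ensemble) -> VoteTable:
    """Vote table for missing consensus positions (V_ABSENT, diagnostic only)."""
    return tally_votes(consensus, voters)


def apply_votes(consensus, table: VoteTable, threshold: float) -> np.ndarray:
    """Delete every position whose duplication vote fraction is >= threshold.

    Single pass on the original consensus; surviving levels keep their
    values and order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    cons = _levels(consensus)
    keep = table.dup_fractions < threshold
    if not keep.any():
        raise ValueError("voting would delete the entire consensus")
    return cons[keep]


def vote_sweep(
    consensus,
    voters: Ensemble,
    thresholds=None,
    gold: GoldModel | None = None,
) -> VotingSweep:
    """Apply the vote table at each threshold of a descending grid.

    The vote table is computed once on the original consensus and re-used:
    each threshold is a single-pass deletion, with no re-averaging or
    re-voting.  For each variant the mean/sd DTW distance back to the
    voters is recorded (and the gold distance, when a gold model is
    supplied — for evaluation only, never selection).
    """
    thresholds = default_thresholds() if thresholds is None else np.asarray(thresholds, float)
    if thresholds.size == 0:
        raise ValueError("empty threshold list")
    if np.any(np.diff(thresholds) > 0):
        raise ValueError("thresholds must be descending")
    table = tally_votes(consensus, voters)
    lengths = np.empty(thresholds.size, dtype=np.int64)
    mean_d = np.empty(thresholds.size)
    sd_d = np.empty(thresholds.size)
    gold_d = np.empty(thresholds.size) if gold is not None else None
    voted_levels = []
    for i, t in enumerate(thresholds):
        voted = apply_votes(consensus, table, float(t))
        voted_levels.append(voted)
        lengths[i] = voted.size
        dists = np.array([dtw_distance(voted, v.levels) for v in voters])
        mean_d[i] = dists.mean()
        sd_d[i] = dists.std(ddof=1) if dists.size > 1 else float("nan")
        if gold_d is not None:
            gold_d[i] = dtw_distance(voted, gold.levels)
    return VotingSweep(
        thresholds=thresholds,
        lengths=lengths,
        mean_dist=mean_d,
        sd_dist=sd_d,
        gold_dist=gold_d,
        voted_levels=voted_levels,
    )


def select_final(sweep: VotingSweep, source: Consensus | None = None) -> tuple[float, Consensus]:
    """Pick the threshold minimising the mean distance to the voters.

    Gold-free by construction; ties break towards the larger threshold
    (fewer deletions).  Returns the threshold and the voted consensus.
    """
    if sweep.thresholds.size == 0:
        raise ValueError("empty sweep")
    idx = int(np.argmin(sweep.mean_dist))  # thresholds descend: first min = largest threshold
    threshold = float(sweep.thresholds[idx])
    sweep.selected_threshold = threshold
    final = Consensus(
        levels=sweep.voted_levels[idx],
        algorithm=(source.algorithm if source else "voted") + "+vote",
        iterations=source.iterations if source else 0,
        frechet_history=[],
        source_size=source.source_size if source else 0,
        seed=source.seed if source else None,
    )
    return threshold, final
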