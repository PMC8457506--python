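"""Dynamic time warped-space averaging (DTWA) of squiggle ensembles.

Three consensus algorithms are provided, all initialised from a medoid and
all producing a consensus of fixed (medoid) length:

DBA
    batch barycentre averaging: every read is aligned to the current
    consensus, then each consensus position is replaced by the mean of all
    read values warped onto it.  Deterministic and order-invariant.
MM
    incremental ("minimize mean") averaging: the consensus is updated after
    each alignment as a running warped mean; may depend on visit order.
SSG
    stochastic subgradient descent on the Frechet function, initialised
    from the medoid of a seeded random subsample; seed-dependent.

The Frechet function — the DTWA objective — is the sum of *squared* DTW
distances from a candidate to the ensemble, while reported distances stay
plain accumulated |.| costs; both conventions are kept as printed sources
state them (a deliberate asymmetry, also present in the medoid criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .squiggle_io import Ensemble
from .warp import dtw, dtw_distance

__all__ = ["Consensus", "medoid", "frechet", "dba", "mm_mean", "ssg_mean"]


@dataclass
class Consensus:
    """A DTWA average plus provenance."""

    levels: np.ndarray
    algorithm: str
    iterations: int
    frechet_history: list[float]
    source_size: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)
        if self.levels.size == 0:
            raise ValueError("consensus levels must be non-empty")

    def __len__(self) -> int:
        return self.levels.size


def frechet(candidate, ensemble: Ensemble) -> float:
    """Sum of squared DTW distances from ``candidate`` to every read."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    return float(sum(dtw_distance(candidate, s.levels) ** 2 for s in ensemble))


def medoid(ensemble: Ensemble) -> int:
    """Index of the read with the smallest sum of squared DTW distances to
    all other reads; ties break to the lowest index.  O(N^2) alignments."""
    n = len(ensemble)
    if n == 0:
        raise ValueError("empty ensemble")
    if n == 1:
        return 0
    series = ensemble.level_arrays()
    totals = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d2 = dtw_distance(series[i], series[j]) ** 2
            totals[i] += d2
            totals[j] += d2
    return int(np.argmin(totals))


def _warped_mean(consensus: np.ndarray, reads: list[np.ndarray]) -> np.ndarray:
    """Align each read to the consensus; per consensus position, mean of all
    read values warped onto it."""
    sums = np.zeros(consensus.size)
    counts = np.zeros(consensus.size, dtype=np.int64)
    for read in reads:
        path = dtw(consensus, read).path
        np.add.at(sums, path.a_indices, read[path.b_indices])
        np.add.at(counts, path.a_indices, 1)
    # boundary-complete paths touch every consensus index at least once
    assert counts.min() >= 1
    return sums / counts


def dba(ensemble: Ensemble, max_iter: int = 10, tol: float = 1e-4) -> Consensus:
    """DTW barycentre averaging.

    Initialised at the ensemble medoid, which fixes the consensus length.
    Iterates batch barycentre updates until the relative Frechet improvement
    drops below ``tol`` or ``max_iter`` is reached; an update that would
    increase the Frechet function is discarded and iteration stops, so the
    recorded history is non-increasing and the returned consensus attains
    its last entry.  Reads are processed in a canonical (read-id-sorted)
    order internally, making the result bit-identical under any input
    permutation.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least 2 reads")
    order = sorted(range(len(ensemble)), key=lambda i: ensemble[i].read_id)
    reads = [ensemble[i].levels for i in order]
    x = ensemble[medoid(ensemble)].levels.copy()
    history: list[float] = [float(sum(dtw_distance(x, r) ** 2 for r in reads))]
    for _ in range(max_iter):
        x_new = _warped_mean(x, reads)
        f_new = float(sum(dtw_distance(x_new, r) ** 2 for r in reads))
        if f_new > history[-1]:
            break  # non-improving update: keep the previous consensus
        x = x_new
        history.append(f_new)
        if history[-2] == 0.0 or (history[-2] - history[-1]) <= tol * history[-2]:
            break
    return Consensus(
        levels=x,
        algorithm="DBA",
        iterations=len(history) - 1,
        frechet_history=history,
        source_size=len(ensemble),
    )


def mm_mean(ensemble: Ensemble, passes: int = 1, order: list[int] | None = None) -> Consensus:
    """Incremental warped-mean consensus.

    Visiting reads in ``order`` (default: input order), after the t-th visit
    the consensus is the running mean with weight 1/t: each visited read is
    warped onto the consensus grid and averaged in.  The result may depend
    on the visit order; that is a property of incremental DTWA, not a bug.
    """
    n = len(ensemble)
    if n < 2:
        raise ValueError("need at least 2 reads")
    if order is None:
        order = list(range(n))
    if sorted(order) != list(range(n)):
        raise ValueError("order must be a permutation of the ensemble indices")
    reads = ensemble.level_arrays()
    x = reads[medoid(ensemble)].copy()
    t = 0
    for _ in range(passes):
        for idx in order:
            t += 1
            read = reads[idx]
            path = dtw(x, read).path
            sums = np.zeros(x.size)
            counts = np.zeros(x.size, dtype=np.int64)
            np.add.at(sums, path.a_indices, read[path.b_indices])
            np.add.at(counts, path.a_indices, 1)
            y = sums / counts
            x = ((t - 1) * x + y) / t
    history = [frechet(x, ensemble)]
    return Consensus(
        levels=x,
        algorithm="MM",
        iterations=passes,
        frechet_history=history,
        source_size=n,
    )


def ssg_mean(
    ensemble: Ensemble,
    epochs: int = 3,
    step0: float = 0.25,
    seed: int = 0,
    subsample_size: int = 16,
) -> Consensus:
    """Stochastic subgradient consensus.

    The initial consensus is the medoid of a seeded random subsample of at
    most ``subsample_size`` reads.  Each visit t aligns one read (seeded
    shuffle every epoch) and steps the consensus along the per-position
    subgradient 2 (x_pos - mean of values warped onto pos) with step size
    step0 / sqrt(t).  A fixed seed makes the run bit-reproducible; different
    seeds may give different consensuses.
    """
    n = len(ensemble)
    if n < 2:
        raise ValueError("need at least 2 reads")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(seed)
    reads = ensemble.level_arrays()
    sub_idx = rng.choice(n, size=min(n, subsample_size), replace=False)
    sub = Ensemble([ensemble[int(i)] for i in sub_idx], label="ssg-subsample")
    x = sub[medoid(sub)].levels.copy()
    history = [frechet(x, ensemble)]
    t = 0
    for _ in range(epochs):
        for idx in rng.permutation(n):
            t += 1
            read = reads[int(idx)]
            path = dtw(x, read).path
            sums = np.zeros(x.size)
            counts = np.zeros(x.size, dtype=np.int64)
            np.add.at(sums, path.a_indices, read[path.b_indices])
            np.add.at(counts, path.a_indices, 1)
            grad = 2.0 * (x - sums / counts)
            x = x - (step0 / np.sqrt(t)) * grad
        history.append(frechet(x, ensemble))
    return Consensus(
        levels=x,
        algorithm="SSG",
        iterations=epochs,
        frechet_history=history,
        source_size=n,
        seed=seed,
    )
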