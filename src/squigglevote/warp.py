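"""Dynamic time warping core and warp-path utilities.

The DTW distance between two level series is the minimum, over all monotone
boundary-complete index paths with steps {(1,0), (0,1), (1,1)}, of the sum
of |a_i - b_j| along the path.  One cost function is used everywhere in the
package so distances reported by different stages are directly comparable.

Series are deliberately *not* z-normalised before alignment: the squiggles
of one ensemble share a common pA scale, and per-read self-normalisation
would reduce, rather than increase, their inherent similarity.  Callers who
do want it can normalise before calling :func:`dtw`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _dtw_core

__all__ = [
    "WarpPath",
    "AlignmentResult",
    "dtw",
    "dtw_distance",
    "dtw_oracle",
    "stretch_runs",
    "normalize_path",
    "dfi",
]


@dataclass(frozen=True)
class WarpPath:
    """A monotone index-pair alignment between series A and B.

    ``steps`` is an integer array of shape (L, 2); column 0 indexes A,
    column 1 indexes B.  The path starts at (0, 0), ends at
    (len_a - 1, len_b - 1) and advances by (1,0), (0,1) or (1,1).
    """

    steps: np.ndarray

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps, dtype=np.int64)
        object.__setattr__(self, "steps", steps)
        if steps.ndim != 2 or steps.shape[1] != 2 or steps.shape[0] == 0:
            raise ValueError("warp path must be a non-empty (L, 2) array")
        if tuple(steps[0]) != (0, 0):
            raise ValueError("warp path must start at (0, 0)")
        d = np.diff(steps, axis=0)
        if len(d) and not (
            np.all((d >= 0) & (d <= 1)) and np.all(d.sum(axis=1) >= 1)
        ):
            raise ValueError("warp path steps must be (1,0), (0,1) or (1,1)")

    def __len__(self) -> int:
        return self.steps.shape[0]

    @property
    def a_indices(self) -> np.ndarray:
        return self.steps[:, 0]

    @property
    def b_indices(self) -> np.ndarray:
        return self.steps[:, 1]

    def transpose(self) -> "WarpPath":
        return WarpPath(self.steps[:, ::-1].copy())

    def to_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.steps, fmt="%d", delimiter="\t", header="i\tj", comments="")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WarpPath":
        return cls(np.loadtxt(path, dtype=np.int64, delimiter="\t", skiprows=1))


@dataclass(frozen=True)
class AlignmentResult:
    """DTW distance (accumulated |.| cost, pA units) and the optimal path."""

    distance: float
    path: WarpPath


def _as_series(x, name: str) -> np.ndarray:
    arr = np.ascontiguousarray(x, dtype=np.float64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name}: expected a non-empty 1-D series")
    return arr


def dtw(a, b) -> AlignmentResult:
    """Align two level series, returning distance and optimal warp path."""
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    D = _dtw_core.accumulated_cost(a, b)
    pi, pj = _dtw_core.traceback(D)
    return AlignmentResult(float(D[-1, -1]), WarpPath(np.column_stack([pi, pj])))


def dtw_distance(a, b) -> float:
    """DTW distance only, in O(min memory); identical value to :func:`dtw`."""
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    if b.size < a.size:  # iterate over the longer axis with the shorter row
        a, b = b, a
    return float(_dtw_core.distance_only(a, b))


def dtw_oracle(a, b) -> AlignmentResult:
    """Exhaustive enumeration of every admissible warp path (testing oracle).

    Only feasible for series of length <= 8; agrees with :func:`dtw` on the
    optimal distance by construction.
    """
    a = _as_series(a, "a")
    b = _as_series(b, "b")
    if a.size > 8 or b.size > 8:
        raise ValueError("oracle restricted to series of length <= 8")
    n, m = a.size, b.size
    best_cost = np.inf
    best_path: list[tuple[int, int]] | None = None

    stack: list[tuple[int, int, float, list[tuple[int, int]]]] = [
        (0, 0, abs(a[0] - b[0]), [(0, 0)])
    ]
    while stack:
        i, j, cost, path = stack.pop()
        if i == n - 1 and j == m - 1:
            if cost < best_cost:
                best_cost = cost
                best_path = path
            continue
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                stack.append((ni, nj, cost + abs(a[ni] - b[nj]), path + [(ni, nj)]))
    assert best_path is not None
    return AlignmentResult(float(best_cost), WarpPath(np.array(best_path)))


def count_paths(n: int, m: int) -> int:
    """Number of admissible warp paths between series of lengths n and m."""
    c = np.zeros((n, m), dtype=object)
    c[0, :] = 1
    c[:, 0] = 1
    for i in range(1, n):
        for j in range(1, m):
            c[i, j] = c[i - 1, j] + c[i, j - 1] + c[i - 1, j - 1]
    return int(c[n - 1, m - 1])


def stretch_runs(path: WarpPath, side: str) -> list[tuple[int, np.ndarray]]:
    """Maximal runs where the ``side`` index repeats while the partner advances.

    Returns ``[(fixed index on side, partner index run), ...]``; empty for a
    strictly diagonal path.  A squiggle-side run against a consensus is the
    voting signal that the consensus is locally duplicated.
    """
    if side == "A":
        fixed, partner = path.a_indices, path.b_indices
    elif side == "B":
        fixed, partner = path.b_indices, path.a_indices
    else:
        raise ValueError(f"side must be 'A' or 'B', got {side!r}")
    runs = []
    start = 0
    for t in range(1, len(fixed) + 1):
        if t == len(fixed) or fixed[t] != fixed[start]:
            if t - start >= 2:
                runs.append((int(fixed[start]), partner[start:t].copy()))
            start = t
    return runs


def normalize_path(path: WarpPath, len_a: int, len_b: int) -> np.ndarray:
    """Warp path as fractional coordinates in [0, 1]^2 (column 0 = A)."""
    if len_a < 2 or len_b < 2:
        raise ValueError("normalized paths require series of length >= 2")
    if path.steps[-1, 0] != len_a - 1 or path.steps[-1, 1] != len_b - 1:
        raise ValueError("declared lengths do not match the path extremes")
    return path.steps / np.array([len_a - 1, len_b - 1], dtype=np.float64)


def dfi(path: WarpPath, len_a: int, len_b: int) -> np.ndarray:
    """Difference-from-Identity series of a warp path.

    Per step, ``j/(len_b - 1) - i/(len_a - 1)`` with A conventionally the
    gold standard and B the consensus.  Flat near zero where the two series
    are noisy stretchings of one another; excursions mark local distortion.
    """
    norm = normalize_path(path, len_a, len_b)
    return norm[:, 1] - norm[:, 0]
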