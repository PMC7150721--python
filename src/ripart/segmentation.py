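"""Fisher's optimal segmentation of ordered multivariate samples.

Given n ordered m-dimensional samples x_1..x_n (here: age-bin feature rows),
a k-class *ordered* clustering keeps every class a contiguous run:

    P_1 = {i_1, ..., i_2 - 1}, ..., P_k = {i_k, ..., n},   1 = i_1 < ... < i_k.

The dispersion of a class covering samples i..j is its diameter

    D(i, j) = sum_{t=i}^{j} (x_t - xbar)' (x_t - xbar),

and the objective is the total within-class dispersion
B(n, k) = sum_t D(i_t, i_{t+1} - 1).  The global optimum B*(n, k) over all
C(n-1, k-1) contiguous partitions is found exactly by dynamic programming:

    B*(i, 1) = D(1, i)
    B*(i, k) = min_{k <= j <= i} [ B*(j-1, k-1) + D(j, i) ],

with cut points recovered by backtracking the minimizing j.  The drop
f(k) = B*(n, k-1) - B*(n, k) measures how much an extra class buys; the
class count is chosen from the f(k) curve (see ``select_k``).

All public indices are 1-based inclusive, matching the usual statement of
the method; ``SegmentationResult`` translates classes to age-bin labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .preprocess import OrderedSampleMatrix

__all__ = [
    "SegmentationResult",
    "count_partitions",
    "class_diameter",
    "pairwise_diameters",
    "optimal_segmentation",
    "brute_force_segmentation",
    "slope_curve",
    "select_k",
]

#: relative tolerance under which two objective values count as tied;
#: ties go to the smallest cut index, identically in the DP and the oracle
TIE_REL_TOL = 1e-12

#: default "f(k) close to zero" threshold, as a fraction of B*(n, 1)
DEFAULT_TOLERANCE = 0.05


def _as_array(matrix: OrderedSampleMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, OrderedSampleMatrix):
        return np.asarray(matrix.analysis_values(), dtype=float)
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def count_partitions(n: int, k: int) -> int:
    """Number of ways to split n ordered samples into k contiguous classes.

    Exactly C(n-1, k-1): a partition is a choice of k-1 cut points among
    the n-1 gaps between consecutive samples.
    """
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    return math.comb(n - 1, k - 1)


def class_diameter(
    matrix: OrderedSampleMatrix | np.ndarray, i: int, j: int
) -> float:
    """Diameter D(i, j): total squared deviation of samples i..j (1-based,
    inclusive) from their class mean vector.  Direct summation; used as the
    reference definition the cached table must reproduce."""
    x = _as_array(matrix)
    n = x.shape[0]
    if not (1 <= i <= j <= n):
        raise ValueError(f"need 1 <= i <= j <= n, got i={i}, j={j}, n={n}")
    block = x[i - 1 : j]
    centered = block - block.mean(axis=0)
    return float(np.sum(centered * centered))


def pairwise_diameters(x: np.ndarray) -> np.ndarray:
    """All D(i, j) for 1 <= i <= j <= n as an (n+1) x (n+1) table
    (1-based; unused entries 0).

    Uses prefix sums of the rows and of the squared row norms:
    D(i, j) = Q(i, j) - ||S(i, j)||^2 / (j - i + 1), O(n^2 m) total.
    """
    n = x.shape[0]
    row_sq = np.einsum("ij,ij->i", x, x)
    S = np.vstack([np.zeros(x.shape[1]), np.cumsum(x, axis=0)])
    Q = np.concatenate([[0.0], np.cumsum(row_sq)])
    D = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            s = S[j] - S[i - 1]
            val = Q[j] - Q[i - 1] - float(s @ s) / (j - i + 1)
            D[i, j] = max(val, 0.0)  # clip tiny negative rounding
    return D


def _better(candidate: float, incumbent: float) -> bool:
    """Strictly-better comparison with the shared tie tolerance."""
    return candidate < incumbent - TIE_REL_TOL * max(abs(incumbent), 1.0)


@dataclass(frozen=True)
class SegmentationResult:
    """Full output of the exact dynamic program.

    ``bstar[i][k]`` (1-based) is the minimal total within-class dispersion
    of the first i samples in k classes; ``bstar_row`` is its last row
    B*(n, k) for k = 1..k_max.  ``boundaries[k]`` are the cut indices
    (i_1=1, i_2, ..., i_k); ``fk[k]`` the drop B*(n,k-1) - B*(n,k) for
    k >= 2.  ``classes``/``class_labels`` describe the partition at the
    selected ``k_opt``.
    """

    n: int
    k_max: int
    bstar: np.ndarray          # (n+1) x (k_max+1), 1-based
    diameters: np.ndarray      # (n+1) x (n+1), 1-based
    boundaries: dict[int, tuple[int, ...]]
    fk: dict[int, float]
    k_opt: int
    row_labels: tuple[int, ...]

    @property
    def bstar_row(self) -> np.ndarray:
        return self.bstar[self.n, 1 : self.k_max + 1]

    def classes_at(self, k: int) -> list[tuple[int, int]]:
        """Contiguous 1-based (start, end) index ranges of the k classes."""
        cuts = self.boundaries[k]
        ends = [*(c - 1 for c in cuts[1:]), self.n]
        return list(zip(cuts, ends))

    def boundary_labels(self, k: int) -> tuple[int, ...]:
        """Row labels (age bins) where classes 2..k begin."""
        return tuple(self.row_labels[c - 1] for c in self.boundaries[k][1:])

    @property
    def classes(self) -> list[tuple[int, int]]:
        return self.classes_at(self.k_opt)


def optimal_segmentation(
    matrix: OrderedSampleMatrix | np.ndarray,
    k_max: int,
    tolerance: float = DEFAULT_TOLERANCE,
    rule: str = "elbow",
) -> SegmentationResult:
    """Exact optimal ordered clustering for every k up to ``k_max``.

    Runs the dynamic program on the matrix's analysis values (the
    nondimensionalized matrix when available), backtracks the optimal cut
    points for each k, computes the f(k) drops and selects ``k_opt`` via
    ``select_k``.  Ties between cut points are broken toward the smallest
    index, so results are fully deterministic.
    """
    x = _as_array(matrix)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 ordered samples")
    if not (2 <= k_max <= n):
        raise ValueError(f"need 2 <= k_max <= n, got k_max={k_max}, n={n}")

    D = pairwise_diameters(x)
    B = np.full((n + 1, k_max + 1), np.inf)
    J = np.zeros((n + 1, k_max + 1), dtype=int)
    for i in range(1, n + 1):
        B[i, 1] = D[1, i]
        J[i, 1] = 1
    for k in range(2, k_max + 1):
        for i in range(k, n + 1):
            best = np.inf
            best_j = -1
            for j in range(k, i + 1):
                cand = B[j - 1, k - 1] + D[j, i]
                if best_j < 0 or _better(cand, best):
                    best, best_j = cand, j
            B[i, k] = best
            J[i, k] = best_j

    boundaries: dict[int, tuple[int, ...]] = {1: (1,)}
    for k in range(2, k_max + 1):
        cuts = []
        i, kk = n, k
        while kk >= 2:
            j = J[i, kk]
            cuts.append(int(j))
            i, kk = j - 1, kk - 1
        boundaries[k] = (1, *reversed(cuts))

    bstar_row = B[n, 1 : k_max + 1]
    fk_vals = slope_curve(bstar_row)
    fk = {k: float(f) for k, f in zip(range(2, k_max + 1), fk_vals)}
    k_opt = select_k(fk_vals, float(bstar_row[0]), tolerance=tolerance, rule=rule)

    row_labels = (
        matrix.row_labels
        if isinstance(matrix, OrderedSampleMatrix)
        else tuple(range(1, n + 1))
    )
    return SegmentationResult(
        n=n,
        k_max=k_max,
        bstar=B,
        diameters=D,
        boundaries=boundaries,
        fk=fk,
        k_opt=k_opt,
        row_labels=row_labels,
    )


def brute_force_segmentation(
    matrix: OrderedSampleMatrix | np.ndarray, k: int
) -> tuple[float, tuple[int, ...]]:
    """Exhaustive minimum of the objective over all C(n-1, k-1) partitions.

    Independent oracle for the dynamic program: enumerates every set of cut
    points in lexicographic order, summing class diameters by direct
    computation, with the same tie rule (first, i.e. smallest, cuts win).
    """
    x = _as_array(matrix)
    n = x.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    budget = count_partitions(n, k)
    if budget > 10**6:
        raise ValueError(f"refusing brute force over {budget} partitions (> 1e6)")

    best = np.inf
    best_cuts: tuple[int, ...] | None = None
    for extra in combinations(range(2, n + 1), k - 1):
        cuts = (1, *extra)
        ends = [*(c - 1 for c in cuts[1:]), n]
        total = 0.0
        for start, end in zip(cuts, ends):
            total += class_diameter(x, start, end)
        if best_cuts is None or _better(total, best):
            best, best_cuts = total, cuts
    assert best_cuts is not None
    return float(best), best_cuts


def slope_curve(bstar_row: Sequence[float] | np.ndarray) -> np.ndarray:
    """f(k) = |B*(n,k) - B*(n,k-1)| / 1 for k = 2..k_max.

    ``bstar_row`` holds B*(n, k) for k = 1..k_max and must be
    non-increasing (a longer partition never fits worse); the unit
    denominator is the step k - (k-1).
    """
    b = np.asarray(bstar_row, dtype=float)
    if b.size < 2:
        return np.empty(0)
    diffs = b[:-1] - b[1:]
    if np.any(diffs < -1e-9 * np.maximum(np.abs(b[:-1]), 1.0)):
        raise ValueError("bstar_row must be non-increasing in k")
    return np.abs(diffs)


def select_k(
    f: Sequence[float] | np.ndarray,
    b_total: float,
    tolerance: float = DEFAULT_TOLERANCE,
    rule: str = "elbow",
) -> int:
    """Choose the class count from the f(k) curve.

    ``f[0]`` corresponds to k = 2.  A drop counts as *substantial* when it
    is at least ``tolerance * b_total`` (b_total = B*(n, 1), the total
    dispersion); drops below that are "close to zero" and further
    subdivision stops.  If no drop is substantial the data carry no age
    structure and 1 ("no partition") is returned.

    rule = "elbow" (default): the largest k whose drop f(k) is still
    substantial — the bend where the B*-k curve flattens.  On ordered data
    with c well-separated phases, drops through k = c stay large while
    f(c+1) collapses to noise, so the elbow recovers c.

    rule = "argmax": the k maximizing f(k) (subject to the same floor).
    On monotone-trend profiles the first split almost always removes the
    most dispersion, so this variant rarely selects beyond k = 2; it is
    provided for comparison.
    """
    f = np.asarray(f, dtype=float)
    if f.size == 0:
        raise ValueError("f must be non-empty")
    if not (0.0 < tolerance < 1.0):
        raise ValueError("tolerance must be in (0, 1)")
    floor = tolerance * b_total
    substantial = f >= floor
    if not substantial.any():
        return 1
    if rule == "elbow":
        # largest k with every drop up to it substantial (stop at first
        # negligible drop, as in "no need to continue subdividing")
        k = 2
        for idx in range(f.size):
            if substantial[idx]:
                k = idx + 2
            else:
                break
        return k
    if rule == "argmax":
        return int(np.argmax(f)) + 2
    raise ValueError(f"unknown rule {rule!r}")
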