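"""Per-sample cleaning and construction of ordered feature matrices.

The segmentation stage consumes an *ordered sample matrix*: one row per age
bin (ascending, ages 1-17), one column per feature.  In percentile mode the
features are the 20 empirical percentiles P5, P10, ..., P100 of a single
analyte within the bin; in summary mode each row is a short vector of
per-analyte central-tendency summaries (mean when the bin sample passes a
normality check, median otherwise).  Because features carry heterogeneous
scales, each column is nondimensionalized by its maximum before distances
are computed, so every column's maximum is exactly 1.

Cleaning follows standard reference-interval practice: Dixon's range test
(gap/range > 1/3) deletes extreme values, iterated until stable, and the
survivors are then only *flagged* (not removed) when they fall outside
Tukey fences at 1.5 IQR — the box-plot step is an inspection aid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .screening import SubjectRecord

__all__ = [
    "PercentileGrid",
    "OrderedSampleMatrix",
    "DixonResult",
    "KSResult",
    "InsufficientSampleError",
    "dixon_outlier_removal",
    "ks_normality",
    "boxcox_transform",
    "rank_quantile",
    "percentile_profile",
    "build_matrix",
    "nondimensionalize",
    "AGE_BINS",
]

#: age bins (completed years); bin t covers [t, t+1)
AGE_BINS: tuple[int, ...] = tuple(range(1, 18))

DIXON_RATIO = 1.0 / 3.0
KS_ALPHA = 0.05


class InsufficientSampleError(ValueError):
    """Sample too small for the requested operation."""


@dataclass(frozen=True)
class PercentileGrid:
    """Ordered percentile probabilities; default P5, P10, ..., P100."""

    probabilities: tuple[float, ...] = tuple(np.round(np.arange(1, 21) * 0.05, 2))

    def __post_init__(self) -> None:
        probs = self.probabilities
        if not probs or any(b <= a for a, b in zip(probs, probs[1:])):
            raise ValueError("probabilities must be strictly increasing")
        if any(not (0 < p <= 1) for p in probs):
            raise ValueError("probabilities must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.probabilities)


@dataclass(frozen=True)
class OrderedSampleMatrix:
    """n x m feature matrix over strictly ascending age bins.

    ``values`` is the raw matrix; ``normalized`` (filled by
    ``nondimensionalize``) divides each column by ``col_max``.
    """

    row_labels: tuple[int, ...]
    values: np.ndarray
    mode: str  # "percentile" | "summary"
    normalized: np.ndarray | None = None
    col_max: np.ndarray | None = None
    feature_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.row_labels, self.row_labels[1:])):
            raise ValueError("row_labels must be strictly ascending")
        if self.values.shape[0] != len(self.row_labels):
            raise ValueError("row_labels/values shape mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def analysis_values(self) -> np.ndarray:
        """The matrix the segmentation should run on (normalized if built)."""
        return self.normalized if self.normalized is not None else self.values


@dataclass(frozen=True)
class DixonResult:
    kept: np.ndarray
    removed: np.ndarray
    flagged: np.ndarray  # survivors outside Tukey fences (inspection only)


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    is_gaussian: bool
    degenerate: bool = False


def dixon_outlier_removal(
    values: Sequence[float] | np.ndarray,
    max_fraction: float = 0.05,
) -> DixonResult:
    """Iterated Dixon range test with Tukey-fence flagging of survivors.

    At each step the larger of the two end gaps (smallest-to-next and
    largest-to-previous), divided by the sample range, is compared with 1/3;
    the corresponding extreme is deleted when the ratio exceeds it.  Ties
    between the two ends delete the upper extreme.  Iterates until nothing
    is removed.  Survivors outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] are
    reported as flags, not removed.  A warning is issued when more than
    ``max_fraction`` of the input is deleted.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sample")
    n0 = arr.size
    if n0 < 3:
        raise InsufficientSampleError(f"Dixon test needs n >= 3, got {n0}")

    work = np.sort(arr)
    removed: list[float] = []
    while work.size >= 3:
        rng = work[-1] - work[0]
        if rng <= 0:
            break
        gap_low = (work[1] - work[0]) / rng
        gap_high = (work[-1] - work[-2]) / rng
        if gap_high >= gap_low:
            ratio, idx = gap_high, work.size - 1
        else:
            ratio, idx = gap_low, 0
        if ratio > DIXON_RATIO:
            removed.append(float(work[idx]))
            work = np.delete(work, idx)
        else:
            break

    # map deletions back to the original order, removing one instance each
    kept_mask = np.ones(n0, dtype=bool)
    for value in removed:
        hits = np.nonzero(kept_mask & (arr == value))[0]
        kept_mask[hits[0]] = False
    kept = arr[kept_mask]

    if kept.size >= 4:
        q1 = rank_quantile(np.sort(kept), 0.25)
        q3 = rank_quantile(np.sort(kept), 0.75)
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        flagged = kept[(kept < lo) | (kept > hi)]
    else:
        flagged = np.empty(0)

    if removed and len(removed) / n0 > max_fraction:
        warnings.warn(
            f"Dixon removal deleted {len(removed)}/{n0} values "
            f"(> {max_fraction:.0%} of the sample)",
            stacklevel=2,
        )
    return DixonResult(kept=kept, removed=np.asarray(removed), flagged=flagged)


def ks_normality(values: Sequence[float] | np.ndarray) -> KSResult:
    """One-sample Kolmogorov-Smirnov test against N(mean, sd) of the data.

    ``is_gaussian`` is True when p >= 0.05.  A constant sample is reported
    as degenerate and non-Gaussian.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 5:
        raise InsufficientSampleError(f"K-S normality needs n >= 5, got {arr.size}")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        return KSResult(statistic=1.0, p_value=0.0, is_gaussian=False, degenerate=True)
    stat, p = stats.kstest(arr, "norm", args=(float(np.mean(arr)), sd))
    return KSResult(statistic=float(stat), p_value=float(p), is_gaussian=bool(p >= KS_ALPHA))


_BOXCOX_GRID = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.05), 2)


def boxcox_transform(
    values: Sequence[float] | np.ndarray,
    lambdas: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Box-Cox power transform with lambda chosen on a fixed grid.

    Maximizes the profile log-likelihood over lambda in [-3, 3] (step 0.05)
    and applies (x^lam - 1)/lam, or log x at lam = 0.  The transform is
    strictly increasing for every lambda, so rank order is preserved.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError(
            "Box-Cox requires strictly positive values; shift or exclude "
            "non-positive observations first"
        )
    grid = _BOXCOX_GRID if lambdas is None else np.asarray(lambdas, dtype=float)
    llf = np.array([stats.boxcox_llf(lam, arr) for lam in grid])
    lam = float(grid[int(np.argmax(llf))])
    if lam == 0.0:
        out = np.log(arr)
    else:
        out = (np.power(arr, lam) - 1.0) / lam
    return out, lam


def rank_quantile(sorted_values: np.ndarray, p: float) -> float:
    """Quantile at rank p*(n+1) with linear interpolation, clamped to [1, n].

    This is the nonparametric rank convention used throughout the package
    (percentile profiles and reference limits alike).  ``sorted_values``
    must already be ascending.
    """
    n = sorted_values.size
    if n == 0:
        raise InsufficientSampleError("empty sample")
    h = p * (n + 1)
    h = min(max(h, 1.0), float(n))
    lo = int(math.floor(h))
    hi = min(lo + 1, n)
    frac = h - lo
    return float(sorted_values[lo - 1] * (1.0 - frac) + sorted_values[hi - 1] * frac)


def percentile_profile(
    values: Sequence[float] | np.ndarray,
    grid: PercentileGrid | None = None,
) -> np.ndarray:
    """Empirical percentile feature vector of one sample on the grid."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size < 20:
        raise InsufficientSampleError(
            f"percentile profile needs n >= 20, got {arr.size}"
        )
    if grid is None:
        grid = PercentileGrid()
    return np.array([rank_quantile(arr, p) for p in grid.probabilities])


def _bin_values(
    records: Iterable[SubjectRecord], analyte: str
) -> dict[int, np.ndarray]:
    by_age: dict[int, list[float]] = {age: [] for age in AGE_BINS}
    for rec in records:
        value = rec.analytes.get(analyte)
        if value is not None and rec.age_years in by_age:
            by_age[rec.age_years].append(float(value))
    return {age: np.asarray(vals) for age, vals in by_age.items()}


def build_matrix(
    records: Sequence[SubjectRecord],
    analytes: str | Sequence[str],
    mode: str = "percentile",
    grid: PercentileGrid | None = None,
) -> OrderedSampleMatrix:
    """Assemble the ordered sample matrix over age bins 1-17.

    percentile mode: ``analytes`` is one analyte name; each row is the
    20-percentile profile of that analyte within an age bin (17 x 20).

    summary mode: ``analytes`` is the panel; each row holds one summary per
    analyte (17 x len(panel)).  An analyte is summarized by its mean when
    its pooled sample passes the K-S normality check and by its median
    otherwise, so a column means the same statistic in every row.
    """
    if mode == "percentile":
        if not isinstance(analytes, str):
            if len(analytes) != 1:
                raise ValueError("percentile mode takes a single analyte")
            analytes = analytes[0]
        by_age = _bin_values(records, analytes)
        rows = []
        for age in AGE_BINS:
            vals = by_age[age]
            if vals.size == 0:
                raise ValueError(f"age bin {age} absent")
            rows.append(percentile_profile(vals, grid))
        g = grid if grid is not None else PercentileGrid()
        labels = tuple(f"P{p * 100:g}" for p in g.probabilities)
        return OrderedSampleMatrix(
            row_labels=AGE_BINS,
            values=np.vstack(rows),
            mode="percentile",
            feature_labels=labels,
        )

    if mode == "summary":
        if isinstance(analytes, str):
            analytes = [analytes]
        panel = list(analytes)
        use_mean: dict[str, bool] = {}
        per_analyte: dict[str, dict[int, np.ndarray]] = {}
        for analyte in panel:
            by_age = _bin_values(records, analyte)
            per_analyte[analyte] = by_age
            pooled = np.concatenate([v for v in by_age.values() if v.size])
            if pooled.size < 5:
                raise InsufficientSampleError(f"analyte {analyte}: pooled n < 5")
            use_mean[analyte] = ks_normality(pooled).is_gaussian
        rows = []
        for age in AGE_BINS:
            row = []
            for analyte in panel:
                vals = per_analyte[analyte][age]
                if vals.size == 0:
                    raise ValueError(f"age bin {age} absent")
                row.append(
                    float(np.mean(vals)) if use_mean[analyte] else float(np.median(vals))
                )
            rows.append(row)
        return OrderedSampleMatrix(
            row_labels=AGE_BINS,
            values=np.asarray(rows, dtype=float),
            mode="summary",
            feature_labels=tuple(panel),
        )

    raise ValueError(f"unknown mode {mode!r}")


def nondimensionalize(matrix: OrderedSampleMatrix) -> OrderedSampleMatrix:
    """Divide each column by its maximum (x'_ij = x_ij / x_max,j).

    Removes units so heterogeneous columns contribute comparably to
    Euclidean class diameters; idempotent, and invariant to positive
    per-column rescaling of the input.
    """
    col_max = matrix.values.max(axis=0)
    if np.any(col_max <= 0):
        bad = int(np.argmax(col_max <= 0))
        raise ValueError(f"column {bad} has non-positive maximum; cannot normalize")
    normalized = matrix.values / col_max
    return replace(matrix, normalized=normalized, col_max=col_max)
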