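"""Statistical verification of candidate partitions (Harris-Boyd Z test).

Fisher segmentation proposes where adjacent age classes *could* differ;
the Harris-Boyd criterion decides whether the difference is large enough
to warrant separate reference intervals.  The standardized between-group
statistic

    z = |m1 - m2| / sqrt(sd1^2/n1 + sd2^2/n2)

is compared against the sample-size-scaled critical value

    z* = 3 * sqrt(nbar / 120),   nbar = (n1 + n2) / 2,

so that with the guideline-minimum 120 subjects per group z* = 3, and the
bar rises with group size — a deliberately conservative rule that only
separates groups whose means differ by an amount that matters at
reference-interval resolution.  Groups whose analyte is non-Gaussian are
compared after a shared Box-Cox transform.

Adjacent classes failing the criterion are merged greedily left-to-right,
re-testing after every merge until the partition is a fixed point; the
same machinery then tests male vs female within each final age range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .preprocess import boxcox_transform, ks_normality
from .screening import SubjectRecord

__all__ = [
    "ZTestResult",
    "SexSplitResult",
    "MergeOutcome",
    "harris_boyd_z",
    "merge_adjacent",
    "sex_split_test",
]

AGE_LO = 1
AGE_HI = 18


@dataclass(frozen=True)
class ZTestResult:
    """One between-group comparison on the analysis scale."""

    z: float
    z_star: float
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    decision: str  # "separate" | "merge"
    degenerate: bool = False
    transform_lambda: float | None = None  # Box-Cox lambda when transformed


def harris_boyd_z(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
) -> ZTestResult:
    """Harris-Boyd decision from group summaries.

    ``decision`` is "separate" iff z > z*.  When both SDs are zero the
    statistic is degenerate: equal means merge, unequal means separate
    (an infinite standardized difference), both flagged.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    z_star = 3.0 * math.sqrt(((n1 + n2) / 2.0) / 120.0)
    if sd1 == 0.0 and sd2 == 0.0:
        if mean1 == mean2:
            return ZTestResult(0.0, z_star, n1, n2, mean1, mean2, sd1, sd2,
                               decision="merge", degenerate=True)
        return ZTestResult(math.inf, z_star, n1, n2, mean1, mean2, sd1, sd2,
                           decision="separate", degenerate=True)
    z = abs(mean1 - mean2) / math.sqrt(sd1 * sd1 / n1 + sd2 * sd2 / n2)
    decision = "separate" if z > z_star else "merge"
    return ZTestResult(float(z), float(z_star), n1, n2,
                       float(mean1), float(mean2), float(sd1), float(sd2),
                       decision=decision)


def _pair_z(values1: np.ndarray, values2: np.ndarray) -> ZTestResult:
    """Compare two samples, Box-Cox-transforming both (shared lambda) when
    the pooled sample fails the normality check and is strictly positive."""
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    pooled = np.concatenate([v1, v2])
    lam: float | None = None
    if pooled.size >= 5 and not ks_normality(pooled).is_gaussian and np.all(pooled > 0):
        transformed, lam = boxcox_transform(pooled)
        v1, v2 = transformed[: v1.size], transformed[v1.size :]
    result = harris_boyd_z(
        v1.size, float(np.mean(v1)), float(np.std(v1, ddof=1)),
        v2.size, float(np.mean(v2)), float(np.std(v2, ddof=1)),
    )
    if lam is not None:
        result = ZTestResult(**{**result.__dict__, "transform_lambda": lam})
    return result


def _range_values(
    records: Iterable[SubjectRecord], analyte: str, lo: int, hi: int,
    sex: str | None = None,
) -> np.ndarray:
    return np.asarray(
        [
            rec.analytes[analyte]
            for rec in records
            if lo <= rec.age_years < hi
            and analyte in rec.analytes
            and (sex is None or rec.sex == sex)
        ],
        dtype=float,
    )


@dataclass(frozen=True)
class MergeOutcome:
    """Final age ranges plus the trace of every pairwise test performed."""

    ranges: tuple[tuple[int, int], ...]
    tests: tuple[tuple[tuple[int, int], tuple[int, int], ZTestResult], ...]


def _check_tiling(partitions: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    parts = sorted((int(lo), int(hi)) for lo, hi in partitions)
    if not parts:
        raise ValueError("empty partition list")
    if parts[0][0] != AGE_LO or parts[-1][1] != AGE_HI:
        raise ValueError(f"partitions must tile [{AGE_LO}, {AGE_HI})")
    for (lo1, hi1), (lo2, hi2) in zip(parts, parts[1:]):
        if hi1 != lo2:
            raise ValueError(f"gap or overlap at age {hi1}")
        if lo1 >= hi1:
            raise ValueError(f"empty partition [{lo1}, {hi1})")
    if parts[-1][0] >= parts[-1][1]:
        raise ValueError("empty partition")
    return parts


def merge_adjacent(
    partitions: Sequence[tuple[int, int]],
    records: Sequence[SubjectRecord],
    analyte: str,
) -> MergeOutcome:
    """Collapse adjacent age ranges that the Z criterion cannot separate.

    Tests adjacent pairs left to right; whenever a pair merges, the merged
    range is re-tested against its new right neighbour, and passes repeat
    until a full sweep performs no merge.  The result is a fixed point:
    re-running it changes nothing.
    """
    parts = _check_tiling(partitions)
    trace: list[tuple[tuple[int, int], tuple[int, int], ZTestResult]] = []
    changed = True
    while changed:
        changed = False
        idx = 0
        while idx < len(parts) - 1:
            left, right = parts[idx], parts[idx + 1]
            v_left = _range_values(records, analyte, *left)
            v_right = _range_values(records, analyte, *right)
            if v_left.size == 0 or v_right.size == 0:
                raise ValueError(f"empty partition sample in {left} or {right}")
            result = _pair_z(v_left, v_right)
            trace.append((left, right, result))
            if result.decision == "merge":
                parts[idx : idx + 2] = [(left[0], right[1])]
                changed = True
                # stay at idx: re-test the merged range against the next
            else:
                idx += 1
    return MergeOutcome(ranges=tuple(parts), tests=tuple(trace))


@dataclass(frozen=True)
class SexSplitResult:
    age_lo: int
    age_hi: int
    ztest: ZTestResult
    sex_specific: bool


def sex_split_test(
    records: Sequence[SubjectRecord],
    age_ranges: Sequence[tuple[int, int]],
    analyte: str,
) -> list[SexSplitResult]:
    """Male-vs-female Harris-Boyd comparison inside each final age range.

    A range is flagged sex-specific when the decision is "separate"; both
    sexes must be present in every range.
    """
    out: list[SexSplitResult] = []
    for lo, hi in age_ranges:
        v_m = _range_values(records, analyte, lo, hi, sex="M")
        v_f = _range_values(records, analyte, lo, hi, sex="F")
        if v_m.size < 2 or v_f.size < 2:
            missing = "M" if v_m.size < 2 else "F"
            raise ValueError(f"sex {missing} absent (or n < 2) in range [{lo}, {hi})")
        result = _pair_z(v_m, v_f)
        out.append(
            SexSplitResult(
                age_lo=lo, age_hi=hi, ztest=result,
                sex_specific=result.decision == "separate",
            )
        )
    return out
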