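"""Nonparametric reference intervals with rank-based confidence intervals.

A reference interval is the central 95% range of an analyte in the healthy
reference population: the 2.5th percentile (lower limit, LL) to the 97.5th
percentile (upper limit, UL).  Limits are estimated nonparametrically at
rank p*(n+1) with linear interpolation between order statistics, and each
limit carries a 90% confidence interval whose bounds are observed order
statistics chosen by the binomial rank method (a seeded bootstrap stands in
when the rank CI runs off the edge of the sample).

Guideline practice requires at least 120 reference individuals per
partition; estimators below refuse smaller samples unless explicitly
overridden (useful in simulations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .preprocess import rank_quantile
from .screening import SubjectRecord

__all__ = [
    "ReferenceInterval",
    "MIN_REFERENCE_N",
    "nonparametric_ri",
    "quantile_rank_ci",
    "ri_confidence",
    "build_ri_table",
]

MIN_REFERENCE_N = 120
LOWER_P = 0.025
UPPER_P = 0.975
DEFAULT_CI_LEVEL = 0.90
BOOTSTRAP_RESAMPLES = 2000

#: tolerance for "the lower limit sits at the detection limit"
_CENSOR_EPS = 1e-9


@dataclass(frozen=True)
class ReferenceInterval:
    """One table row: analyte x age range x sex cell."""

    analyte: str
    age_lo: int
    age_hi: int
    sex: str  # "M" | "F" | "M+F"
    n: int
    ll: float
    ul: float
    ci_ll: tuple[float, float]
    ci_ul: tuple[float, float]
    censored: bool = False

    def __post_init__(self) -> None:
        if self.ll > self.ul:
            raise ValueError("lower limit exceeds upper limit")


def _guard(n: int, override: bool) -> None:
    if n < MIN_REFERENCE_N and not override:
        raise ValueError(
            f"partition has n={n} < {MIN_REFERENCE_N} reference individuals; "
            "each partition requires at least 120 (pass override to bypass)"
        )


def nonparametric_ri(
    values: Sequence[float] | np.ndarray, override: bool = False
) -> tuple[float, float]:
    """(LL, UL) = 2.5th/97.5th percentiles at ranks 0.025(n+1)/0.975(n+1)."""
    arr = np.sort(np.asarray(values, dtype=float))
    _guard(arr.size, override)
    return rank_quantile(arr, LOWER_P), rank_quantile(arr, UPPER_P)


def quantile_rank_ci(
    sorted_values: np.ndarray, p: float, level: float = DEFAULT_CI_LEVEL
) -> tuple[float, float] | None:
    """Distribution-free CI for the p-quantile from order statistics.

    Chooses ranks l <= u with each binomial tail at most (1-level)/2, so
    coverage P(X_(l) <= q_p <= X_(u)) = F(u-1) - F(l-1) >= level, with
    F = Binom(n, p) CDF.  Returns None when no such ranks exist inside the
    sample (the quantile sits too close to an edge for this n).
    """
    n = sorted_values.size
    alpha = 1.0 - level
    dist = stats.binom(n, p)
    # largest l in [1, n] with F(l-1) <= alpha/2
    l = int(dist.ppf(alpha / 2.0))  # F(l-1) <= alpha/2 < F(l) around here
    while l >= 1 and dist.cdf(l - 1) > alpha / 2.0:
        l -= 1
    while l + 1 <= n and dist.cdf(l) <= alpha / 2.0:
        l += 1
    # smallest u in [1, n] with 1 - F(u-1) <= alpha/2
    u = int(dist.ppf(1.0 - alpha / 2.0)) + 1
    while u > 1 and dist.sf(u - 2) <= alpha / 2.0:
        u -= 1
    while u <= n and dist.sf(u - 1) > alpha / 2.0:
        u += 1
    if l < 1 or u > n or l > u:
        return None
    return float(sorted_values[l - 1]), float(sorted_values[u - 1])


def _bootstrap_ci(
    arr: np.ndarray, p: float, level: float, seed: int
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = arr.size
    estimates = np.empty(BOOTSTRAP_RESAMPLES)
    for b in range(BOOTSTRAP_RESAMPLES):
        sample = np.sort(rng.choice(arr, size=n, replace=True))
        estimates[b] = rank_quantile(sample, p)
    alpha = 1.0 - level
    lo, hi = np.quantile(estimates, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def ri_confidence(
    values: Sequence[float] | np.ndarray,
    level: float = DEFAULT_CI_LEVEL,
    override: bool = False,
    seed: int = 0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """(CI for LL, CI for UL) at the given confidence level.

    Rank-based by default; falls back to a seeded bootstrap (2,000
    resamples) for a limit whose rank CI is undefined at the sample edge.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    _guard(arr.size, override)
    out: list[tuple[float, float]] = []
    for p in (LOWER_P, UPPER_P):
        ci = quantile_rank_ci(arr, p, level)
        if ci is None:
            ci = _bootstrap_ci(arr, p, level, seed)
        out.append(ci)
    return out[0], out[1]


def build_ri_table(
    records: Sequence[SubjectRecord],
    final_partitions: Mapping[str, Sequence[tuple[int, int, bool]]],
    detection_limits: Mapping[str, float] | None = None,
    level: float = DEFAULT_CI_LEVEL,
    override: bool = False,
    seed: int = 0,
) -> list[ReferenceInterval]:
    """One ReferenceInterval row per (analyte, age range, sex cell).

    ``final_partitions`` maps analyte -> list of (age_lo, age_hi,
    sex_specific); sex-specific ranges yield an M row and an F row,
    otherwise a pooled M+F row.  A row is flagged censored when its lower
    limit sits at the analyte's detection limit.  Any cell below the
    120-subject minimum raises, naming the cell.
    """
    detection_limits = detection_limits or {}
    table: list[ReferenceInterval] = []
    for analyte, ranges in final_partitions.items():
        limit = detection_limits.get(analyte)
        for age_lo, age_hi, sex_specific in ranges:
            cells = ("M", "F") if sex_specific else ("M+F",)
            for sex in cells:
                vals = np.asarray(
                    [
                        rec.analytes[analyte]
                        for rec in records
                        if age_lo <= rec.age_years < age_hi
                        and analyte in rec.analytes
                        and (sex == "M+F" or rec.sex == sex)
                    ],
                    dtype=float,
                )
                if vals.size < MIN_REFERENCE_N and not override:
                    raise ValueError(
                        f"cell {analyte} [{age_lo},{age_hi}) {sex}: n={vals.size} "
                        f"< {MIN_REFERENCE_N} reference individuals"
                    )
                ll, ul = nonparametric_ri(vals, override=True)
                ci_ll, ci_ul = ri_confidence(vals, level, override=True, seed=seed)
                censored = limit is not None and ll <= limit + _CENSOR_EPS
                table.append(
                    ReferenceInterval(
                        analyte=analyte, age_lo=age_lo, age_hi=age_hi, sex=sex,
                        n=int(vals.size), ll=float(ll), ul=float(ul),
                        ci_ll=ci_ll, ci_ul=ci_ul, censored=bool(censored),
                    )
                )
    return table
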