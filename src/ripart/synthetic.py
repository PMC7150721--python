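"""Seeded synthetic cohorts with known piecewise age structure.

The generator emulates the kind of cross-sectional pediatric cohort used in
reference-interval studies: for each analyte and sex, age 1-17 is tiled by
contiguous segments, and within a segment subject values are drawn from a
two-parameter family (normal or lognormal) whose exact 2.5th and 97.5th
percentiles are set to prescribed limits.  Because the generative truth is
the pair of reference limits itself, segmentation, class merging and
reference-interval estimation can all be tested by parameter recovery.

An optional per-analyte lower detection limit floors draws and flags them,
mimicking assays that cannot report below their analytical sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .screening import SubjectRecord

__all__ = [
    "SegmentSpec",
    "CohortSpec",
    "FamilyParams",
    "InvalidSpecError",
    "solve_family_params",
    "generate_cohort",
    "example_panel_spec",
    "EXAMPLE_PANEL_SEGMENTS",
    "cohort_spec_from_dict",
    "cohort_spec_to_dict",
    "load_cohort_spec",
]

AGE_LO = 1
AGE_HI = 18  # exclusive

#: two-sided central-95% standard-normal quantile, z_{0.975}
Z_975 = float(stats.norm.ppf(0.975))


class InvalidSpecError(ValueError):
    """Raised for cohort specifications that violate their invariants."""


@dataclass(frozen=True)
class SegmentSpec:
    """One age segment of an analyte's generative truth.

    Covers completed-years ages [age_lo, age_hi) with true 2.5th/97.5th
    percentiles ``p2_5``/``p97_5`` (analyte units).  ``drift`` shifts both
    quantiles linearly by that many units per year inside the segment,
    which produces gradual trends without changing the family shape.
    """

    age_lo: int
    age_hi: int
    p2_5: float
    p97_5: float
    family: str = "lognormal"
    drift: float = 0.0

    def __post_init__(self) -> None:
        if self.age_lo >= self.age_hi:
            raise InvalidSpecError(f"age_lo {self.age_lo} >= age_hi {self.age_hi}")
        if self.p2_5 >= self.p97_5:
            raise InvalidSpecError(f"p2_5 {self.p2_5} >= p97_5 {self.p97_5}")
        if self.family not in ("normal", "lognormal"):
            raise InvalidSpecError(f"unknown family {self.family!r}")
        if self.family == "lognormal" and self.p2_5 <= 0:
            raise InvalidSpecError("lognormal quantiles must be positive")

    def quantiles_at(self, age: int) -> tuple[float, float]:
        """Effective (p2_5, p97_5) at an age bin, including drift."""
        shift = self.drift * (age - self.age_lo)
        return self.p2_5 + shift, self.p97_5 + shift


@dataclass(frozen=True)
class FamilyParams:
    """Location/scale of a fitted family.

    For ``normal``: mean and SD.  For ``lognormal``: mean and SD of log(x).
    """

    family: str
    loc: float
    scale: float

    def quantile(self, p: float) -> float:
        z = float(stats.norm.ppf(p))
        if self.family == "normal":
            return self.loc + self.scale * z
        return float(np.exp(self.loc + self.scale * z))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        draws = rng.standard_normal(n) * self.scale + self.loc
        if self.family == "lognormal":
            return np.exp(draws)
        return draws


def solve_family_params(p2_5: float, p97_5: float, family: str) -> FamilyParams:
    """Location/scale parameters whose exact central-95% limits match.

    Both supported families are monotone transforms of a normal, so the
    match is closed-form: the (possibly log-scale) location is the midpoint
    of the (log-)quantiles and the scale is half their spread divided by
    z_{0.975}.  Round-trips through ``FamilyParams.quantile`` to ~1e-16.
    """
    if family not in ("normal", "lognormal"):
        raise InvalidSpecError(f"unknown family {family!r}")
    if p2_5 >= p97_5:
        raise InvalidSpecError(f"p2_5 {p2_5} must be < p97_5 {p97_5}")
    if family == "lognormal":
        if p2_5 <= 0:
            raise InvalidSpecError("lognormal quantiles must be positive")
        lo, hi = np.log(p2_5), np.log(p97_5)
    else:
        lo, hi = p2_5, p97_5
    loc = (lo + hi) / 2.0
    scale = (hi - lo) / (2.0 * Z_975)
    return FamilyParams(family=family, loc=float(loc), scale=float(scale))


SegmentTable = Mapping[str, Mapping[str, Sequence[SegmentSpec]]]


@dataclass(frozen=True)
class CohortSpec:
    """Full generative description of a synthetic cohort.

    ``segments`` maps analyte -> sex ('M'/'F') -> ordered SegmentSpec list
    tiling ages [1, 18).  ``n_per_age_sex`` subjects are generated in every
    (age bin, sex) cell when ``sex_ratio`` is 0.5; other ratios rebalance
    the two cells of each age bin while keeping their total at
    2*n_per_age_sex.  ``detection_limit`` optionally floors an analyte.
    """

    analytes: tuple[str, ...]
    segments: SegmentTable
    n_per_age_sex: int = 200
    sex_ratio: float = 0.5
    detection_limit: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_age_sex < 1:
            raise InvalidSpecError("n_per_age_sex must be >= 1")
        if not (0.0 < self.sex_ratio < 1.0):
            raise InvalidSpecError("sex_ratio must be in (0, 1)")
        for analyte in self.analytes:
            if analyte not in self.segments:
                raise InvalidSpecError(f"no segments for analyte {analyte!r}")
            for sex in ("M", "F"):
                if sex not in self.segments[analyte]:
                    raise InvalidSpecError(f"no segments for {analyte!r} sex {sex}")
                _check_tiling(self.segments[analyte][sex], analyte, sex)

    def cell_count(self, sex: str) -> int:
        """Subjects per (age bin, sex) cell after applying the sex ratio."""
        total = 2 * self.n_per_age_sex
        n_m = int(round(total * self.sex_ratio))
        n_m = min(max(n_m, 1), total - 1)
        return n_m if sex == "M" else total - n_m

    def segment_for(self, analyte: str, sex: str, age: int) -> SegmentSpec:
        for seg in self.segments[analyte][sex]:
            if seg.age_lo <= age < seg.age_hi:
                return seg
        raise InvalidSpecError(f"no segment covers age {age} for {analyte}/{sex}")


def _check_tiling(segs: Sequence[SegmentSpec], analyte: str, sex: str) -> None:
    segs = sorted(segs, key=lambda s: s.age_lo)
    if not segs:
        raise InvalidSpecError(f"{analyte}/{sex}: empty segment list")
    if segs[0].age_lo != AGE_LO or segs[-1].age_hi != AGE_HI:
        raise InvalidSpecError(
            f"{analyte}/{sex}: segments must cover [{AGE_LO}, {AGE_HI})"
        )
    for prev, cur in zip(segs, segs[1:]):
        if prev.age_hi != cur.age_lo:
            raise InvalidSpecError(
                f"{analyte}/{sex}: gap or overlap at age {prev.age_hi}"
            )


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> list[SubjectRecord]:
    """Draw a full cohort; deterministic given (spec, seed).

    Iterates age bins ascending, then sexes (M before F), drawing every
    analyte for the whole cell at once from a single seeded generator, so
    identical inputs give byte-identical cohorts.  Values below an
    analyte's detection limit are floored to it and flagged.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    sid = 0
    for age in range(AGE_LO, AGE_HI):
        for sex in ("M", "F"):
            n_cell = spec.cell_count(sex)
            draws: dict[str, np.ndarray] = {}
            floored: dict[str, np.ndarray] = {}
            for analyte in spec.analytes:
                seg = spec.segment_for(analyte, sex, age)
                q_lo, q_hi = seg.quantiles_at(age)
                params = solve_family_params(q_lo, q_hi, seg.family)
                values = params.sample(rng, n_cell)
                limit = spec.detection_limit.get(analyte)
                if limit is not None:
                    below = values < limit
                    values = np.where(below, limit, values)
                    floored[analyte] = below
                else:
                    floored[analyte] = np.zeros(n_cell, dtype=bool)
                draws[analyte] = values
            for i in range(n_cell):
                sid += 1
                flags = frozenset(
                    a for a in spec.analytes if floored[a][i]
                )
                records.append(
                    SubjectRecord(
                        subject_id=f"S{sid:06d}",
                        age_years=age,
                        sex=sex,
                        analytes={a: float(draws[a][i]) for a in spec.analytes},
                        detection_flags=flags,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Bundled example: a four-enzyme pediatric myocardial panel
# ---------------------------------------------------------------------------

def _seg(lo: int, hi: int, p_lo: float, p_hi: float) -> SegmentSpec:
    return SegmentSpec(age_lo=lo, age_hi=hi, p2_5=p_lo, p97_5=p_hi, family="lognormal")


#: Generative truth for the bundled example panel: age-segmented central-95%
#: limits (U/L) for four serum enzymes in a healthy 1-<18-year population,
#: patterned on published pediatric myocardial-enzyme reference data.  AST
#: and LDH decline with age; CK is age-stable; CKMB is sex-divergent from
#: age 6 with a 2.7 U/L lower detection limit.  Enzyme activities are
#: right-skewed and positive, so every segment uses the lognormal family.
EXAMPLE_PANEL_SEGMENTS: dict[str, dict[str, list[SegmentSpec]]] = {
    "AST": {
        "M": [_seg(1, 2, 29.1, 57.2), _seg(2, 10, 20.1, 40.7), _seg(10, 18, 15.7, 33.8)],
        "F": [_seg(1, 2, 29.1, 57.2), _seg(2, 10, 20.1, 40.7), _seg(10, 18, 14.0, 27.7)],
    },
    "LDH": {
        "M": [_seg(1, 4, 461.0, 761.0), _seg(4, 12, 397.0, 674.0), _seg(12, 18, 339.0, 624.0)],
        "F": [_seg(1, 4, 461.0, 761.0), _seg(4, 12, 397.0, 674.0), _seg(12, 18, 316.0, 555.0)],
    },
    "CK": {
        "M": [_seg(1, 18, 40.2, 179.0)],
        "F": [_seg(1, 18, 40.2, 179.0)],
    },
    "CKMB": {
        "M": [_seg(1, 6, 11.7, 39.1), _seg(6, 14, 8.9, 34.2), _seg(14, 18, 2.5, 26.3)],
        "F": [_seg(1, 6, 11.7, 39.1), _seg(6, 14, 4.5, 30.2), _seg(14, 18, 2.7, 15.1)],
    },
}


def example_panel_spec(n_per_age_sex: int = 200, seed: int = 0) -> CohortSpec:
    """CohortSpec for the bundled four-enzyme example panel."""
    return CohortSpec(
        analytes=("AST", "LDH", "CK", "CKMB"),
        segments=EXAMPLE_PANEL_SEGMENTS,
        n_per_age_sex=n_per_age_sex,
        detection_limit={"CKMB": 2.7},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------

def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "analytes": list(spec.analytes),
        "n_per_age_sex": spec.n_per_age_sex,
        "sex_ratio": spec.sex_ratio,
        "detection_limit": dict(spec.detection_limit),
        "seed": spec.seed,
        "segments": {
            analyte: {
                sex: [
                    {
                        "age_lo": s.age_lo,
                        "age_hi": s.age_hi,
                        "p2_5": s.p2_5,
                        "p97_5": s.p97_5,
                        "family": s.family,
                        "drift": s.drift,
                    }
                    for s in segs
                ]
                for sex, segs in by_sex.items()
            }
            for analyte, by_sex in spec.segments.items()
        },
    }


def cohort_spec_from_dict(data: Mapping) -> CohortSpec:
    segments = {
        analyte: {
            sex: [SegmentSpec(**seg) for seg in segs]
            for sex, segs in by_sex.items()
        }
        for analyte, by_sex in data["segments"].items()
    }
    return CohortSpec(
        analytes=tuple(data["analytes"]),
        segments=segments,
        n_per_age_sex=int(data.get("n_per_age_sex", 200)),
        sex_ratio=float(data.get("sex_ratio", 0.5)),
        detection_limit=dict(data.get("detection_limit", {})),
        seed=int(data.get("seed", 0)),
    )


def load_cohort_spec(path) -> CohortSpec:
    """Load a CohortSpec from a YAML or JSON config file."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return cohort_spec_from_dict(data)
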