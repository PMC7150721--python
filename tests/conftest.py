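from __future__ import annotations

import numpy as np
import pytest

from ripart.synthetic import (
    EXAMPLE_PANEL_SEGMENTS,
    CohortSpec,
    SegmentSpec,
    example_panel_spec,
    generate_cohort,
)


def single_analyte_spec(analyte: str, n_per_age_sex: int = 200) -> CohortSpec:
    """Cohort spec carrying just one enzyme of the bundled example panel."""
    return CohortSpec(
        analytes=(analyte,),
        segments={analyte: EXAMPLE_PANEL_SEGMENTS[analyte]},
        n_per_age_sex=n_per_age_sex,
        detection_limit={"CKMB": 2.7} if analyte == "CKMB" else {},
    )


def flat_spec(
    analyte: str = "CK",
    p2_5: float = 40.2,
    p97_5: float = 179.0,
    n_per_age_sex: int = 200,
) -> CohortSpec:
    """Age-homogeneous cohort: one lognormal segment covering all ages."""
    seg = [SegmentSpec(age_lo=1, age_hi=18, p2_5=p2_5, p97_5=p97_5)]
    return CohortSpec(
        analytes=(analyte,),
        segments={analyte: {"M": seg, "F": seg}},
        n_per_age_sex=n_per_age_sex,
    )


@pytest.fixture(scope="session")
def panel_spec():
    return example_panel_spec(n_per_age_sex=200)


@pytest.fixture(scope="session")
def panel_cohort(panel_spec):
    """One seeded draw of the full four-enzyme example cohort (6,800 subjects)."""
    return generate_cohort(panel_spec, seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
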