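"""Shared fixtures: small synthetic slides and the whole-slide testing cohort."""

from __future__ import annotations

import numpy as np
import pytest

from slnpatch.synthetic import (
    LOCAL_STYLE,
    COHORT_TUMOR_FRACTIONS,
    SlideSpec,
    generate_cohort,
    generate_slide,
)


@pytest.fixture(scope="session")
def small_slide():
    """One 900 px positive slide with fibrosis, for patch/inference tests."""
    spec = SlideSpec(
        width_px=900,
        height_px=900,
        domain=LOCAL_STYLE,
        seed=11,
        tumor_fraction=0.18,
        fibrosis_fraction=0.06,
    )
    return generate_slide(spec)


@pytest.fixture(scope="session")
def negative_slide():
    spec = SlideSpec(width_px=900, height_px=900, domain=LOCAL_STYLE, seed=12)
    return generate_slide(spec)


@pytest.fixture(scope="session")
def study_cohort():
    """The whole-slide testing cohort: five positives at the study's tumor
    burdens (0.03% .. 29.41%) on slides large enough that every lesion is
    resolvable at patch scale."""
    base = SlideSpec(width_px=2700, height_px=2700, domain=LOCAL_STYLE, seed=0)
    return generate_cohort(COHORT_TUMOR_FRACTIONS, [LOCAL_STYLE], base, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
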