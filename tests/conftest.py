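import numpy as np
import pytest

from adiposcan.config import LabelModelConfig, Profile
from adiposcan.synthgen import PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def tiny_profile() -> Profile:
    return Profile()


@pytest.fixture(scope="session")
def base_spec() -> PhantomSpec:
    return PhantomSpec(
        sex=1,
        age=50.0,
        bmi=28.0,
        insulin_sensitivity=10.0,
        hba1c_pct=5.5,
        fasting_glucose=5.2,
        glucose_2h=6.1,
        depot_fractions={
            "subcutaneous": 0.3,
            "visceral_upper": 0.3,
            "visceral_lower": 0.3,
            "thigh": 0.35,
            "arm": 0.3,
            "neck": 0.25,
            "breast": 0.5,
        },
        slice_count=104,
        seed=7,
    )


@pytest.fixture(scope="session")
def base_phantom(base_spec, tiny_profile):
    return generate_phantom(base_spec, tiny_profile)


@pytest.fixture(scope="session")
def small_cohort(tiny_profile):
    """30-subject cohort shared by read-only tests."""
    return generate_cohort(30, LabelModelConfig(), seed=42, profile=tiny_profile)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
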