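import pytest
from hypothesis import HealthCheck, settings

from rfcohort.cohort import default_calibration, generate_cohort, zero_dispersion
from rfcohort.dosimetry import AntennaSpec

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

# the study's antenna: 0.0891 W at the input, ~7 dB gain, 2.4 GHz carrier
STUDY_ANTENNA = AntennaSpec(power_input_w=0.0891, gain_db=7.0, frequency_ghz=2.4)


@pytest.fixture(scope="session")
def antenna():
    return STUDY_ANTENNA


@pytest.fixture(scope="session")
def juvenile_control_spec():
    return default_calibration("juvenile", "control")


@pytest.fixture(scope="session")
def juvenile_control_cohort(juvenile_control_spec):
    return generate_cohort(juvenile_control_spec, seed=12345)


@pytest.fixture(scope="session")
def zero_disp_cohorts():
    """Degenerate-noise cohorts for every (age group, arm)."""
    out = {}
    for age in ("juvenile", "adult", "presenile"):
        for arm in ("exposed", "control"):
            spec = zero_dispersion(default_calibration(age, arm))
            out[(age, arm)] = generate_cohort(spec, seed=0)
    return out
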