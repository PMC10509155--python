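import pytest
from hypothesis import HealthCheck, settings

import lianahydro as lh
from lianahydro.synthetic_data import Counts, StudyConfig, generate_study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMALL_COUNTS = Counts(
    individuals_min=5, individuals_max=6, stems=4, branches=2,
    vessels_per_branch=30, manometers=3,
)


@pytest.fixture(scope="session")
def ref_bundle():
    """Reference-design bundle with reduced per-unit effort (fast)."""
    return generate_study(StudyConfig(seed=11, counts=SMALL_COUNTS))


@pytest.fixture(scope="session")
def ref_traits(ref_bundle):
    return lh.report.run_traits(ref_bundle)


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Zero-dispersion bundle: every unit sits exactly on its site target."""
    return generate_study(StudyConfig(seed=3, counts=SMALL_COUNTS).zero_noise())
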