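import pytest
from hypothesis import HealthCheck, settings

from clozanc import SimParams, emit_cohort, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-subject synthetic cohort under default study-like conditions."""
    return simulate_cohort(SimParams(n_subjects=400, seed=7))


@pytest.fixture(scope="session")
def cohort_files(tmp_path_factory, small_cohort):
    """The small cohort emitted to disk (VCF + phenotype + local-ancestry TSV)."""
    out = tmp_path_factory.mktemp("cohort")
    return emit_cohort(small_cohort, out)
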