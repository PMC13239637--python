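import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fearcon import scr_scoring, scr_synth
from fearcon.paradigm import build_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design_a():
    return build_experiment("A", seed=7)


@pytest.fixture(scope="session")
def design_b():
    return build_experiment("B", seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """6 + 6 participants at default generator settings."""
    return scr_synth.simulate_cohort(6, 6, scr_synth.SCRGenParams(), seed=3)


@pytest.fixture(scope="session")
def small_cohort_scores(small_cohort):
    return scr_scoring.score_cohort(small_cohort)


@pytest.fixture(scope="session")
def default_cohort_scores():
    """The study-sized cohort: 18 sham / 22 verum, default settings."""
    members = scr_synth.simulate_cohort(18, 22, scr_synth.SCRGenParams(), seed=11)
    return members, scr_scoring.score_cohort(members)
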