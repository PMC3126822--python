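import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_experiment():
    """A tiny two-particle, two-condition experiment for I/O and CLI tests."""
    from mucotrack import Trajectory, TrackingExperiment

    times = np.arange(5) * 0.1
    t1 = Trajectory("S1", "control", "P1", times, np.linspace(0, 1, 5), np.zeros(5))
    t2 = Trajectory("S1", "treated", "P2", times, np.zeros(5), np.linspace(0, 2, 5))
    return TrackingExperiment([t1, t2])


@pytest.fixture(scope="session")
def default_study():
    """One study-scale paired synthetic ensemble, shared across tests (expensive)."""
    from mucotrack import StudyDesign, generate_study

    experiment, truth = generate_study(StudyDesign(seed=20260928), return_truth=True)
    return experiment, truth


@pytest.fixture(scope="session")
def default_study_analysis(default_study):
    from mucotrack import analyze_experiment

    experiment, truth = default_study
    summary, ensembles = analyze_experiment(experiment)
    return summary, ensembles
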