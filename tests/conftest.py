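import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bayesdca as b

# deterministic property tests: same examples every run
settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ferret() -> b.CaseBundle:
    return b.ferret_case()


@pytest.fixture(scope="session")
def ferret_belief(ferret) -> b.BeliefState:
    """Composite pre-surgical belief: priors + five-finding conditionals."""
    return ferret.belief("pre-surgical")


@pytest.fixture()
def tiny_belief() -> b.BeliefState:
    """Two diagnoses at 50/50 with one 80/20 finding: posteriors are 80/20."""
    return b.BeliefState(
        b.DifferentialSet(["disease A", "disease B"]),
        b.FindingSet(["sign"]),
        np.array([50.0, 50.0]),
        np.array([[80.0], [20.0]]),
    )


def make_belief(priors, conditionals, findings=None) -> b.BeliefState:
    """Small helper: belief from plain lists, auto-labelled."""
    priors = np.asarray(priors, dtype=float)
    conditionals = np.asarray(conditionals, dtype=float)
    dx = b.DifferentialSet([f"dx{i}" for i in range(len(priors))])
    fs = b.FindingSet(findings or [f"f{j}" for j in range(conditionals.shape[1])])
    return b.BeliefState(dx, fs, priors, conditionals)
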