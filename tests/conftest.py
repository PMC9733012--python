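import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gohidi as g

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def final_framework():
    return g.load_final_framework()


@pytest.fixture(scope="session")
def initial_framework():
    return g.load_initial_framework()


@pytest.fixture(scope="session")
def revision_log():
    return g.load_packaged_revision_log()


def consistent_matrix(weights, group="1", indicators=None):
    """Reciprocal matrix r_ie = w_i / w_e — perfectly consistent by design."""
    w = np.asarray(weights, dtype=float)
    if indicators is None:
        indicators = [f"{group}.{k}" for k in range(1, len(w) + 1)]
    return g.JudgmentMatrix(
        group_code=group,
        indicators=list(indicators),
        values=np.outer(w, 1.0 / w),
        scale="reciprocal",
        expert_id="oracle",
    )
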