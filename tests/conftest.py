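import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small generic 3-clone cohort with truth, shared across tests."""
    from clonaltrace import synthetic_tumor as st

    truth = st.simulate_clone_tree(3, 45, seed=11, edge_sizes=[15, 15, 15])
    st.simulate_clone_fractions(truth, 6, concentration=2.0, seed=12)
    matrix = st.simulate_read_counts(truth, depth_mean=200.0, seed=13)
    return truth, matrix


@pytest.fixture(scope="session")
def preset_cohort():
    """The emulated 11-sample rapid-autopsy cohort (292 mutations)."""
    from clonaltrace import synthetic_tumor as st

    return st.simulate_figure3c_cohort(seed=5, depth_mean=231.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20190801 % (2**31))
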