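import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_phantom():
    """One modest phantom with puncta on both sides of the vessel wall."""
    from perivesiq.cli import default_phantom_spec
    from perivesiq.simulate import make_vessel_phantom

    spec = default_phantom_spec(seed=7, n_puncta=12)
    return make_vessel_phantom(spec)


@pytest.fixture(scope="session")
def lfq_with_signature():
    """LFQ matrix with ten clearly up-shifted proteins in the SAD group.

    The planted fold (2.5x) sits safely above the 2x volcano boundary so
    that recovery is well defined under sampling noise.
    """
    from perivesiq.simulate import LFQSpec, make_lfq_matrix

    planted = tuple((i, "SAD", 2.5) for i in range(10))
    spec = LFQSpec(n_proteins=200, fold_changes=planted, noise_log_sd=0.05, seed=3)
    return make_lfq_matrix(spec)
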