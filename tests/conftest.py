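import os

os.environ.setdefault("MPLBACKEND", "Agg")

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lvadsim import default_params, run_to_steady_state
from lvadsim.scenarios import run_bai_sweep, run_mode_comparison


@pytest.fixture(scope="session")
def params():
    """Shipped calibrated parameter set."""
    return default_params()


@pytest.fixture(scope="session")
def healthy_sol(params):
    """Converged healthy baseline (no pump)."""
    return run_to_steady_state(params.without_pump())


@pytest.fixture(scope="session")
def hf_sol(params, healthy_sol):
    """Converged unassisted heart-failure cycle (peak calcium 0.54 μM)."""
    return run_to_steady_state(
        params.with_ca_max(0.54).without_pump(), y0=healthy_sol.y_final
    )


@pytest.fixture(scope="session")
def bai_sweep_table(params):
    """Support-level sweep over the standard 20–90 % grid."""
    return run_bai_sweep(
        [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9], base_params=params
    )


@pytest.fixture(scope="session")
def mode_drug_table(params):
    """Three support modes at 98 mmHg MAP, paired with β-blocker runs."""
    return run_mode_comparison(98.0, with_drug=True, base_params=params)
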