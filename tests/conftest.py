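import numpy as np
import pytest

from collidersim import GridConfig, Scenario, default_params, run_grid
from collidersim.experiment import summaries_to_frame


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def params_major():
    return default_params(-6.0)


@pytest.fixture
def small_scenario():
    return Scenario(n_total=10, gamma1=-1.0, attrition_q=0.10)


@pytest.fixture(scope="session")
def full_grid():
    """One default 27-scenario x 10,000-replication run, shared across tests.

    Returns (summaries, summary frame, per-replication records).
    """
    summaries, records = run_grid(GridConfig(root_seed=0), return_records=True)
    return summaries, summaries_to_frame(summaries), records


def grid_cell(frame, n_total, severity, attrition_pct):
    rows = frame[
        (frame.n_total == n_total)
        & (frame.severity == severity)
        & (frame.attrition_pct == attrition_pct)
    ]
    assert len(rows) == 1
    return rows.iloc[0]
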