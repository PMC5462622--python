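import numpy as np
import pytest

from somatotune.travelwave import TaskDesign, build_reference_model, default_lag_grid


@pytest.fixture(scope="session")
def paper_design() -> TaskDesign:
    """8 s blocks, digits 2-5 (32 s cycle), 8 cycles, TR 1.5 s."""
    return TaskDesign(tr=1.5, block_s=8.0, n_cycles=8)


@pytest.fixture(scope="session")
def lag_grid(paper_design):
    return default_lag_grid(paper_design)


@pytest.fixture(scope="session")
def model_bank(paper_design, lag_grid):
    """Precomputed reference regressors, one per lag (amortized across tests)."""
    return np.stack([build_reference_model(paper_design, lag) for lag in lag_grid])
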