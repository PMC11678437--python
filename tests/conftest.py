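import numpy as np
import pandas as pd
import pytest

from malnutburden import colombia
from malnutburden.markov import CohortTrace, StateSpace, simulate


@pytest.fixture(scope="session")
def col_model():
    """(space, matrix, alloc, n_cycles) of the bundled Colombia fixture."""
    return colombia.model()


@pytest.fixture(scope="session")
def col_trace(col_model):
    space, matrix, alloc, n_cycles = col_model
    return simulate(alloc, matrix, space, n_cycles)


@pytest.fixture(scope="session")
def burden_target():
    """Published per-cycle YLL/YLD/DALY cells (no Total row)."""
    df = colombia.burden_table()
    return df[df["cycle"].astype(str) != "Total"].astype({"cycle": int})


@pytest.fixture(scope="session")
def cost_target():
    """Published per-cycle direct/indirect cost cells (no Total row)."""
    df = colombia.cost_table()
    return df[df["cycle"].astype(str) != "Total"].astype({"cycle": int})


@pytest.fixture
def tiny_trace():
    """Hand-built two-cycle trace: 1000 alive, 100 die each cycle, 200 disabled."""
    space = StateSpace(names=("healthy", "disabled", "death"), absorbing=frozenset({"death"}))
    occupancy = np.array(
        [
            [1000.0, 0.0, 0.0],
            [700.0, 200.0, 100.0],
            [500.0, 300.0, 200.0],
        ]
    )
    flows = np.zeros((2, 3, 3))
    return CohortTrace(space, occupancy, flows)
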