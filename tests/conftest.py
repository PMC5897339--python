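import numpy as np
import pandas as pd
import pytest

from netexpr import (
    ExpressionMatrix,
    SimulationConfig,
    ValueScale,
    make_expression,
)


@pytest.fixture(scope="session")
def small_config():
    """Reduced synthetic study used by unit tests (fast, seeded)."""
    return SimulationConfig(
        n_genes=300,
        n_donors=4,
        networks=[("limbic", 2, 2), ("somato_motor", 2, 2), ("visual", 2, 2)],
        striatal_networks=[("limbic", 2, 2), ("somato_motor", 2, 2)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return make_expression(small_config)


@pytest.fixture
def toy_matrix():
    """4 samples x 3 genes, log2 scale, two donors in each compartment."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 3.0],
            "s2": [3.0, 2.0, 1.0],
            "s3": [10.0, 20.0, 30.0],
            "s4": [20.0, 10.0, 0.0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(values, ValueScale.LOG2)


@pytest.fixture
def toy_manifest():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "donor_id": ["d1", "d2", "d1", "d2"],
            "compartment": ["cortex", "cortex", "striatum", "striatum"],
            "mni_x": [0.0, 1.0, 2.0, 3.0],
            "mni_y": [0.0, 0.0, 0.0, 0.0],
            "mni_z": [0.0, 0.0, 0.0, 0.0],
        }
    )
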