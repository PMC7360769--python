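import numpy as np
import pytest

from ancombc.data_model import AbundanceTable, GroupDesign
from ancombc.synthetic_data import SimulationConfig, generate


@pytest.fixture
def tiny_table() -> AbundanceTable:
    counts = np.array([
        [10, 12, 8, 20, 18],
        [5, 0, 7, 9, 11],
        [0, 0, 0, 3, 4],
    ])
    return AbundanceTable(counts, ["OTU1", "OTU2", "OTU3"],
                          ["s1", "s2", "s3", "s4", "s5"])


@pytest.fixture
def tiny_design() -> GroupDesign:
    return GroupDesign({"s1": "A", "s2": "A", "s3": "A",
                        "s4": "B", "s5": "B"})


@pytest.fixture(scope="session")
def large_dataset():
    """One dataset from the default large-variability benchmark preset."""
    cfg = SimulationConfig(m=300, n=(20, 30), prop_da=0.1,
                           scenario="large", seed=7)
    return generate(cfg)
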