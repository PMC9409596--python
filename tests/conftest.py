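import logging

import numpy as np
import pandas as pd
import pytest

from fdsweep import CommunityMatrix, TraitTable

# the metrics log every undefined value; keep test output readable
logging.getLogger("fdsweep").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_traits():
    """Three species, two continuous traits and one categorical; sp3 lacks T2."""
    rows = [
        ("sp1", "T1", 2.0, "continuous"),
        ("sp2", "T1", 7.0, "continuous"),
        ("sp3", "T1", 5.0, "continuous"),
        ("sp1", "T2", 0.1, "continuous"),
        ("sp2", "T2", 0.9, "continuous"),
        ("sp1", "pathway", "C3", "categorical"),
        ("sp2", "pathway", "C4", "categorical"),
        ("sp3", "pathway", "C4", "categorical"),
    ]
    return TraitTable(
        pd.DataFrame(rows, columns=["species", "trait", "value", "kind"])
    )


@pytest.fixture
def toy_community():
    """One plot covering sp1/sp2/sp3 at 50/30/20."""
    return CommunityMatrix(
        pd.DataFrame(
            {
                "plot": ["plotA"] * 3,
                "study": ["demo"] * 3,
                "species": ["sp1", "sp2", "sp3"],
                "abundance": [50.0, 30.0, 20.0],
            }
        )
    )


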