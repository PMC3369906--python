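import numpy as np
import pandas as pd
import pytest

from painscreen.dspi import PhenotypeIndex, build_index


def make_index(n: int, ratios=None) -> PhenotypeIndex:
    """Index over n diseases with strictly increasing ratios unless given."""
    if ratios is None:
        ratios = np.linspace(0.01, 0.99, n)
    records = pd.DataFrame(
        {
            "disease_id": [f"D{i:03d}" for i in range(n)],
            "disease_name": [f"disease {i}" for i in range(n)],
            "n_total": 1000,
            "n_phenotype": np.round(np.asarray(ratios) * 1000).astype(int),
        }
    )
    return build_index(records)


@pytest.fixture
def index20() -> PhenotypeIndex:
    return make_index(20)


@pytest.fixture
def index40() -> PhenotypeIndex:
    return make_index(40)
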