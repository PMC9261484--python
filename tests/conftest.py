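import numpy as np
import pandas as pd
import pytest

from trophicniche.data_model import Dataset
from trophicniche.fixtures import load_fixture
from trophicniche.diet_metrics import iri_table


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_diet")


@pytest.fixture(scope="session")
def table2_iri(table2):
    """IRI table recomputed from the pooled %FO/%N/%W columns."""
    return iri_table(table2[["taxon", "pctFO", "pctN", "pctW"]])


@pytest.fixture(scope="session")
def taxonomy_table(table2):
    return table2[["taxon", "category", "habitat_origin"]].rename(
        columns={"taxon": "taxon_name"}
    )


@pytest.fixture
def toy_dataset():
    """Five fish in two estuaries, one with an empty gut."""
    fish = pd.DataFrame(
        {
            "fish_id": ["f1", "f2", "f3", "f4", "f5"],
            "estuary": ["Alpha", "Alpha", "Alpha", "Beta", "Beta"],
            "station": ["lower", "middle", "upper", "lower", "upper"],
            "season": ["winter", "spring", "summer", "autumn", "winter"],
            "total_length": [400.0, 450.0, 500.0, 380.0, 410.0],
            "gut_empty": [False, False, True, False, False],
        }
    )
    taxonomy = pd.DataFrame(
        {
            "taxon_name": ["gammarid", "crab", "goby"],
            "category": ["Malacostraca", "Malacostraca", "Actinopterygii"],
            "habitat_origin": ["MB", "M", "MBF"],
        }
    )
    prey = pd.DataFrame(
        {
            "fish_id": ["f1", "f1", "f2", "f4", "f4", "f5"],
            "taxon_name": ["gammarid", "crab", "gammarid", "goby", "gammarid", "goby"],
            "count": [3, 1, 5, 2, 1, 4],
            "weight": [0.3, 2.0, 0.5, 6.0, 0.1, 11.0],
        }
    )
    isotopes = pd.DataFrame(
        {
            "fish_id": ["f1", "f2", "f3", "f4", "f5"],
            "delta13C": [-24.0, -23.5, -25.0, -19.0, -18.5],
            "delta15N": [15.0, 15.5, 14.8, 13.0, 13.5],
            "cn_ratio": [3.2, 3.5, 4.5, 3.1, 3.3],
        }
    )
    baselines = pd.DataFrame(
        {
            "estuary": ["Alpha", "Alpha", "Beta"],
            "station": ["lower", "middle", "lower"],
            "season": ["winter", "spring", "autumn"],
            "delta15N_base": [8.2, 8.0, 7.0],
            "tp_base": [1.0, 1.0, 1.0],
        }
    )
    return Dataset(fish=fish, prey=prey, taxonomy=taxonomy,
                   isotopes=isotopes, baselines=baselines)


@pytest.fixture
def rng():
    # function-scoped so every test sees the same, order-independent stream
    return np.random.default_rng(20260919)
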