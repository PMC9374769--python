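import io

import numpy as np
import pandas as pd
import pytest

from spatsig.io import QuadratRecords, pool_quadrats
from spatsig.synthetic import SyntheticConfig, generate_dataset

TOY_CSV = """wetland_id,quadrat_id,species_id,biomass
w1,q1,spA,2.0
w1,q2,spA,3.0
w1,q2,spB,1.0
w2,q1,spC,4.0
w2,q2,spC,1.5
"""


@pytest.fixture
def toy_records():
    return QuadratRecords(pd.read_csv(io.StringIO(TOY_CSV)))


@pytest.fixture
def toy_pooled(toy_records):
    return pool_quadrats(toy_records)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic metacommunity shared across tests."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_records(rng, n_sites=4, n_species=6, n_quadrats=3):
    rows = []
    for i in range(n_sites):
        for q in range(n_quadrats):
            for s in range(n_species):
                if rng.random() < 0.5:
                    rows.append((f"w{i}", f"q{q}", f"sp{s}",
                                 float(rng.lognormal())))
    if not rows:
        rows.append(("w0", "q0", "sp0", 1.0))
    return QuadratRecords(pd.DataFrame(
        rows, columns=["wetland_id", "quadrat_id", "species_id", "biomass"]))
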