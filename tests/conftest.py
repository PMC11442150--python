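import logging

import numpy as np
import pytest

import drugresc as dr

# drop the warning chatter from intentionally degenerate fixtures
logging.getLogger("drugresc").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def worked_example():
    """3 genes x 2 cells with a hand-evaluable ranking (a > c > b in cell c1)."""
    return dr.make_worked_example()


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared by model-level tests."""
    config = dr.SimConfig(
        n_genes=400,
        n_cells=120,
        program_size=40,
        effect_size=3.0,
        n_positive_drugs=1,
        n_negative_drugs=7,
        seed=7,
    )
    return dr.simulate(config)


@pytest.fixture(scope="session")
def small_model(small_dataset):
    data = small_dataset
    sigs = [dr.build_signature(p) for p in data.profiles]
    return dr.DrugReSC(data.expression, data.labels, sigs)


def random_ranking(rng, n):
    genes = [f"g{j:03d}" for j in range(n)]
    values = rng.normal(0, 3, n)
    return dr.rank_cell(genes, values), genes
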