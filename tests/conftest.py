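import numpy as np
import pandas as pd
import pytest

from seedpheno.io import PhenotypeTable


@pytest.fixture
def tiny_table() -> PhenotypeTable:
    """2 genotypes x 2 blocks x 1 trait."""
    return PhenotypeTable(
        pd.DataFrame(
            {
                "genotype": ["G1", "G1", "G2", "G2"],
                "block": ["B1", "B2", "B1", "B2"],
                "trait": ["area"] * 4,
                "value": [1.0, 1.2, 2.0, 2.1],
            }
        )
    )


@pytest.fixture
def hand_rcbd() -> PhenotypeTable:
    """3 genotypes x 2 blocks, values chosen to leave a nonzero residual."""
    rows = []
    values = {("G1", "B1"): 1.0, ("G1", "B2"): 2.0,
              ("G2", "B1"): 3.0, ("G2", "B2"): 5.0,
              ("G3", "B1"): 6.0, ("G3", "B2"): 4.0}
    for (g, b), v in values.items():
        rows.append({"genotype": g, "block": b, "trait": "y", "value": v})
    return PhenotypeTable(pd.DataFrame(rows))


def random_rcbd(g: int, r: int, seed: int, trait: str = "y") -> PhenotypeTable:
    rng = np.random.default_rng(seed)
    y = rng.normal(10.0, 2.0, size=(g, r))
    rows = [
        {"genotype": f"G{i}", "block": f"B{j}", "trait": trait, "value": y[i, j]}
        for i in range(g)
        for j in range(r)
    ]
    return PhenotypeTable(pd.DataFrame(rows))
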