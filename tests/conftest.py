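import numpy as np
import pytest

import topreg as tg


SMILES_POOL = [
    # benzene-scaffold series
    "c1ccccc1CCO",
    "c1ccccc1CCN",
    "c1ccccc1C(=O)O",
    "c1ccccc1CC(=O)N",
    # pyridine series
    "c1ccncc1CC",
    "c1ccncc1CCO",
    "c1ccncc1C(=O)O",
    # cyclohexane series
    "C1CCCCC1O",
    "C1CCCCC1N",
    "C1CCCCC1CC",
    # acyclic (empty Murcko scaffold)
    "CCO",
    "CCCCO",
]


@pytest.fixture
def smiles_dataset(tmp_path):
    """Small real-chemistry dataset spanning three ring scaffolds."""
    import pandas as pd

    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        {
            "id": [f"m{i}" for i in range(len(SMILES_POOL))],
            "smiles": SMILES_POOL,
            "activity": np.round(rng.uniform(4, 9, len(SMILES_POOL)), 2),
        }
    )
    path = tmp_path / "activity.csv"
    df.to_csv(path, index=False)
    return tg.read_activity_table(path)


@pytest.fixture(scope="session")
def landscape():
    """One deterministic cliff landscape plus derived matrices."""
    ds, truth = tg.simulate_landscape(tg.LandscapeSpec(seed=11))
    sim = tg.pairwise_similarity_matrix(ds).values
    dist = tg.design_distances(1.0 - sim, 2)
    return {"ds": ds, "truth": truth, "sim": sim, "dist": dist, "y": ds.activities()}


def random_bitsets(rng, n, nbits=64, density=0.2):
    out = []
    for _ in range(n):
        out.append(frozenset(int(b) for b in np.flatnonzero(rng.random(nbits) < density)))
    return out
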