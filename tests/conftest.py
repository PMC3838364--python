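import numpy as np
import pandas as pd
import pytest

from comindic import DistanceMatrix, TraitTable


@pytest.fixture
def mixed_trait_table() -> TraitTable:
    """Four species, one binary + one quantitative trait spanning 0-10."""
    df = pd.DataFrame(
        {
            "armor": [1, 0, 0, 1],
            "length": [5.0, 10.0, 0.0, 10.0],
        },
        index=pd.Index(["A", "B", "C", "D"], name="species"),
    )
    return TraitTable(df, {"armor": "binary", "length": "quantitative"})


@pytest.fixture
def three_taxon_matrix() -> DistanceMatrix:
    """d(A,B)=2, d(A,C)=d(B,C)=6: merges at heights 1 and 3 under UPGMA."""
    return DistanceMatrix(
        ["A", "B", "C"], np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0.0]])
    )


def random_mixed_table(rng: np.random.Generator, n_species: int, n_traits: int,
                       missingness: float = 0.15) -> TraitTable:
    """Small random mixed-type table for oracle comparisons."""
    kinds_pool = ["quantitative", "ordinal", "nominal", "binary"]
    ids = [f"s{i}" for i in range(n_species)]
    cols, kinds = {}, {}
    for j in range(n_traits):
        kind = kinds_pool[int(rng.integers(len(kinds_pool)))]
        name = f"t{j}"
        kinds[name] = kind
        if kind == "quantitative":
            vals = rng.normal(size=n_species)
        elif kind == "ordinal":
            vals = rng.integers(1, 5, n_species).astype(float)
        elif kind == "nominal":
            vals = rng.choice(list("abc"), n_species)
        else:
            vals = rng.choice([0, 1], n_species)
        cols[name] = vals
    df = pd.DataFrame(cols, index=pd.Index(ids, name="species"), dtype=object)
    mask = rng.random(df.shape) < missingness
    # keep every column partly observed and every row pair comparable on t0
    mask[:, 0] = False
    df = df.mask(mask)
    for name, kind in kinds.items():
        if kind in ("quantitative", "ordinal"):
            df[name] = pd.to_numeric(df[name])
    return TraitTable(df, kinds)
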