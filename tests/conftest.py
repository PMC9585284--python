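import numpy as np
import pandas as pd
import pytest

from fdnull.community import CommunityMatrix
from fdnull.synthetic import generate_species_pool
from fdnull.traits import TraitDefinition, TraitTable, vineyard_trait_schema


@pytest.fixture
def toy_cm() -> CommunityMatrix:
    """3 plots x 4 species with simple integer covers."""
    ab = pd.DataFrame(
        [[30.0, 10.0, 0.0, 5.0], [0.0, 20.0, 5.0, 0.0], [10.0, 0.0, 15.0, 5.0]],
        index=["plot1", "plot2", "plot3"],
        columns=["spA", "spB", "spC", "spD"],
    )
    return CommunityMatrix(ab)


@pytest.fixture
def mini_schema() -> dict:
    """Three-trait schema: two quantitative, one nominal."""
    full = vineyard_trait_schema()
    return {k: full[k] for k in ("PHV", "SLA", "DS")}


@pytest.fixture
def mini_traits(mini_schema) -> TraitTable:
    data = pd.DataFrame(
        {
            "PHV": [10.0, 30.0, 20.0, 15.0],
            "SLA": [20.0, 20.0, 40.0, 30.0],
            "DS": ["unspecialized", "anemochorous", "zoochorous", "unspecialized"],
        },
        index=["spA", "spB", "spC", "spD"],
    )
    return TraitTable(data, mini_schema)


@pytest.fixture(scope="session")
def pool20():
    """A 20-species pool with the full ten-trait schema, drawn once."""
    return generate_species_pool(s_pool=20, seed=11)


def one_trait_table(values, name="PHV") -> TraitTable:
    """A pool carrying a single quantitative trait (1-D trait space)."""
    schema = {name: TraitDefinition(name, "quantitative", "cm")}
    data = pd.DataFrame({name: list(map(float, values))},
                        index=[f"s{i}" for i in range(len(values))])
    return TraitTable(data, schema)


def reference_gower(data: pd.DataFrame, schema) -> np.ndarray:
    """Loop-based Gower oracle, independent of the vectorized implementation."""
    n = len(data)
    out = np.zeros((n, n))
    names = list(data.columns)
    for a in range(n):
        for b in range(n):
            acc = 0.0
            for name in names:
                d = schema[name]
                va, vb = data[name].iloc[a], data[name].iloc[b]
                if d.kind == "quantitative":
                    rng = data[name].max() - data[name].min()
                    acc += 0.0 if rng == 0 else abs(va - vb) / rng
                elif d.kind == "ordinal":
                    acc += abs(d.levels.index(va) - d.levels.index(vb)) / (
                        len(d.levels) - 1
                    )
                else:
                    acc += float(va != vb)
            out[a, b] = acc / len(names)
    return out
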