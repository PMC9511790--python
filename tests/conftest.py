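import numpy as np
import pandas as pd
import pytest

from embryokit import simulate
from embryokit.io import CountMatrix, FeatureSet, MethCallSet


@pytest.fixture(scope="session")
def small_atlas():
    """Compact labelled reference atlas shared across mapping/DE tests."""
    spec = simulate.AtlasSpec(
        n_cell_types=3,
        n_genes=200,
        n_markers_per_type=12,
        stages=("E8.5",),
        n_embryos_per_stage=4,
        n_cells_per_embryo=250,
        seed=11,
    )
    counts, ann, embryos = simulate.simulate_atlas(spec)
    return spec, counts, ann, embryos


@pytest.fixture(scope="session")
def enhancer_features():
    return simulate.make_enhancer_catalogue(n_per_class=10)


@pytest.fixture
def tiny_counts():
    values = np.array([[1, 0, 2, 0], [0, 3, 0, 0], [4, 0, 0, 5]])
    return CountMatrix(values, ["c1", "c2", "c3"], ["g1", "g2", "g3", "g4"])


def make_calls(records, context="CpG", cell_id="cellA"):
    df = pd.DataFrame(records, columns=["chrom", "pos", "meth", "unmeth"])
    return MethCallSet(context=context, cell_id=cell_id, records=df)


@pytest.fixture
def meth_calls_factory():
    return make_calls
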