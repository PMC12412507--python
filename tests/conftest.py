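import numpy as np
import pytest

from graphdec.io_data import (CellTypeAnnotation, ProportionMatrix,
                              ProteinMatrix, REFERENCE, TARGET)
from graphdec.synthetic import SyntheticSpec, make_benchmark_pair


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cells(rng):
    """60 labeled cells, 3 types x 20 cells, 8 proteins."""
    types = ["A", "B", "C"]
    mu = rng.uniform(0.5, 3.0, size=(3, 8))
    values = np.vstack([
        mu[k] * rng.lognormal(0, 0.1, size=(20, 8)) for k in range(3)
    ])
    ids = [f"c{i}" for i in range(60)]
    labels = [types[i // 20] for i in range(60)]
    pm = ProteinMatrix(values, ids, [f"p{j}" for j in range(8)], REFERENCE)
    ann = CellTypeAnnotation(ids, labels, types)
    return pm, ann


@pytest.fixture
def tiny_matrix():
    return ProteinMatrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
                         ["s1", "s2", "s3"], ["f1", "f2"], REFERENCE)


@pytest.fixture
def valid_props():
    return ProportionMatrix([[0.25, 0.75], [0.5, 0.5]],
                            ["s1", "s2"], ["A", "B"])


@pytest.fixture(scope="session")
def mini_benchmark():
    """Small but non-trivial reference/target benchmark pair."""
    spec = SyntheticSpec(seed=7, cells_per_type_per_batch=120)
    return make_benchmark_pair(spec, n_ref_samples=160, n_tgt_samples=60,
                               cells_per_sample=25)
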