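import numpy as np
import pytest

from seedcoexp import ExpressionMatrix
from seedcoexp.synthetic_data import ModuleSpec, SyntheticSpec

STAGES7 = tuple(f"{2 + 4 * i}DAF" for i in range(7))


@pytest.fixture
def stages7():
    return STAGES7


@pytest.fixture
def small_matrix():
    """3 genes x 7 stages, hand-written values."""
    values = np.array([
        [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
        [10.0, 9.0, 8.0, 7.0, 6.0, 5.0, 4.0],
        [2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
    ])
    return ExpressionMatrix(["g1", "g2", "g3"], STAGES7, values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, n_genes=100, n_stages=7, scale=50.0):
    """Random positive FPKM-like matrix."""
    values = scale * rng.lognormal(0.0, 1.0, size=(n_genes, n_stages))
    return ExpressionMatrix([f"g{i:04d}" for i in range(n_genes)],
                            [f"{2 + 4 * j}DAF" for j in range(n_stages)],
                            values)


@pytest.fixture
def guide_spec():
    """Three 31-gene modules (one guide + 30 partners each), 500 smooth
    background genes, TF labels on 30% of genes."""
    return SyntheticSpec(
        modules=(ModuleSpec("mid", "mid_peak", 31),
                 ModuleSpec("early", "early_declining", 31),
                 ModuleSpec("late", "late_rising", 31)),
        n_background=500, tf_fraction=0.3,
        guides=(("mid", 1), ("early", 1), ("late", 1)),
        seed=7)
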