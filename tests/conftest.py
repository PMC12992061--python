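import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import synmac as sm

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small 4-group simulation with one planted DE effect, shared across
    tests that only read from it."""
    cfg = sm.SimConfig(
        n_genes=400,
        n_cells_per_group=300,
        marker_genes_per_subpop=8,
        de_effects=[sm.DEEffect(gene=150, group="old_F", log2fc=1.5, subpop="CD163+")],
        seed=42,
    )
    cm, cells, truth = sm.simulate_counts(cfg)
    return cfg, cm, cells, truth


@pytest.fixture(scope="session")
def small_norm(small_sim):
    _cfg, cm, cells, _truth = small_sim
    cm_f, cells_f, _ = sm.apply_qc(cm, cells)
    return cm_f, sm.lognormalize(cm_f), cells_f


@pytest.fixture(scope="session")
def small_embedding(small_norm):
    _cm, norm, cells = small_norm
    hvg = sm.select_hvg(norm, n=300)
    return sm.compute_pca(norm, hvg, n_pcs=20), cells


def toy_cells(labels_a, labels_b, group_a="A", group_b="B"):
    """Build a minimal cell table from two subpopulation-label lists."""
    n_a, n_b = len(labels_a), len(labels_b)
    return pd.DataFrame(
        {
            "group": [group_a] * n_a + [group_b] * n_b,
            "subpopulation": list(labels_a) + list(labels_b),
        },
        index=pd.Index([f"c{i}" for i in range(n_a + n_b)], name="barcode"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
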