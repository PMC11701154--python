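import numpy as np
import pytest

from mlagnn.graph import CoexpressionGraph, build_graph
from mlagnn.integrate import SplitSpec, cartesian_integrate, split_train_test
from mlagnn.model import MLAGNNConfig, train
from mlagnn.omics import FeaturePanel
from mlagnn.preprocess import preprocess_layer
from mlagnn.simulate import SimConfig, generate_paired_cohort


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(
        n_genes=60, n_tumor_expr=15, n_normal_expr=15,
        n_tumor_meth=15, n_normal_meth=15, n_planted=8,
        n_modules=2, module_size=15, seed=7,
    )
    return generate_paired_cohort(cfg)


@pytest.fixture(scope="session")
def integrated(small_cohort):
    expr, meth, _ = small_cohort
    _, enorm = preprocess_layer(expr)
    _, mnorm = preprocess_layer(meth)
    panel = FeaturePanel(gene_ids=sorted(enorm.gene_ids))
    ds = cartesian_integrate(enorm, mnorm, panel)
    train_ds, test_ds = split_train_test(ds, SplitSpec(seed=3))
    return ds, train_ds, test_ds


@pytest.fixture(scope="session")
def small_graph(integrated):
    _, train_ds, _ = integrated
    return build_graph(train_ds.features, train_ds.gene_ids, alpha=6.0, adj_thresh=0.5)


@pytest.fixture(scope="session")
def small_model_config():
    return MLAGNNConfig(gat_hidden_dim=4, projection_dim=4, epochs=8, seed=11)


@pytest.fixture(scope="session")
def trained_small(integrated, small_graph, small_model_config):
    _, train_ds, _ = integrated
    params, trace = train(train_ds, small_graph, small_model_config)
    return params, trace


@pytest.fixture
def path_graph3():
    """3-node path graph with self-loops: 0-1-2."""
    A = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=np.int8)
    return CoexpressionGraph(
        gene_ids=["g0", "g1", "g2"], C=np.eye(3), alpha=1.0, adj_thresh=0.5, A=A
    )
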