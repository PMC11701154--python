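import numpy as np
import pytest

from mlagnn.graph import CoexpressionGraph
from mlagnn.model import (
    MLAGNNConfig,
    fgs_saliency,
    forward,
    init_params,
    predict_proba,
    train,
)

CFG = MLAGNNConfig(gat_hidden_dim=4, projection_dim=3, seed=0)


def _graph(A):
    A = np.asarray(A, dtype=np.int8)
    n = len(A)
    return CoexpressionGraph(
        gene_ids=[f"g{i}" for i in range(n)], C=np.eye(n), alpha=1.0,
        adj_thresh=0.5, A=A,
    )


class TestGATLayer:
    def test_single_node_attention_is_one(self):
        g = _graph([[1]])
        x = np.random.default_rng(0).random((2, 1, 2))
        _, levels = forward(x, g, init_params(CFG, 1), CFG)
        for att in levels.attention:
            np.testing.assert_allclose(att, 1.0)

    def test_identical_nodes_get_uniform_attention(self):
        g = _graph([[1, 1], [1, 1]])
        x = np.tile(np.array([0.3, 0.9]), (1, 2, 1))  # both nodes identical
        _, levels = forward(x, g, init_params(CFG, 2), CFG)
        np.testing.assert_allclose(levels.attention[0], 0.5, atol=1e-12)

    def test_attention_rows_sum_to_one(self, small_graph, integrated):
        _, train_ds, _ = integrated
        cfg = MLAGNNConfig(gat_hidden_dim=3, projection_dim=2,
                           attention_heads=2, seed=1)
        params = init_params(cfg, len(small_graph.gene_ids))
        _, levels = forward(train_ds.features[:16], small_graph, params, cfg)
        assert len(levels.attention) == 4  # 2 layers x 2 heads
        for att in levels.attention:
            np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-6)

    def test_path_graph_matches_per_edge_oracle(self, path_graph3):
        """Brute-force attention computation over the 3-node path graph."""
        cfg = MLAGNNConfig(gat_hidden_dim=2, projection_dim=2, seed=3,
                           leaky_slope=0.2)
        params = init_params(cfg, 3)
        x = np.random.default_rng(5).random((1, 3, 2))
        _, levels = forward(x, path_graph3, params, cfg)

        W = params["gat1_h0_W"]
        a_src = params["gat1_h0_asrc"][:, 0]
        a_dst = params["gat1_h0_adst"][:, 0]
        b = params["gat1_b"]
        H = x[0] @ W
        A = path_graph3.A
        out = np.zeros_like(H)
        att_oracle = np.zeros((3, 3))
        for i in range(3):
            nbrs = [j for j in range(3) if A[i, j]]
            e = []
            for j in nbrs:
                raw = a_src @ H[i] + a_dst @ H[j]
                e.append(raw if raw > 0 else 0.2 * raw)
            e = np.array(e)
            w = np.exp(e - e.max())
            w /= w.sum()
            for wj, j in zip(w, nbrs):
                att_oracle[i, j] = wj
                out[i] += wj * H[j]
        out = out + b
        out = np.where(out > 0, out, np.expm1(out))  # ELU
        np.testing.assert_allclose(levels.attention[0][0], att_oracle, atol=1e-10)
        np.testing.assert_allclose(levels.G2.data[0], out, atol=1e-10)

    def test_missing_self_loop_rejected(self):
        g = _graph([[0, 1], [1, 0]])
        x = np.zeros((1, 2, 2))
        with pytest.raises(ValueError, match="self-loops"):
            forward(x, g, init_params(CFG, 2), CFG)


class TestForward:
    def test_zero_head_gives_even_probabilities(self, path_graph3):
        params = init_params(CFG, 3)
        params["head_W"][:] = 0.0
        params["head_b"][:] = 0.0
        x = np.random.default_rng(1).random((4, 3, 2))
        logits, _ = forward(x, path_graph3, params, CFG)
        np.testing.assert_allclose(logits.data, 0.0)
        np.testing.assert_allclose(
            predict_proba(x, path_graph3, params, CFG), 0.5
        )

    def test_g1_is_input_bit_exact(self, path_graph3):
        x = np.random.default_rng(2).random((3, 3, 2))
        _, levels = forward(x, path_graph3, init_params(CFG, 3), CFG)
        assert levels.G1.data.tobytes() == x.tobytes()

    def test_consistent_permutation_leaves_logits_unchanged(self):
        rng = np.random.default_rng(8)
        n = 5
        A = (rng.random((n, n)) > 0.5).astype(np.int8)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 1)
        g = _graph(A)
        x = rng.random((2, n, 2))
        cfg = MLAGNNConfig(gat_hidden_dim=3, projection_dim=2, seed=4)
        params = init_params(cfg, n)
        logits, _ = forward(x, g, params, cfg)

        perm = rng.permutation(n)
        g_p = _graph(A[np.ix_(perm, perm)])
        params_p = {k: v.copy() for k, v in params.items()}
        # permute the head weights' node blocks to match the permuted order
        d_in, p = cfg.in_channels, cfg.projection_dim
        blocks = np.split(np.arange(n * d_in), n)
        f1_idx = np.concatenate([blocks[i] for i in perm])
        blocks_p = np.split(np.arange(n * p), n)
        fp_idx = np.concatenate([blocks_p[i] for i in perm])
        W = params["head_W"]
        params_p["head_W"] = np.concatenate([
            W[: n * d_in][f1_idx],
            W[n * d_in : n * (d_in + p)][fp_idx],
            W[n * (d_in + p) :][fp_idx],
        ])
        logits_p, _ = forward(x[:, perm], g_p, params_p, cfg)
        np.testing.assert_allclose(logits_p.data, logits.data, atol=1e-8)

    def test_shape_mismatch_names_level(self, path_graph3):
        with pytest.raises(ValueError, match="G1"):
            forward(np.zeros((1, 4, 2)), path_graph3, init_params(CFG, 3), CFG)


def _separable_dataset(n_per_class=25, n_genes=6, seed=0):
    from mlagnn.integrate import IntegratedDataset
    import pandas as pd

    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.3, 0.05, (n_per_class, n_genes, 2))
    x1 = rng.normal(0.7, 0.05, (n_per_class, n_genes, 2))
    feats = np.clip(np.concatenate([x1, x0]), 0, 1)
    labels = np.array(["tumor"] * n_per_class + ["normal"] * n_per_class)
    prov = pd.DataFrame(
        {"expr_sample_id": [f"e{i}" for i in range(2 * n_per_class)],
         "meth_sample_id": [f"m{i}" for i in range(2 * n_per_class)]}
    )
    return IntegratedDataset(
        features=feats, labels=labels, provenance=prov,
        gene_ids=[f"g{i}" for i in range(n_genes)],
    )


class TestTrain:
    def test_loss_decreases_on_separable_data(self):
        ds = _separable_dataset()
        g = _graph(np.eye(6, dtype=np.int8))
        cfg = MLAGNNConfig(gat_hidden_dim=3, projection_dim=2, epochs=30,
                           batch_size=16, seed=2)
        _, trace = train(ds, g, cfg)
        assert trace[-1] < trace[0]

    def test_same_seed_identical_loss_trace(self, integrated, small_graph):
        _, train_ds, _ = integrated
        cfg = MLAGNNConfig(gat_hidden_dim=2, projection_dim=2, epochs=3, seed=9)
        _, t1 = train(train_ds, small_graph, cfg)
        _, t2 = train(train_ds, small_graph, cfg)
        assert t1 == t2

    def test_empty_training_set_rejected(self, small_graph, integrated):
        ds, _, _ = integrated
        with pytest.raises(ValueError, match="empty"):
            train(ds.subset(np.array([], dtype=int)), small_graph, MLAGNNConfig())


class TestSaliency:
    def test_linear_head_on_f1_matches_closed_form(self, path_graph3):
        """With a head reading only F1, per-gene FGS is |sum_c W[n,c] x[n,c]|
        averaged over samples — the model's attention path carries no
        gradient into F1."""
        cfg = MLAGNNConfig(gat_hidden_dim=2, projection_dim=2, seed=6)
        params = init_params(cfg, 3)
        params["head_W"][:] = 0.0
        rng = np.random.default_rng(7)
        W1 = rng.standard_normal((3, 2))  # per-gene, per-channel weight
        params["head_W"][: 3 * 2, 1] = W1.ravel()
        x = rng.random((10, 3, 2))
        rep = fgs_saliency(params, path_graph3, x, cfg, top_k=3)
        # predicted class is 1 whenever its logit > 0, else 0 (score 0)
        logit1 = (x * W1).sum(axis=(1, 2))
        contrib = np.where(logit1[:, None] > 0, (x * W1).sum(axis=2), 0.0)
        expected = np.abs(contrib).mean(axis=0)
        np.testing.assert_allclose(rep.scores["score_F1"], expected, atol=1e-10)

    def test_zero_input_gene_scores_zero_at_f1(self, path_graph3):
        cfg = MLAGNNConfig(gat_hidden_dim=2, projection_dim=2, seed=1)
        params = init_params(cfg, 3)
        x = np.random.default_rng(3).random((5, 3, 2))
        x[:, 1, :] = 0.0
        rep = fgs_saliency(params, path_graph3, x, cfg, top_k=3)
        assert rep.scores["score_F1"].iloc[1] == 0.0

    def test_randomizing_head_changes_fused_ranking(
        self, integrated, small_graph, trained_small, small_model_config
    ):
        _, _, test_ds = integrated
        params, _ = trained_small
        rep = fgs_saliency(params, small_graph, test_ds.features,
                           small_model_config)
        rng = np.random.default_rng(123)
        scrambled = {k: v.copy() for k, v in params.items()}
        scrambled["head_W"] = rng.standard_normal(params["head_W"].shape)
        rep2 = fgs_saliency(scrambled, small_graph, test_ds.features,
                            small_model_config)
        assert rep.top["F"] != rep2.top["F"]

    def test_rankings_deterministic(self, integrated, small_graph,
                                    trained_small, small_model_config):
        _, _, test_ds = integrated
        params, _ = trained_small
        a = fgs_saliency(params, small_graph, test_ds.features, small_model_config)
        b = fgs_saliency(params, small_graph, test_ds.features, small_model_config)
        assert a.top == b.top
        assert (a.scores == b.scores).all().all()

    def test_nan_params_rejected(self, path_graph3):
        cfg = MLAGNNConfig(gat_hidden_dim=2, projection_dim=2)
        params = init_params(cfg, 3)
        params["proj2_W"][0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fgs_saliency(params, path_graph3, np.ones((1, 3, 2)), cfg, top_k=2)

    def test_top_k_bounded_by_gene_count(self, path_graph3):
        cfg = MLAGNNConfig(gat_hidden_dim=2, projection_dim=2)
        with pytest.raises(ValueError, match="top_k"):
            fgs_saliency(init_params(cfg, 3), path_graph3, np.ones((1, 3, 2)),
                         cfg, top_k=5)


def test_trained_model_separates_planted_cohort(integrated, small_graph,
                                                trained_small,
                                                small_model_config):
    from mlagnn.evaluate import compute_metrics

    _, _, test_ds = integrated
    params, trace = trained_small
    assert trace[-1] < trace[0]
    prob = predict_proba(test_ds.features, small_graph, params,
                         small_model_config)
    assert compute_metrics(prob, test_ds.y).auroc >= 0.9
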