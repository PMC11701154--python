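import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlagnn.graph import (
    binarize,
    build_graph,
    pick_soft_power,
    scale_free_fit,
    signed_adjacency,
    training_observations,
    tune_adj_thresh,
)
from mlagnn.integrate import SplitSpec, split_train_test
from mlagnn.model import MLAGNNConfig


def _brute_pearson_power(obs, alpha):
    """Independent oracle: per-pair Pearson from the definition, then power."""
    n = obs.shape[0]
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = obs[i], obs[j]
            num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
            den = np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
            r = num / den
            C[i, j] = C[j, i] = ((1 + r) / 2) ** alpha
    return C


class TestSignedAdjacency:
    def test_perfectly_correlated_pair_weight_one(self):
        x = np.arange(10.0)
        obs = np.vstack([x, 2 * x + 3])
        for alpha in (1, 4, 9):
            assert signed_adjacency(obs, alpha)[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pair_weight_zero(self):
        x = np.arange(10.0)
        obs = np.vstack([x, -x])
        assert signed_adjacency(obs, 3)[0, 1] == pytest.approx(0.0)

    def test_uncorrelated_pair_at_alpha_two(self):
        obs = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        assert signed_adjacency(obs, 2)[0, 1] == pytest.approx(0.25)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        obs = rng.standard_normal((10, 30))
        for alpha in (1.0, 6.0):
            C = signed_adjacency(obs, alpha)
            assert np.abs(C - _brute_pearson_power(obs, alpha)).max() < 1e-10

    def test_constant_gene_becomes_edgeless(self):
        obs = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="constant"):
            C = signed_adjacency(obs, 2)
        assert C[0, 1] == pytest.approx(0.25)  # r treated as 0
        assert C[0, 0] == 1.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="3 observations"):
            signed_adjacency(np.ones((4, 2)), 2)

    def test_monotone_decreasing_in_alpha_below_perfect_correlation(self):
        rng = np.random.default_rng(1)
        obs = rng.standard_normal((6, 40))
        prev = signed_adjacency(obs, 1)
        for alpha in (2, 4, 8):
            cur = signed_adjacency(obs, alpha)
            off = ~np.eye(6, dtype=bool)
            assert (cur[off] <= prev[off] + 1e-12).all()
            prev = cur


class TestBinarize:
    def test_strict_threshold(self):
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert binarize(C, 0.5)[0, 1] == 1
        C[0, 1] = C[1, 0] = 0.5
        assert binarize(C, 0.5)[0, 1] == 0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        C = rng.random((10, 10))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        A = binarize(C, 0.4)
        for i in range(10):
            for j in range(10):
                expected = 1 if (i == j or C[i, j] > 0.4) else 0
                assert A[i, j] == expected

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_edge_count_monotone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(9)
        C = rng.random((12, 12))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        lo, hi = sorted((t1, t2))
        assert binarize(C, hi).sum() <= binarize(C, lo).sum()

    def test_self_loops_kept_even_when_empty(self):
        C = np.eye(3)
        with pytest.warns(UserWarning, match="self-loops"):
            A = binarize(C, 0.9)
        assert (np.diag(A) == 1).all()


class TestPickSoftPower:
    def test_r2_matches_regression_oracle(self):
        rng = np.random.default_rng(12)
        obs = rng.standard_normal((5, 50))
        obs[1] = obs[0] * 0.9 + 0.1 * obs[1]  # some structure
        C = signed_adjacency(obs, 2)
        got = scale_free_fit(C, n_bins=10)

        # independent oracle: same binning definition, lstsq regression
        k = C.sum(axis=1) - np.diag(C)
        edges = np.linspace(k.min(), k.max(), 11)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        xs, ys = [], []
        for b in range(10):
            mem = k[idx == b]
            if len(mem) and mem.mean() > 0:
                xs.append(np.log10(mem.mean()))
                ys.append(np.log10(len(mem) / len(k)))
        X = np.column_stack([xs, np.ones(len(xs))])
        beta, res, *_ = np.linalg.lstsq(X, np.array(ys), rcond=None)
        y = np.array(ys)
        r2 = 1 - ((y - X @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        expected = -np.sign(beta[0]) * r2
        assert got == pytest.approx(expected, abs=1e-10)

    def test_no_candidate_reaching_target_warns_and_returns_best(self):
        rng = np.random.default_rng(0)
        obs = rng.standard_normal((30, 40))
        with pytest.warns(UserWarning, match="best fit"):
            alpha, trace = pick_soft_power(obs, candidate_powers=(1, 2, 3, 4, 5))
        finite = {p: r for p, r in trace.items() if np.isfinite(r)}
        assert alpha == max(finite, key=finite.get)

    def test_degenerate_connectivity_falls_back(self):
        obs = np.tile(np.arange(5.0), (8, 1))  # all rows identical: r=1
        with pytest.warns(UserWarning, match="degenerate|falling back"):
            alpha, _ = pick_soft_power(obs)
        assert alpha == 6.0

    def test_deterministic_on_planted_modules(self, integrated):
        _, train_ds, _ = integrated
        obs = training_observations(train_ds.features)
        a1, t1 = pick_soft_power(obs)
        a2, t2 = pick_soft_power(obs)
        assert a1 == a2 and t1 == t2

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            pick_soft_power(np.random.default_rng(0).standard_normal((4, 10)), ())


class TestTuneAdjThresh:
    @pytest.fixture(scope="class")
    def split_small(self, integrated):
        _, train_ds, _ = integrated
        return split_train_test(train_ds, SplitSpec(train_fraction=0.75, seed=2))

    def test_single_candidate_returned_unchanged(self, split_small):
        tr, val = split_small
        cfg = MLAGNNConfig(gat_hidden_dim=2, projection_dim=2, epochs=2, seed=0)
        best, scores = tune_adj_thresh(tr, val, (0.5,), alpha=6.0, model_config=cfg)
        assert best == 0.5 and set(scores) == {0.5}

    def test_deterministic_and_argmax(self, split_small):
        tr, val = split_small
        cfg = MLAGNNConfig(gat_hidden_dim=2, projection_dim=2, epochs=2, seed=0)
        b1, s1 = tune_adj_thresh(tr, val, (0.3, 0.7), alpha=6.0, model_config=cfg)
        b2, s2 = tune_adj_thresh(tr, val, (0.3, 0.7), alpha=6.0, model_config=cfg)
        assert b1 == b2 and s1 == s2
        assert s1[b1] >= min(s1.values())

    def test_out_of_range_candidate_rejected(self, split_small):
        tr, val = split_small
        with pytest.raises(ValueError, match="not in"):
            tune_adj_thresh(tr, val, (1.5,), alpha=6.0)


def test_graph_built_from_training_features_only(integrated):
    _, train_ds, test_ds = integrated
    g_train = build_graph(train_ds.features, train_ds.gene_ids, alpha=6.0)
    g_test = build_graph(test_ds.features, test_ds.gene_ids, alpha=6.0)
    assert g_train.training_fingerprint != g_test.training_fingerprint


def test_training_observations_stacks_channels():
    feats = np.arange(24.0).reshape(2, 3, 4)  # wrong channel count on purpose
    obs = training_observations(feats)
    assert obs.shape == (3, 8)
    # gene 0: pair 0 channels then pair 1 channels
    np.testing.assert_array_equal(obs[0], [0, 1, 2, 3, 12, 13, 14, 15])
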