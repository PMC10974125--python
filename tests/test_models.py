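"""Attention identities, position embeddings, estimator contracts, training
convergence and the R² reporting convention."""

import numpy as np
import pytest

from mmgmotion import (
    EvalReport,
    SupervisedDataset,
    TransformerConfig,
    TransformerEstimator,
    ValidationError,
    evaluate,
    make_estimator,
    position_embedding,
    r2_score,
    train_estimator,
)
from mmgmotion.nn import MultiHeadSelfAttention, scaled_dot_attention


class TestScaledDotAttention:
    def test_single_position_returns_v(self):
        out, w = scaled_dot_attention(
            np.array([[3.7, -2.0]]), np.array([[0.4, 9.9]]), np.array([[5.0, 6.0]])
        )
        np.testing.assert_allclose(out, [[5.0, 6.0]])
        np.testing.assert_allclose(w, [[1.0]])

    def test_identical_keys_average_v(self):
        K = np.tile([1.0, 2.0], (4, 1))
        V = np.arange(8.0).reshape(4, 2)
        out, w = scaled_dot_attention(np.array([[0.3, -1.2]]), K, V)
        np.testing.assert_allclose(out[0], V.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(w, 0.25, atol=1e-12)

    def test_hand_evaluated_two_key_case(self):
        Q = np.array([[1.0, 0.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        out, w = scaled_dot_attention(Q, K, V)
        # softmax(1/sqrt(2), 0): 1/(1 + e^(-0.70711)) = 0.669762
        np.testing.assert_allclose(w[0], [0.669762, 0.330238], atol=1e-5)
        np.testing.assert_allclose(out[0], w[0], atol=1e-12)

    def test_rows_sum_to_one_and_masked_keys_zero(self):
        rng = np.random.default_rng(0)
        Q, K, V = rng.normal(size=(3, 4)), rng.normal(size=(5, 4)), rng.normal(size=(5, 2))
        mask = np.array([True, False, True, True, False])
        out, w = scaled_dot_attention(Q, K, V, mask)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(w[:, ~mask] == 0.0)

    def test_fully_masked_rejected(self):
        with pytest.raises(ValidationError):
            scaled_dot_attention(
                np.ones((1, 2)), np.ones((2, 2)), np.ones((2, 1)),
                np.array([False, False]),
            )


class TestMultiHead:
    def test_single_head_identity_projections_reduce_to_plain_attention(self):
        rng = np.random.default_rng(1)
        mha = MultiHeadSelfAttention(4, 1, rng)
        for lin in (mha.wq, mha.wk, mha.wv, mha.wo):
            lin.W.value[...] = np.eye(4)
            lin.b.value[...] = 0.0
        X = rng.normal(size=(1, 3, 4))
        out = mha.forward(X)
        ref, _ = scaled_dot_attention(X[0], X[0], X[0])
        np.testing.assert_allclose(out[0], ref, atol=1e-9)

    def test_permutation_equivariance_with_mask(self):
        rng = np.random.default_rng(2)
        mha = MultiHeadSelfAttention(4, 2, rng)
        X = rng.normal(size=(1, 3, 4))
        mask = np.array([[True, True, False]])
        X[0, 2] = 0.0
        out = mha.forward(X, mask)
        perm = [1, 0, 2]
        out_p = mha.forward(X[:, perm], mask[:, perm])
        np.testing.assert_allclose(out_p[0], out[0][perm], atol=1e-10)

    def test_zero_input_zero_output_before_bias(self):
        rng = np.random.default_rng(3)
        mha = MultiHeadSelfAttention(4, 2, rng)
        for lin in (mha.wq, mha.wk, mha.wv, mha.wo):
            lin.b.value[...] = 0.0
        out = mha.forward(np.zeros((2, 3, 4)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_masked_position_cannot_influence_others(self):
        rng = np.random.default_rng(4)
        mha = MultiHeadSelfAttention(4, 2, rng)
        X = rng.normal(size=(1, 4, 4))
        mask = np.array([[True, True, True, False]])
        base = mha.forward(X, mask)
        X2 = X.copy()
        X2[0, 3] += 100.0  # perturb only the masked position
        pert = mha.forward(X2, mask)
        np.testing.assert_allclose(pert[0, :3], base[0, :3], atol=1e-10)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValidationError):
            MultiHeadSelfAttention(6, 4, np.random.default_rng(0))


class TestPositionEmbedding:
    def test_position_zero_alternates_zero_one(self):
        pe = position_embedding(4, 6)
        np.testing.assert_array_equal(pe[0, 0::2], 0.0)
        np.testing.assert_array_equal(pe[0, 1::2], 1.0)

    def test_position_one_first_pair(self):
        pe = position_embedding(2, 4)
        assert pe[1, 0] == pytest.approx(np.sin(1.0), abs=1e-12)
        assert pe[1, 1] == pytest.approx(np.cos(1.0), abs=1e-12)

    def test_matches_direct_evaluation(self):
        d_pos, max_len = 8, 50
        pe = position_embedding(max_len, d_pos)
        direct = np.zeros((max_len, d_pos))
        for p in range(max_len):
            for i in range(0, d_pos, 2):
                direct[p, i] = np.sin(p / 10000 ** (i / d_pos))
                direct[p, i + 1] = np.cos(p / 10000 ** (i / d_pos))
        np.testing.assert_allclose(pe, direct, atol=1e-12)

    def test_entries_bounded(self):
        pe = position_embedding(200, 7)
        assert np.all(np.abs(pe) <= 1.0)


_LINEAR_W = np.random.default_rng(12345).normal(size=(8, 3))


def linear_dataset(n=160, seq_len=20, n_feat=8, n_targ=3, noise=0.02, seed=0):
    """Targets are one fixed linear map of features plus small noise."""
    rng = np.random.default_rng(seed)
    X = rng.random((n, seq_len, n_feat))
    y = X @ _LINEAR_W + noise * rng.standard_normal((n, seq_len, n_targ))
    mask = np.ones((n, seq_len), bool)
    return SupervisedDataset(X, y, mask)


class TestEstimators:
    @pytest.fixture
    def config(self):
        return TransformerConfig(epochs=25, dropout=0.0, lr=3e-3, seed=0)

    def test_forward_shapes_and_batch_independence(self, config):
        model = TransformerEstimator(config)
        rng = np.random.default_rng(0)
        X = rng.random((2, 20, 8))
        pred = model.predict(X)
        assert pred.shape == (2, 20, 3)
        doubled = model.predict(np.concatenate([X, X]))
        np.testing.assert_allclose(doubled[:2], pred, atol=1e-12)
        np.testing.assert_allclose(doubled[2:], pred, atol=1e-12)

    def test_eval_mode_deterministic(self, config):
        model = TransformerEstimator(config)
        X = np.random.default_rng(1).random((3, 20, 8))
        np.testing.assert_array_equal(model.predict(X), model.predict(X))

    def test_feature_mismatch_rejected(self, config):
        model = TransformerEstimator(config)
        with pytest.raises(ValidationError):
            model.forward(np.zeros((1, 20, 5)))

    @pytest.mark.parametrize("kind,lr,factor", [
        ("transformer", 1e-2, 0.1), ("rnn", 3e-3, 0.5), ("lstm", 3e-3, 0.5),
    ])
    def test_training_reduces_val_loss(self, kind, lr, factor):
        train = linear_dataset(n=320, seed=0)
        val = linear_dataset(n=64, seed=1)
        cfg = TransformerConfig(epochs=100, dropout=0.0, lr=lr, seed=0)
        model = make_estimator(kind, cfg)
        history = train_estimator(model, train, val)
        assert min(history["val_loss"]) < factor * history["val_loss"][0]

    def test_zero_epochs_returns_initial_params(self):
        cfg = TransformerConfig(epochs=0, seed=0)
        m1 = TransformerEstimator(cfg)
        init = {k: v.copy() for k, v in m1.state_dict().items()}
        history = train_estimator(m1, linear_dataset(n=30))
        assert history["train_loss"] == []
        for k, v in m1.state_dict().items():
            np.testing.assert_array_equal(v, init[k])

    def test_seeded_training_deterministic(self):
        cfg = TransformerConfig(epochs=3, seed=5)
        train = linear_dataset(n=80)
        h1 = train_estimator(TransformerEstimator(cfg), train)
        h2 = train_estimator(TransformerEstimator(cfg), train)
        assert h1["train_loss"] == h2["train_loss"]


def test_grid_search_sweeps_and_selects_by_val_r2():
    from mmgmotion.models import grid_search

    train = linear_dataset(n=60)
    val = linear_dataset(n=20, seed=1)
    base = TransformerConfig(epochs=2, dropout=0.0, seed=0)
    best, records = grid_search(
        train, val, base, grid={"n_heads": [1, 2], "n_layers": [1]}
    )
    assert len(records) == 2
    top = max(records, key=lambda r: r["val_r2"])
    assert best.n_heads == top["n_heads"]


class TestR2:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2_score(y, y) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2_score(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_hand_arithmetic_case(self):
        assert r2_score(np.array([1.0, 2, 3]), np.array([1.0, 2, 2])) == pytest.approx(0.5)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValidationError):
            r2_score(np.ones(5), np.zeros(5))

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import r2_score as sk_r2
        rng = np.random.default_rng(0)
        y, p = rng.normal(size=200), rng.normal(size=200)
        assert r2_score(y, p) == pytest.approx(sk_r2(y, p), abs=1e-12)


class TestEvalReport:
    def test_single_trial_collapses(self):
        rep = EvalReport.from_scores([0.8])
        assert rep.highest == rep.lowest == rep.mean == 0.8

    def test_order_statistics(self):
        rep = EvalReport.from_scores([0.9, 0.8, 1.0])
        assert (rep.highest, rep.lowest) == (1.0, 0.8)
        assert rep.mean == pytest.approx(0.9)

    def test_trial_order_invariance(self):
        a = EvalReport.from_scores([0.3, 0.6, 0.9])
        b = EvalReport.from_scores([0.9, 0.3, 0.6])
        assert (a.highest, a.lowest, a.mean) == (b.highest, b.lowest, b.mean)

    def test_evaluate_skips_empty_trials(self):
        cfg = TransformerConfig(epochs=0, seed=0)
        model = TransformerEstimator(cfg)
        good = linear_dataset(n=10)
        empty = SupervisedDataset(
            np.zeros((0, 20, 8)), np.zeros((0, 20, 3)), np.zeros((0, 20), bool)
        )
        with pytest.warns(UserWarning):
            rep = evaluate(model, [good, empty])
        assert len(rep.r2_per_trial) == 1
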