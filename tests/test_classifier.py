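"""Tests for the gated three-pathway classifier: gates, forward pass,
loss, analytic gradient, training and serialization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eegentropy.classifier import (
    DynamicSynapseClassifier,
    DySCConfig,
    DySCParameters,
    TrainingConfig,
    cross_entropy,
    forward,
    gate_hierarchical,
    gate_multiscale,
    gate_time_invariant,
    initialize_parameters,
    loss_and_gradient,
    pathway_fuse,
    predict,
    softmax,
    train,
)
from eegentropy.features import FeatureBatch

SMALL = DySCConfig(d_m=4, d_h=3, d_t=3, n_classes=2, hidden_pathway=5, hidden_fusion=6)


def random_batch(rng, cfg, n):
    return FeatureBatch(
        x_m=rng.uniform(0, 1, (n, cfg.d_m)),
        x_h=rng.uniform(0, 1, (n, cfg.d_h)),
        x_t=rng.uniform(0, 1, (n, cfg.d_t)),
    )


def separable_batch(rng, cfg, n_per_class):
    lo = FeatureBatch(
        x_m=rng.uniform(0.0, 0.4, (n_per_class, cfg.d_m)),
        x_h=rng.uniform(0.0, 0.4, (n_per_class, cfg.d_h)),
        x_t=rng.uniform(0.0, 0.4, (n_per_class, cfg.d_t)),
    )
    hi = FeatureBatch(
        x_m=rng.uniform(0.6, 1.0, (n_per_class, cfg.d_m)),
        x_h=rng.uniform(0.6, 1.0, (n_per_class, cfg.d_h)),
        x_t=rng.uniform(0.6, 1.0, (n_per_class, cfg.d_t)),
    )
    batch = FeatureBatch(
        x_m=np.vstack([lo.x_m, hi.x_m]),
        x_h=np.vstack([lo.x_h, hi.x_h]),
        x_t=np.vstack([lo.x_t, hi.x_t]),
    )
    labels = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    return batch, labels


class TestGates:
    def test_zero_attention_kills_hierarchical_pathway(self, rng):
        x = rng.uniform(0, 1, (4, 3))
        G, xp = gate_hierarchical(x, np.zeros(3))
        assert np.all(G == 0) and np.all(xp == 0)

    def test_hierarchical_gate_open_range(self, rng):
        # entropy features in [0,1] with O(1) attention weights: the
        # tanh stays strictly inside (-1, 1)
        G, _ = gate_hierarchical(rng.uniform(0, 1, (50, 3)), rng.standard_normal(3) * 3)
        assert np.all(np.abs(G) < 1)

    def test_variance_gate_constant_input_passes_through(self):
        x = np.full((2, 5), 0.3)
        g, xp, var = gate_time_invariant(x, gamma=2.0)
        np.testing.assert_array_equal(g, 1.0)
        np.testing.assert_array_equal(xp, x)

    def test_variance_gate_large_gamma_suppresses(self, rng):
        x = rng.uniform(0, 1, (3, 6))
        g, _, _ = gate_time_invariant(x, gamma=1e6)
        assert np.all(g < 1e-3)

    def test_variance_gate_range(self, rng):
        g, _, _ = gate_time_invariant(rng.uniform(0, 1, (100, 10)), gamma=0.7)
        assert np.all(g > 0) and np.all(g <= 1)

    def test_variance_gate_rejects_nonpositive_gamma(self, rng):
        with pytest.raises(ValueError, match="positive"):
            gate_time_invariant(rng.uniform(0, 1, (2, 4)), gamma=0.0)

    def test_static_mask_identity_and_zero(self, rng):
        x = rng.uniform(0, 1, (5, 4))
        np.testing.assert_array_equal(gate_multiscale(x, np.ones(4)), x)
        np.testing.assert_array_equal(gate_multiscale(x, np.zeros(4)), 0 * x)

    def test_static_mask_linear(self, rng):
        x = rng.uniform(0, 1, (5, 4))
        w = rng.standard_normal(4)
        np.testing.assert_allclose(gate_multiscale(3 * x, w), 3 * gate_multiscale(x, w))

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            gate_hierarchical(rng.uniform(0, 1, (2, 3)), np.ones(4))


class TestFuseAndSoftmax:
    def test_zero_input_zero_bias(self):
        F = pathway_fuse(np.zeros((2, 3)), np.ones((3, 4)), np.zeros(4))
        np.testing.assert_array_equal(F, 0.0)

    def test_degenerate_affine(self):
        b = np.array([0.3, -0.2])
        F = pathway_fuse(np.ones((1, 3)), np.zeros((3, 2)), b)
        np.testing.assert_allclose(F[0], np.tanh(b))

    def test_symmetric_softmax(self):
        np.testing.assert_allclose(softmax([[0.0, 0.0]]), [[0.5, 0.5]])

    def test_shift_invariance(self, rng):
        z = rng.standard_normal((5, 4))
        np.testing.assert_allclose(softmax(z + 13.7), softmax(z), atol=1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_forward_invariants_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        batch = random_batch(rng, SMALL, 6)
        params = DySCParameters.from_vector(
            rng.standard_normal(initialize_parameters(SMALL, TrainingConfig()).to_vector().size),
            SMALL,
        )
        tr = forward(batch, params, SMALL)
        np.testing.assert_allclose(tr.P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(tr.P >= 0)
        assert np.all(np.abs(tr.G_h) < 1)
        assert np.all((tr.g_t > 0) & (tr.g_t <= 1))
        assert np.all(np.abs(tr.F_combined) < 1)


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy(P, np.array([0, 1])) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_uniform_prediction_log_k(self, k):
        P = np.full((4, k), 1.0 / k)
        assert cross_entropy(P, np.zeros(4, int)) == pytest.approx(np.log(k))

    def test_nonnegative(self, rng):
        P = rng.dirichlet(np.ones(3), size=20)
        assert cross_entropy(P, rng.integers(0, 3, 20)) >= 0.0

    def test_label_out_of_range(self, rng):
        with pytest.raises(ValueError, match="0..1"):
            cross_entropy(np.array([[0.5, 0.5]]), np.array([2]))


def finite_difference(vec, batch, labels, cfg, h=1e-6):
    fd = np.zeros_like(vec)
    for i in range(vec.size):
        vp, vm = vec.copy(), vec.copy()
        vp[i] += h
        vm[i] -= h
        fd[i] = (
            loss_and_gradient(vp, batch, labels, cfg)[0]
            - loss_and_gradient(vm, batch, labels, cfg)[0]
        ) / (2 * h)
    return fd


class TestGradient:
    def test_matches_central_differences(self, rng):
        for trial in range(5):
            k = int(rng.integers(2, 4))
            cfg = DySCConfig(
                d_m=4, d_h=3, d_t=3, n_classes=k, hidden_pathway=5, hidden_fusion=6
            )
            batch = random_batch(rng, cfg, 7)
            labels = rng.integers(0, k, 7)
            vec = initialize_parameters(cfg, TrainingConfig(seed=trial)).to_vector()
            vec = vec + 0.2 * rng.standard_normal(vec.size)
            _, grad = loss_and_gradient(vec, batch, labels, cfg)
            fd = finite_difference(vec, batch, labels, cfg)
            np.testing.assert_allclose(grad, fd, rtol=1e-5, atol=1e-7)

    def test_dead_feature_has_zero_mask_gradient(self, rng):
        batch = random_batch(rng, SMALL, 10)
        batch.x_m[:, 2] = 0.0  # feature that can never affect the loss
        labels = rng.integers(0, 2, 10)
        vec = initialize_parameters(SMALL, TrainingConfig(seed=3)).to_vector()
        params_grad = DySCParameters.from_vector(
            loss_and_gradient(vec, batch, labels, SMALL)[1], SMALL
        )
        assert params_grad.w_m_att[2] == 0.0
        np.testing.assert_array_equal(params_grad.W_m[2], 0.0)

    def test_gradient_small_at_optimum(self, rng):
        batch, labels = separable_batch(rng, SMALL, 30)
        params, res = train(batch, labels, SMALL, TrainingConfig(seed=0, max_iterations=200))
        _, grad = loss_and_gradient(params.to_vector(), batch, labels, SMALL)
        assert np.linalg.norm(grad) <= 1e-4


class TestTraining:
    def test_separable_data_high_accuracy(self, rng):
        batch, labels = separable_batch(rng, SMALL, 100)
        params, _ = train(batch, labels, SMALL, TrainingConfig(seed=1))
        pred, _ = predict(batch, params, SMALL)
        assert (pred == labels).mean() >= 0.99

    def test_loss_never_increases_from_init(self, rng):
        batch, labels = separable_batch(rng, SMALL, 20)
        tcfg = TrainingConfig(seed=5)
        x0 = initialize_parameters(SMALL, tcfg).to_vector()
        loss0, _ = loss_and_gradient(x0, batch, labels, SMALL)
        _, res = train(batch, labels, SMALL, tcfg)
        assert res.fun <= loss0

    def test_seed_determinism_bit_identical(self, rng):
        batch, labels = separable_batch(rng, SMALL, 15)
        p1, _ = train(batch, labels, SMALL, TrainingConfig(seed=9))
        p2, _ = train(batch, labels, SMALL, TrainingConfig(seed=9))
        assert np.array_equal(p1.to_vector(), p2.to_vector())

    def test_single_class_rejected(self, rng):
        batch = random_batch(rng, SMALL, 8)
        with pytest.raises(ValueError, match="2 classes"):
            train(batch, np.zeros(8, int), SMALL)


class TestPredict:
    def test_argmax_and_tie_break(self, rng):
        params = initialize_parameters(SMALL, TrainingConfig(seed=0))
        # zero output layer forces z = const -> uniform posterior -> class 0
        params.W_o[:] = 0.0
        params.b_o[:] = 0.0
        batch = random_batch(rng, SMALL, 4)
        pred, P = predict(batch, params, SMALL)
        np.testing.assert_allclose(P, 0.5)
        np.testing.assert_array_equal(pred, 0)

    def test_logit_shift_invariance(self, rng):
        params = initialize_parameters(SMALL, TrainingConfig(seed=2))
        batch = random_batch(rng, SMALL, 6)
        pred1, _ = predict(batch, params, SMALL)
        params.b_o += 100.0  # uniform logit shift
        pred2, _ = predict(batch, params, SMALL)
        np.testing.assert_array_equal(pred1, pred2)


class TestSerialization:
    def test_save_load_round_trip_bit_stable(self, rng, tmp_path):
        batch, labels = separable_batch(rng, SMALL, 10)
        clf = DynamicSynapseClassifier(SMALL, TrainingConfig(seed=4)).fit(batch, labels)
        p1 = tmp_path / "model.json"
        p2 = tmp_path / "model2.json"
        clf.save(p1)
        loaded = DynamicSynapseClassifier.load(p1)
        loaded.save(p2)
        assert p1.read_bytes() == p2.read_bytes()
        np.testing.assert_array_equal(clf.predict(batch), loaded.predict(batch))

    def test_version_checked(self, tmp_path):
        with pytest.raises(ValueError, match="format version"):
            DynamicSynapseClassifier.from_json_dict({"format_version": 99})
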