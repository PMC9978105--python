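import numpy as np
import pytest

from erpdtw import ErpTransformerClassifier, ErpTransformerNet, positional_encoding
from erpdtw.nn import softmax_cross_entropy


class TestPositionalEncoding:
    def test_row_zero_alternates_zero_one(self):
        pe = positional_encoding(10, 6)
        assert np.all(pe[0, 0::2] == 0.0)
        assert np.all(pe[0, 1::2] == 1.0)

    def test_entries_bounded(self):
        pe = positional_encoding(256, 35)
        assert pe.shape == (256, 35)
        assert np.all(np.abs(pe) <= 1.0)

    def test_matches_cellwise_generating_function(self):
        seq_len, dim = 12, 7
        pe = positional_encoding(seq_len, dim)
        for t in range(seq_len):
            for i in range(dim):
                k2 = i - (i % 2)                    # even index 2k below i
                omega = 10000.0 ** (-k2 / dim)
                expected = np.sin(omega * t) if i % 2 == 0 else np.cos(omega * t)
                assert pe[t, i] == pytest.approx(expected)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(0, 4)


def tiny_net(dropout_p=0.0, use_pe=True, seed=0, num_encoders=2):
    return ErpTransformerNet(seq_len=6, input_dim=4, num_encoders=num_encoders,
                             num_heads=2, head_dim=3, ffn_hidden=5,
                             dropout_p=dropout_p, use_positional_encoding=use_pe,
                             seed=seed)


class TestAttention:
    def test_softmax_rows_sum_to_one(self, rng):
        net = tiny_net()
        x = rng.standard_normal((2, 6, 4))
        net.forward(x)
        for enc in net.encoders:
            attn = enc.mha.attention_weights()
            assert attn.shape == (2, 2, 6, 6)
            np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-12)

    def test_constant_input_gives_time_constant_attention_output(self, rng):
        net = tiny_net(use_pe=False)
        x = np.tile(rng.standard_normal(4), (1, 6, 1))
        out = net.encoders[0].mha.forward(x)
        np.testing.assert_allclose(
            out, np.broadcast_to(out[:, :1, :], out.shape), atol=1e-12)

    def test_permutation_equivariance_without_positional_encoding(self, rng):
        net = tiny_net(use_pe=False)
        x = rng.standard_normal((1, 6, 4))
        perm = rng.permutation(6)
        out = net.encode(x)
        out_perm = net.encode(x[:, perm, :])
        np.testing.assert_allclose(out_perm, out[:, perm, :], atol=1e-10)

    def test_positional_encoding_breaks_permutation_equivariance(self, rng):
        net = tiny_net(use_pe=True)
        x = rng.standard_normal((1, 6, 4))
        perm = np.array([3, 0, 5, 1, 4, 2])
        assert not np.allclose(net.encode(x[:, perm, :]),
                               net.encode(x)[:, perm, :])


class TestEncoderAndForward:
    def test_shape_conserved_through_encoders(self, rng):
        net = tiny_net()
        x = rng.standard_normal((3, 6, 4))
        h = x + net.pe
        for enc in net.encoders:
            h = enc.forward(h, train=False, rng=None)
            assert h.shape == x.shape

    def test_layernorm_output_standardised(self, rng):
        net = tiny_net()
        h = net.encode(rng.standard_normal((2, 6, 4)))
        np.testing.assert_allclose(h.mean(axis=-1), 0.0, atol=1e-10)
        # var = s^2/(s^2+eps) sits just below 1 for small rows
        np.testing.assert_allclose(h.var(axis=-1), 1.0, atol=5e-3)

    def test_eval_mode_deterministic(self, rng):
        net = tiny_net(dropout_p=0.5)
        x = rng.standard_normal((2, 6, 4))
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_train_mode_reproducible_with_seeded_rng(self, rng):
        net = tiny_net(dropout_p=0.5)
        x = rng.standard_normal((2, 6, 4))
        a = net.forward(x, train=True, rng=np.random.default_rng(5))
        b = net.forward(x, train=True, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)
        c = net.forward(x, train=True, rng=np.random.default_rng(6))
        assert not np.array_equal(a, c)

    def test_probabilities_normalised(self, rng):
        net = tiny_net()
        p = net.predict_proba(rng.standard_normal((4, 6, 4)))
        assert p.shape == (4, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_architecture_introspection(self):
        net = ErpTransformerNet(seq_len=8, input_dim=5, num_encoders=3,
                                num_heads=5, dropout_p=0.5)
        assert len(net.encoders) == 3
        assert net.encoders[0].mha.h == 5
        assert net.encoders[0].mha.WQ.value.shape == (5, 5, 5)
        assert net.classifier.W.value.shape == (40, 2)

    def test_wrong_shape_names_expectation(self, rng):
        net = tiny_net()
        with pytest.raises(ValueError, match=r"\(6, 4\)"):
            net.forward(rng.standard_normal((2, 5, 4)))


class TestBackprop:
    def test_gradients_match_finite_differences(self, rng):
        """Whole-network gradient check: backprop vs central differences."""
        net = tiny_net(dropout_p=0.0, seed=3)
        X = rng.standard_normal((3, 6, 4))
        y = np.array([0, 1, 0])
        net.loss_and_grad(X, y, rng=np.random.default_rng(0))
        h = 1e-5
        check_rng = np.random.default_rng(9)
        worst = 0.0
        for p in net.params():
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for i in check_rng.choice(flat.size, min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + h
                l1, _ = softmax_cross_entropy(net.forward(X), y)
                flat[i] = orig - h
                l2, _ = softmax_cross_entropy(net.forward(X), y)
                flat[i] = orig
                fd = (l1 - l2) / (2 * h)
                worst = max(worst, abs(fd - gflat[i])
                            / max(abs(fd), abs(gflat[i]), 1e-3))
        assert worst < 1e-4


class TestClassifierEstimator:
    def test_untrained_model_is_at_chance_on_random_data(self, rng):
        net = tiny_net(seed=11)
        X = rng.standard_normal((400, 6, 4))
        y = rng.integers(0, 2, 400)
        pred = np.argmax(net.predict_proba(X), axis=1)
        acc = np.mean(pred == y)
        assert 0.4 <= acc <= 0.6

    def test_learns_separable_classes(self, rng):
        n = 120
        X = rng.standard_normal((n, 6, 4)) * 0.5
        y = np.where(rng.random(n) < 0.5, "Related", "Unrelated")
        X[y == "Related", 2:4, 1:3] += 2.0
        clf = ErpTransformerClassifier(num_encoders=2, num_heads=2, head_dim=4,
                                       ffn_hidden=8, dropout_p=0.1, n_epochs=40,
                                       batch_size=32, lr=2e-3, random_state=0)
        clf.fit(X[:90], y[:90])
        assert set(clf.classes_) == {"Related", "Unrelated"}
        assert clf.score(X[90:], y[90:]) >= 0.8
        proba = clf.predict_proba(X[90:])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_fit_reproducible_for_fixed_random_state(self, rng):
        X = rng.standard_normal((40, 6, 4))
        y = rng.integers(0, 2, 40)
        kw = dict(num_encoders=1, num_heads=2, head_dim=3, ffn_hidden=4,
                  n_epochs=3, batch_size=16, random_state=7)
        a = ErpTransformerClassifier(**kw).fit(X, y)
        b = ErpTransformerClassifier(**kw).fit(X, y)
        assert a.loss_history_ == b.loss_history_
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_checkpoint_round_trip(self, rng, tmp_path):
        X = rng.standard_normal((30, 6, 4))
        y = rng.integers(0, 2, 30)
        clf = ErpTransformerClassifier(num_encoders=1, num_heads=2, head_dim=3,
                                       ffn_hidden=4, n_epochs=2, random_state=1)
        clf.fit(X, y)
        path = tmp_path / "model.npz"
        clf.save(path)
        loaded = ErpTransformerClassifier.from_checkpoint(path)
        np.testing.assert_array_equal(loaded.predict(X), clf.predict(X))

    def test_rejects_2d_input(self, rng):
        clf = ErpTransformerClassifier()
        with pytest.raises(ValueError, match="n_trials"):
            clf.fit(rng.standard_normal((10, 24)), np.zeros(10))

    def test_sklearn_params_round_trip(self):
        clf = ErpTransformerClassifier(num_heads=3)
        assert clf.get_params()["num_heads"] == 3
        clf.set_params(lr=1e-3)
        assert clf.lr == 1e-3
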