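"""CNN encoder: shapes, training, determinism, gradients, ablations."""

import numpy as np
import pytest
from scipy.special import log_softmax

from mirdisc.encoder import CNNEncoder


def _toy_data(n=40, w=64, seed=0):
    """Linearly separable: two informative coordinates out of w."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, w))
    y = (rng.random(n) < 0.5).astype(int)
    X[:, 0] += 3.0 * y
    X[:, 1] -= 3.0 * y
    return X, y


class TestShapes:
    def test_internal_maps_follow_architecture(self):
        X, y = _toy_data(w=64)
        enc = CNNEncoder(epochs=2, random_state=0).fit(X, y)
        _, _, cache = enc._forward(X[:5].astype(enc.dtype), False)
        assert cache["conv_out"].shape == (5, 16, 64)
        assert cache["pooled_flat"].shape == (5, 16 * 32)
        assert cache["code"].shape == (5, 256)

    def test_code_width_and_probability_normalization(self):
        X, y = _toy_data(w=32)
        enc = CNNEncoder(epochs=2, random_state=0).fit(X, y)
        probs, codes = enc.forward(X[:7])
        assert codes.shape == (7, 256)
        assert probs.shape == (7, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_wrong_input_width_rejected(self):
        X, y = _toy_data(w=32)
        enc = CNNEncoder(epochs=1, random_state=0).fit(X, y)
        with pytest.raises(ValueError):
            enc.transform(np.zeros((3, 16)))

    def test_odd_width_incompatible_with_pooling(self):
        X, y = _toy_data(w=30)
        with pytest.raises(ValueError):
            CNNEncoder(epochs=1).fit(X[:, :29], y)


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        X, y = _toy_data(n=40, w=64)
        enc = CNNEncoder(epochs=20, patience=20, random_state=1).fit(X, y)
        assert enc.loss_trace_[-1] < enc.loss_trace_[0]

    def test_same_seed_gives_identical_parameters(self):
        X, y = _toy_data(n=24, w=32)
        e1 = CNNEncoder(epochs=3, random_state=5).fit(X, y)
        e2 = CNNEncoder(epochs=3, random_state=5).fit(X, y)
        for k in e1.params_:
            np.testing.assert_array_equal(e1.params_[k], e2.params_[k])

    def test_reported_loss_matches_cross_entropy_recomputation(self):
        # dropout off, one full batch: the first recorded loss is the
        # cross-entropy of the initial parameters' emitted probabilities
        X, y = _toy_data(n=16, w=16)
        enc = CNNEncoder(epochs=1, batch_size=16, dropout=0.0, random_state=2).fit(X, y)
        init = CNNEncoder(epochs=0, batch_size=16, dropout=0.0, random_state=2).fit(X, y)
        probs = init.predict_proba(X)
        ce = -np.mean(np.log(probs[np.arange(len(y)), y]))
        assert abs(ce - enc.loss_trace_[0]) < 1e-6

    def test_single_class_labels_rejected(self):
        X, _ = _toy_data(n=10, w=16)
        with pytest.raises(ValueError):
            CNNEncoder(epochs=1).fit(X, np.ones(10, dtype=int))


class TestEncode:
    def test_encode_is_deterministic_and_dropout_free(self):
        X, y = _toy_data(n=20, w=32)
        enc = CNNEncoder(epochs=2, random_state=0).fit(X, y)
        c1 = enc.transform(X)
        c2 = enc.transform(X)
        np.testing.assert_array_equal(c1, c2)
        assert c1.shape == (20, 256)

    def test_duplicated_rows_get_identical_codes(self):
        X, y = _toy_data(n=20, w=32)
        enc = CNNEncoder(epochs=2, random_state=0).fit(X, y)
        dup = np.vstack([X[0], X[0]])
        codes = enc.transform(dup)
        np.testing.assert_array_equal(codes[0], codes[1])


class TestGradientCheck:
    def test_full_network_gradients_match_central_differences(self):
        """Analytic gradients of the softmax cross-entropy w.r.t. a random
        20-parameter subset match central differences (rel err < 1e-4)."""
        rng = np.random.default_rng(0)
        X, y = _toy_data(n=4, w=8, seed=3)
        enc = CNNEncoder(
            epochs=0, dropout=0.0, code_dim=5, conv_channels=3,
            dtype=np.float64, random_state=4,
        ).fit(X, y)
        Xb = X.astype(np.float64)
        onehot = np.eye(2)[y]

        def loss():
            _, _, cache = enc._forward(Xb, False)
            logp = log_softmax(cache["logits"], axis=1)
            return -float((onehot * logp).sum()) / len(y)

        probs, _, cache = enc._forward(Xb, False)
        grads = enc._backward((probs - onehot) / len(y), cache)
        flat = [(k, idx) for k, g in grads.items() for idx in np.ndindex(g.shape)]
        eps = 1e-6
        for k, idx in [flat[i] for i in rng.choice(len(flat), 20, replace=False)]:
            orig = enc.params_[k][idx]
            enc.params_[k][idx] = orig + eps
            lp = loss()
            enc.params_[k][idx] = orig - eps
            lm = loss()
            enc.params_[k][idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[k][idx]
            assert abs(num - ana) / max(abs(num), 1e-7) < 1e-4, (k, idx)


class TestAblationVariants:
    def test_full_stack_has_five_learnable_layers_before_head(self):
        X, y = _toy_data(n=12, w=16)
        enc = CNNEncoder(epochs=1, random_state=0).fit(X, y)
        assert set(enc.params_) == {"Wc", "bc", "W1", "b1", "W2", "b2", "W3", "b3"}

    def test_pool_ablation_code_fc_consumes_full_hidden_map(self):
        X, y = _toy_data(n=12, w=16)
        enc = CNNEncoder(variant="pool_ablation", epochs=1, random_state=0).fit(X, y)
        assert enc.params_["W2"].shape == (16 * 16, 256)

    def test_conv_ablation_first_layer_consumes_raw_width(self):
        X, y = _toy_data(n=12, w=16)
        enc = CNNEncoder(variant="conv_ablation", epochs=1, random_state=0).fit(X, y)
        assert "Wc" not in enc.params_
        assert enc.params_["W1"].shape == (16, 16)

    def test_relu_fc_ablation_conv_feeds_pooling(self):
        X, y = _toy_data(n=12, w=16)
        enc = CNNEncoder(variant="relu_fc_ablation", epochs=1, random_state=0).fit(X, y)
        assert "W1" not in enc.params_
        assert enc.params_["W2"].shape == (16 * 8, 256)

    @pytest.mark.parametrize("variant", ["relu_fc_ablation", "pool_ablation", "conv_ablation"])
    def test_every_variant_keeps_the_code_and_head(self, variant):
        X, y = _toy_data(n=12, w=16)
        enc = CNNEncoder(variant=variant, epochs=1, random_state=0).fit(X, y)
        probs, codes = enc.forward(X[:3])
        assert codes.shape == (3, 256)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_variant_rejected(self):
        X, y = _toy_data(n=12, w=16)
        with pytest.raises(ValueError):
            CNNEncoder(variant="nope", epochs=1).fit(X, y)


class TestPersistence:
    def test_save_load_round_trip_preserves_codes(self, tmp_path):
        X, y = _toy_data(n=12, w=16)
        enc = CNNEncoder(epochs=2, random_state=0).fit(X, y)
        path = tmp_path / "encoder.npz"
        enc.save(path)
        back = CNNEncoder.load(path)
        np.testing.assert_array_equal(back.transform(X), enc.transform(X))
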