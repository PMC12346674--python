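import numpy as np
import pytest

from chilipcnn.data_model import InstanceTable
from chilipcnn.model import (
    ConfigError,
    ModelConfig,
    ParameterSet,
    Standardizer,
    TrainingConfig,
    backward_batch,
    conv1d_valid,
    dense,
    forward,
    forward_batch,
    init_params,
    predict,
    softmax_cross_entropy,
    train,
)


class TestLayerPrimitives:
    def test_conv_hand_example(self):
        np.testing.assert_array_equal(
            conv1d_valid([1, 2, 3, 4, 5], [1, 1, 1]), [6, 9, 12]
        )

    def test_conv_zero_kernel(self, rng):
        x = rng.normal(size=8)
        np.testing.assert_array_equal(conv1d_valid(x, [0, 0, 0]), np.zeros(6))

    def test_conv_identity_kernel(self, rng):
        x = rng.normal(size=8)
        np.testing.assert_array_equal(conv1d_valid(x, [1.0]), x)

    def test_conv_matches_numpy_correlate(self, rng):
        x, w = rng.normal(size=12), rng.normal(size=5)
        np.testing.assert_allclose(
            conv1d_valid(x, w), np.correlate(x, w, mode="valid")
        )

    def test_conv_kernel_too_long(self):
        with pytest.raises(ConfigError):
            conv1d_valid([1, 2], [1, 2, 3])

    def test_dense_hand_example(self):
        out = dense(np.array([1.0, 2.0]), np.array([[1.0, 1.0], [1.0, -1.0]]))
        np.testing.assert_array_equal(out, [3.0, -1.0])

    def test_dense_identity_and_zero(self, rng):
        x = rng.normal(size=4)
        np.testing.assert_array_equal(dense(x, np.eye(4)), x)
        np.testing.assert_array_equal(dense(x, np.zeros((3, 4))), np.zeros(3))

    def test_dense_shape_mismatch(self):
        with pytest.raises(ConfigError):
            dense(np.ones(3), np.ones((2, 4)))


class TestConfigValidation:
    def test_reshape_must_factor_hidden_width(self):
        with pytest.raises(ConfigError):
            ModelConfig(n_classes=3, fc_widths=(16,), reshape_shape=(3, 5))

    def test_stage2_kernel_must_fit(self):
        with pytest.raises(ConfigError):
            ModelConfig(n_classes=3, stage2_kernel=(3, 8))

    def test_sum_fusion_needs_matching_branches(self):
        with pytest.raises(ConfigError):
            ModelConfig(n_classes=3, fusion="sum", padding3="valid")

    def test_projection_width_is_pinned(self):
        with pytest.raises(ConfigError):
            ModelConfig(n_classes=3, projection_width=5)


class TestForward:
    def test_zero_params_give_zero_scores(self, rng):
        # bias-free: with all-zero weights nothing can light up
        cfg = ModelConfig(n_classes=5)
        params = init_params(cfg, seed=0)
        for t in params.tensors.values():
            t[:] = 0.0
        np.testing.assert_array_equal(
            forward(cfg, params, rng.normal(size=10)), np.zeros(5)
        )

    def test_forward_bitwise_reproducible(self, rng):
        cfg = ModelConfig(n_classes=7)
        params = init_params(cfg, seed=3)
        x = rng.normal(size=10)
        np.testing.assert_array_equal(forward(cfg, params, x),
                                      forward(cfg, params, x))

    def test_crafted_selector_network(self):
        # hand-set weights that route sensor 0 to class 1's score
        cfg = ModelConfig(n_classes=2)
        params = init_params(cfg, seed=0)
        for t in params.tensors.values():
            t[:] = 0.0
        params.tensors["conv3"][0] = [0.0, 1.0, 0.0]   # centre tap: identity
        params.tensors["fc0"][0, 0] = 1.0              # pick sensor 0
        params.tensors["stage2"][0, 0, 0] = 1.0        # map cell (0,0)
        params.tensors["proj"][0, 0] = 1.0
        params.tensors["classifier"][1, 0] = 1.0
        x = np.zeros(10)
        x[0] = 2.5
        scores = forward(cfg, params, x)
        np.testing.assert_array_equal(scores, [0.0, 2.5])
        assert predict(cfg, params, x) == 1

    def test_tie_breaks_to_lowest_index(self):
        cfg = ModelConfig(n_classes=4)
        params = init_params(cfg, seed=0)
        for t in params.tensors.values():
            t[:] = 0.0
        assert predict(cfg, params, np.ones(10)) == 0

    def test_predict_equals_argmax_of_forward(self, rng):
        cfg = ModelConfig(n_classes=6)
        params = init_params(cfg, seed=9)
        for _ in range(10):
            x = rng.normal(size=10)
            assert predict(cfg, params, x) == int(np.argmax(forward(cfg, params, x)))

    def test_wrong_input_length(self):
        cfg = ModelConfig(n_classes=3)
        params = init_params(cfg, seed=0)
        with pytest.raises(ConfigError):
            forward(cfg, params, np.ones(9))


@pytest.mark.parametrize(
    "config",
    [
        ModelConfig(n_classes=3),
        ModelConfig(n_classes=3, fusion="concat", fc_widths=(5, 12),
                    reshape_shape=(3, 4), stage2_kernel=(1, 4), f3=3,
                    padding3="valid"),
        ModelConfig(n_classes=2, fusion="concat", f1=2, f2=1, fc_widths=(),
                    padding3="valid", padding5="valid",
                    reshape_shape=(2, 11), stage2_kernel=(2, 3), f3=2),
    ],
    ids=["sum-default", "concat-two-fc", "no-fc"],
)
def test_gradients_match_finite_differences(config):
    """Analytic backprop vs central differences on every weight."""
    params = init_params(config, seed=7)
    rng = np.random.default_rng(3)
    X = rng.normal(size=(5, 10))
    y = rng.integers(0, config.n_classes, size=5)

    scores, cache = forward_batch(config, params, X, want_cache=True)
    _, dscores = softmax_cross_entropy(scores, y)
    grads = backward_batch(config, params, cache, dscores)

    eps = 1e-6
    for name, t in params.tensors.items():
        numeric = np.zeros_like(t)
        it = np.nditer(t, flags=["multi_index"])
        while not it.finished:
            i = it.multi_index
            orig = t[i]
            t[i] = orig + eps
            lp = softmax_cross_entropy(forward_batch(config, params, X), y)[0]
            t[i] = orig - eps
            lm = softmax_cross_entropy(forward_batch(config, params, X), y)[0]
            t[i] = orig
            numeric[i] = (lp - lm) / (2 * eps)
            it.iternext()
        rel = np.abs(numeric - grads[name]) / np.maximum(
            1e-8, np.abs(numeric) + np.abs(grads[name])
        )
        assert rel.max() < 1e-4, f"gradient mismatch in {name}"


class TestTraining:
    def test_learning_rate_schedule(self):
        tc = TrainingConfig()
        assert tc.learning_rate(0) == pytest.approx(0.01)
        assert tc.learning_rate(9) == pytest.approx(0.01)
        assert tc.learning_rate(10) == pytest.approx(0.0095)
        assert tc.learning_rate(25) == pytest.approx(0.009025)

    def test_loss_decreases_on_separable_toy(self, rng):
        # two well-separated 2-class clusters: smoothed loss must fall
        n = 120
        X = np.vstack([
            rng.normal(loc=+1.0, scale=0.1, size=(n // 2, 10)),
            rng.normal(loc=-1.0, scale=0.1, size=(n // 2, 10)),
        ])
        y = np.repeat([0, 1], n // 2)
        table = InstanceTable(np.abs(X) + 0.01, y,
                              np.arange(n).astype(str), np.ones(n))
        cfg = ModelConfig(n_classes=2)
        tc = TrainingConfig(epochs=50, seed=0)
        _, hist = train(cfg, table, tc, X=X)
        early = np.mean(hist.loss[:5])
        late = np.mean(hist.loss[-5:])
        assert late < early

    def test_training_reproducible(self, rng):
        n = 40
        X = rng.normal(size=(n, 10))
        y = rng.integers(0, 2, size=n)
        table = InstanceTable(np.abs(X) + 0.01, y,
                              np.arange(n).astype(str), np.ones(n))
        cfg = ModelConfig(n_classes=2)
        tc = TrainingConfig(epochs=3, seed=5)
        p1, h1 = train(cfg, table, tc, X=X)
        p2, h2 = train(cfg, table, tc, X=X)
        assert h1.loss == h2.loss
        for k in p1.tensors:
            np.testing.assert_array_equal(p1.tensors[k], p2.tensors[k])

    def test_restarts_never_worse_than_single_run(self, rng):
        n = 60
        X = rng.normal(size=(n, 10))
        y = rng.integers(0, 3, size=n)
        table = InstanceTable(np.abs(X) + 0.01, y,
                              np.arange(n).astype(str), np.ones(n))
        cfg = ModelConfig(n_classes=3)
        single = TrainingConfig(epochs=5, seed=4, n_restarts=1)
        multi = TrainingConfig(epochs=5, seed=4, n_restarts=3)
        _, h1 = train(cfg, table, single, X=X)
        _, h3 = train(cfg, table, multi, X=X)
        assert h3.loss[-1] <= h1.loss[-1]

    def test_label_out_of_range(self, rng):
        table = InstanceTable(
            np.abs(rng.normal(size=(10, 10))) + 0.01,
            np.full(10, 5), np.arange(10).astype(str), np.ones(10),
        )
        with pytest.raises(ValueError, match="label out of range"):
            train(ModelConfig(n_classes=3), table, TrainingConfig(epochs=1))

    def test_invalid_train_fraction(self):
        with pytest.raises(ConfigError):
            TrainingConfig(train_fraction=1.0)


class TestStandardizer:
    def test_transform_centers_and_scales(self, rng):
        X = rng.normal(loc=3.0, scale=2.0, size=(500, 10))
        std = Standardizer.fit(X)
        Z = std.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_constant_feature_no_blowup(self):
        X = np.ones((20, 10))
        Z = Standardizer.fit(X).transform(X)
        assert np.all(np.isfinite(Z))

    def test_identity_passthrough(self, rng):
        X = rng.normal(size=(5, 10))
        np.testing.assert_array_equal(Standardizer.identity().transform(X), X)


class TestParameterSet:
    def test_flat_serialization_4_bytes_per_weight(self):
        cfg = ModelConfig(n_classes=13)
        params = init_params(cfg, seed=0)
        assert len(params.to_flat_bytes()) == 4 * params.n_elements

    def test_save_load_roundtrip(self, tmp_path):
        cfg = ModelConfig(n_classes=5)
        params = init_params(cfg, seed=2)
        path = tmp_path / "w.npz"
        params.save(path)
        loaded = ParameterSet.load(path)
        assert list(loaded.tensors) == list(params.tensors)
        for k in params.tensors:
            np.testing.assert_array_equal(loaded.tensors[k], params.tensors[k])

    def test_init_deterministic(self):
        cfg = ModelConfig(n_classes=4)
        a = init_params(cfg, seed=11)
        b = init_params(cfg, seed=11)
        for k in a.tensors:
            np.testing.assert_array_equal(a.tensors[k], b.tensors[k])
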