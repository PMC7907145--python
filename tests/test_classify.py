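import numpy as np
import pytest

from _oracles import (
    conv_param_count,
    conv_size,
    dense_param_count,
    lstm_param_count,
    lstm_step,
    pool_size,
)
from eegtopo.classify import (
    CONFIGS,
    CnnConfig,
    FoldResult,
    HybridNet,
    LstmSpec,
    TrainConfig,
    baseline_fit,
    build_model,
    count_parameters,
    crossvalidate,
    evaluate,
    flatten_size,
    kfold_indices,
    layer_sizes,
    train,
)
from eegtopo.classify.layers import LSTM, softmax

TINY = CnnConfig("T", ((1, 4), (1, 8)), fc_nodes=16)


def toy_dataset(n=24, frames=3, size=8, seed=0, separable=True):
    """Class-constant images: trivially separable unless separable=False."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    x = rng.random((n, frames, size, size, 3)).astype(np.float32) * 0.1
    if separable:
        x += y[:, None, None, None, None] * 0.8
    return x.astype(np.float32), y


class TestLayerArithmetic:
    @pytest.mark.parametrize("name", ["A", "B", "C", "D"])
    def test_sizes_obey_conv_and_pool_formulas(self, name):
        cfg = CONFIGS[name]
        trace = layer_sizes(cfg, 32)
        size = 32
        for desc, got_size, _channels in trace[1:-2]:
            if desc.startswith("conv"):
                size = conv_size(size, 3, 1, 1)
            else:
                size = pool_size(size, 2, 2)
            assert size == int(size) and got_size == size

    def test_config_c_flatten_2048(self):
        assert flatten_size(CONFIGS["C"], 32) == 4 * 4 * 128 == 2048

    def test_config_c_spatial_trace(self):
        sizes = [s for d, s, c in layer_sizes(CONFIGS["C"], 32) if d.startswith("pool")]
        assert sizes == [16, 8, 4]

    def test_config_a_flatten_8192(self):
        assert flatten_size(CONFIGS["A"], 32) == 16 * 16 * 32 == 8192

    def test_plans_match_table(self):
        assert CONFIGS["A"].conv_plan == ((2, 32),)
        assert CONFIGS["B"].conv_plan == ((2, 32), (2, 64))
        assert CONFIGS["C"].conv_plan == ((2, 32), (2, 64), (1, 128))
        assert CONFIGS["D"].conv_plan == ((4, 32), (2, 64), (1, 128))

    def test_non_integer_size_rejected(self):
        # 7x7 input cannot be pooled 2x2/stride 2 evenly
        with pytest.raises(ValueError, match="pool"):
            layer_sizes(CONFIGS["A"], 7)


class TestParameterCounts:
    def test_first_conv_layer_896(self):
        assert conv_param_count(3, 32) == 896

    def test_config_c_conv_stack_sum(self):
        expected = 896 + 9248 + 18496 + 36928 + 73856
        assert expected == 139424
        model = build_model("C", seed=0)
        conv_params = sum(
            layer.W.size + layer.b.size
            for layer in model.cnn_layers
            if hasattr(layer, "W")
        )
        assert conv_params == expected

    def test_lstm_count_512_to_128(self):
        assert lstm_param_count(512, 128) == 328192
        lstm = LSTM(512, 128, np.random.default_rng(0))
        assert sum(p.size for p in lstm.params()) == 328192

    def test_total_matches_layerwise_closed_form(self):
        model = build_model("C", seed=0)
        expected = (
            139424
            + dense_param_count(2048, 512)
            + lstm_param_count(512, 128)
            + dense_param_count(128, 2)
        )
        assert count_parameters(model) == expected


class TestLstmOracle:
    def test_single_step_matches_gate_equations(self, rng):
        hidden, n_in = 3, 4
        lstm = LSTM(n_in, hidden, rng)
        x = rng.standard_normal((1, 1, n_in)).astype(np.float32)
        h = lstm.forward(x, train=False)

        wx = lstm.Wx.value.astype(np.float64)
        wh = lstm.Wh.value.astype(np.float64)
        b = lstm.b.value.astype(np.float64)

        def gate_w(idx):
            # oracle wants W.[h, x]: hidden columns first, then input columns
            block_x = wx[:, idx * hidden : (idx + 1) * hidden].T
            block_h = wh[:, idx * hidden : (idx + 1) * hidden].T
            return np.hstack([block_h, block_x])

        h_ref, c_ref = lstm_step(
            x[0, 0].astype(np.float64),
            np.zeros(hidden),
            np.zeros(hidden),
            gate_w(0),
            gate_w(1),
            gate_w(2),
            gate_w(3),
            b[0 * hidden : 1 * hidden],
            b[1 * hidden : 2 * hidden],
            b[2 * hidden : 3 * hidden],
            b[3 * hidden : 4 * hidden],
        )
        np.testing.assert_allclose(h[0], h_ref, atol=1e-6)

    def test_two_steps_match_oracle(self, rng):
        hidden, n_in = 2, 3
        lstm = LSTM(n_in, hidden, rng)
        x = rng.standard_normal((1, 2, n_in)).astype(np.float32)
        h = lstm.forward(x, train=False)
        wx = lstm.Wx.value.astype(np.float64)
        wh = lstm.Wh.value.astype(np.float64)
        b = lstm.b.value.astype(np.float64)

        def gate_w(idx):
            return np.hstack(
                [wh[:, idx * hidden : (idx + 1) * hidden].T, wx[:, idx * hidden : (idx + 1) * hidden].T]
            )

        ws = [gate_w(i) for i in range(4)]
        bs = [b[i * hidden : (i + 1) * hidden] for i in range(4)]
        h_ref = np.zeros(hidden)
        c_ref = np.zeros(hidden)
        for t in range(2):
            h_ref, c_ref = lstm_step(x[0, t].astype(np.float64), h_ref, c_ref, *ws, *bs)
        np.testing.assert_allclose(h[0], h_ref, atol=1e-6)


class TestBuildModel:
    def test_softmax_rows_sum_to_one(self, rng):
        model = build_model(TINY, n_frames=3, image_size=8, seed=0)
        x = rng.random((5, 3, 8, 8, 3)).astype(np.float32)
        probs = model.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_unknown_config_name_rejected(self):
        with pytest.raises(ValueError, match="unknown CNN"):
            build_model("E")

    def test_forward_shape(self, rng):
        model = build_model(TINY, n_frames=3, image_size=8, seed=0)
        out = model.forward(rng.random((4, 3, 8, 8, 3)))
        assert out.shape == (4, 2)

    def test_bad_input_shape_rejected(self, rng):
        model = build_model(TINY, n_frames=3, image_size=8, seed=0)
        with pytest.raises(ValueError, match="expected"):
            model.forward(rng.random((4, 3, 8, 8)))

    def test_softmax_normalization(self, rng):
        logits = rng.standard_normal((6, 2)) * 10
        probs = softmax(logits)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)


class TestTrain:
    def test_memorizes_separable_toy_data(self):
        x, y = toy_dataset(40, separable=True)
        model = build_model(TINY, n_frames=3, image_size=8, dropout=0.0, seed=1)
        cfg = TrainConfig(epochs=5, batch_size=8, dropout=0.0, seed=1)
        history = train(model, x, y, cfg)
        assert history["train_acc"][-1] == 1.0

    def test_zero_epochs_is_noop(self):
        x, y = toy_dataset(8)
        model = build_model(TINY, n_frames=3, image_size=8, seed=0)
        before = model.get_state()
        history = train(model, x, y, TrainConfig(epochs=0, seed=0))
        assert history["train_loss"] == []
        for a, b in zip(before, model.get_state()):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_identical_losses(self):
        x, y = toy_dataset(16)
        losses = []
        for _ in range(2):
            model = build_model(TINY, n_frames=3, image_size=8, seed=7)
            history = train(model, x, y, TrainConfig(epochs=2, batch_size=4, seed=7))
            losses.append(history["train_loss"])
        assert losses[0] == losses[1]

    def test_single_class_rejected(self):
        x, y = toy_dataset(8)
        model = build_model(TINY, n_frames=3, image_size=8, seed=0)
        with pytest.raises(ValueError, match="two classes"):
            train(model, x, np.zeros(8, dtype=int), TrainConfig(epochs=1))

    def test_validation_history_recorded(self):
        x, y = toy_dataset(16)
        model = build_model(TINY, n_frames=3, image_size=8, seed=0)
        history = train(model, x, y, TrainConfig(epochs=2, batch_size=8, seed=0), x, y)
        assert len(history["val_acc"]) == 2

    def test_loss_non_negative(self):
        x, y = toy_dataset(8)
        model = build_model(TINY, n_frames=3, image_size=8, seed=0)
        loss, _acc = evaluate(model, x, y)
        assert loss >= 0.0

    def test_plateau_abort_stops_early(self):
        x, y = toy_dataset(16, separable=False)
        model = build_model(TINY, n_frames=3, image_size=8, seed=0)
        cfg = TrainConfig(
            epochs=10,
            batch_size=8,
            seed=0,
            plateau_abort_epoch=2,
            plateau_abort_acc=1.0,  # unreachable -> abort at epoch 2
        )
        history = train(model, x, y, cfg, x, y)
        assert len(history["train_loss"]) == 2


class TestCrossvalidate:
    def test_partition_contract(self, rng):
        folds = kfold_indices(100, 10, rng)
        assert len(folds) == 10
        assert all(len(f) == 10 for f in folds)
        combined = np.concatenate(folds)
        assert len(combined) == 100 and len(set(combined.tolist())) == 100

    @pytest.mark.parametrize("n,k", [(10, 3), (17, 5), (23, 10)])
    def test_partition_various_sizes(self, n, k, rng):
        folds = kfold_indices(n, k, rng)
        combined = sorted(np.concatenate(folds).tolist())
        assert combined == list(range(n))

    def test_too_many_folds_rejected(self, rng):
        with pytest.raises(ValueError, match="folds"):
            kfold_indices(5, 10, rng)

    def test_crossvalidate_separable(self):
        x, y = toy_dataset(40, separable=True)

        def factory(seed):
            return build_model(TINY, n_frames=3, image_size=8, dropout=0.0, seed=seed)

        results, summary = crossvalidate(
            x, y, factory, TrainConfig(epochs=10, batch_size=8, dropout=0.0, seed=0), k=5
        )
        assert len(results) == 5
        assert summary["mean_test_accuracy"] >= 0.9
        for r in results:
            assert np.sum(r.confusion) == r.n_test
            assert 0.0 <= r.test_accuracy <= 1.0

    def test_retrain_gate_and_train_eval_skip(self):
        x, y = toy_dataset(20, separable=True)
        built_seeds = []

        def factory(seed):
            built_seeds.append(seed)
            return build_model(TINY, n_frames=3, image_size=8, seed=seed)

        results, _ = crossvalidate(
            x,
            y,
            factory,
            TrainConfig(epochs=1, batch_size=4, seed=0),
            k=2,
            retrain_below=1.1,  # unreachable gate -> every attempt retried
            max_retrains=2,
            eval_train=False,
        )
        assert len(built_seeds) == 2 * 3  # 2 folds x (1 + 2 retries)
        assert all(0.0 <= r.train_accuracy <= 1.0 for r in results)

    def test_explicit_folds_respected(self):
        x, y = toy_dataset(12)

        def factory(seed):
            return build_model(TINY, n_frames=3, image_size=8, seed=seed)

        folds = [np.arange(0, 4), np.arange(4, 8), np.arange(8, 12)]
        results, summary = crossvalidate(
            x, y, factory, TrainConfig(epochs=1, batch_size=4, seed=0), folds=folds
        )
        assert summary["k"] == 3
        assert all(r.n_test == 4 for r in results)


class TestBaselines:
    def blobs(self, n=60, sep=4.0, seed=0):
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2
        x = rng.standard_normal((n, 8)) + sep * y[:, None]
        return x, y

    @pytest.mark.parametrize("method", ["svm", "knn", "logreg"])
    def test_separable_blobs(self, method):
        x, y = self.blobs()
        _fitted, acc = baseline_fit(x, y, method, seed=0)
        assert acc >= 0.95

    def test_label_permutation_null(self):
        x, _ = self.blobs(n=80, sep=0.0)
        y = np.random.default_rng(1).integers(0, 2, 80)
        _fitted, acc = baseline_fit(x, y, "logreg", seed=0)
        assert abs(acc - 0.5) < 0.2

    def test_knn_k1_self_training_accuracy(self):
        from sklearn.neighbors import KNeighborsClassifier

        x, y = self.blobs(n=30, sep=1.0)
        knn = KNeighborsClassifier(n_neighbors=1).fit(x, y)
        assert knn.score(x, y) == 1.0

    def test_unknown_method_rejected(self):
        x, y = self.blobs(n=20)
        with pytest.raises(ValueError, match="unknown baseline"):
            baseline_fit(x, y, "forest")

    def test_single_class_rejected(self):
        x, _ = self.blobs(n=20)
        with pytest.raises(ValueError, match="two classes"):
            baseline_fit(x, np.zeros(20, dtype=int), "svm")
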