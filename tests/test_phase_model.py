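import numpy as np
import pytest

from gaitphase._nn import BatchNorm, SequenceClassifier, sigmoid
from gaitphase.features import FeatureSet
from gaitphase.gait_labeler import LabeledSeries
from gaitphase.phase_model import (
    ModelSpec,
    PhaseModel,
    PredictionTrace,
    TrainConfig,
    build_model,
    combine_traces,
    frame_metrics,
    predict_trace,
    train,
)
from gaitphase.windowing import WindowTensor


def _toy_spec(seq_len=31, units=(4, 8, 4)):
    return ModelSpec(units=units, seq_len=seq_len, dropout_rate=0.0)


def _toy_windows(n_pos=12, n_neg=24, seq_len=31, seed=0, phase="FO"):
    """Linearly separable set: high-amplitude bump at center vs flat noise."""
    rng = np.random.default_rng(seed)
    windows, targets = [], []
    t = np.arange(seq_len)
    bump = np.exp(-0.5 * ((t - seq_len // 2) / 2.0) ** 2)
    for _ in range(n_pos):
        w = rng.normal(0, 0.05, size=(seq_len, 3))
        w[:, 0] += bump
        windows.append(w)
        targets.append(1)
    for _ in range(n_neg):
        windows.append(rng.normal(0, 0.05, size=(seq_len, 3)))
        targets.append(0)
    order = rng.permutation(len(targets))
    return WindowTensor(
        windows=np.array(windows)[order],
        targets=np.array(targets, dtype=np.int8)[order],
        source_frames=np.arange(len(targets)),
        phase=phase,
        center_offset=seq_len // 2,
    )


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """End-to-end gradient check through LSTM, batch-norm and dense layers."""
        net = SequenceClassifier(n_features=2, units=[3, 4], dropout_rate=0.0,
                                 bn_momentum=0.99, bn_epsilon=0.001, seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 7, 2))
        y = rng.integers(0, 2, 5).astype(float)

        def loss():
            p = sigmoid(net.forward(x, mode="train"))
            return -np.mean(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12))

        for layer in net.layers:
            layer.zero_grads()
        p = sigmoid(net.forward(x, mode="train"))
        dout = ((p - y) / y.size)[:, None]
        for layer in reversed(net.layers):
            dout = layer.backward(dout)

        worst = 0.0
        for li, layer in enumerate(net.layers):
            for key, w in layer.params.items():
                flat = np.random.default_rng(li).choice(w.size, size=min(5, w.size),
                                                        replace=False)
                for fi in flat:
                    idx = np.unravel_index(fi, w.shape)
                    orig, h = w[idx], 1e-6
                    w[idx] = orig + h
                    lp = loss()
                    w[idx] = orig - h
                    lm = loss()
                    w[idx] = orig
                    num = (lp - lm) / (2 * h)
                    g = layer.grads[key][idx]
                    worst = max(worst, abs(num - g) / max(1e-8, abs(num) + abs(g)))
        assert worst < 1e-5


class TestArchitecture:
    def test_default_spec_layer_units(self):
        model = build_model(ModelSpec(), phase="FO")
        from gaitphase._nn import LSTM
        lstms = [l for l in model.net.layers if isinstance(l, LSTM)]
        assert [l.units for l in lstms] == [30, 60, 60, 60, 30]
        assert [l.return_sequences for l in lstms] == [True, True, True, True, False]
        assert model.net.layers[-1].params["W"].shape == (30, 1)

    def test_reduced_spec_forward_shape(self):
        model = build_model(_toy_spec(seq_len=251, units=(4, 8, 4)))
        out = model.net.predict_proba(np.zeros((2, 251, 3)))
        assert out.shape == (2,)
        assert np.all((out >= 0) & (out <= 1))

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(dropout_rate=1.0)

    def test_batchnorm_inference_uses_moving_stats(self):
        bn = BatchNorm(3)
        x = np.random.default_rng(0).normal(2.0, 3.0, size=(40, 3))
        bn.forward(x, "train", None)
        out1 = bn.forward(x[:5], "infer", None)
        out2 = bn.forward(x[:5], "infer", None)
        np.testing.assert_array_equal(out1, out2)


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        tensor = _toy_windows()
        model = build_model(_toy_spec(), seed=1)
        history = train(model, tensor,
                        cfg=TrainConfig(learning_rate=3e-3, epochs=5, batch_size=8, seed=1))
        assert history[-1]["loss"] < history[0]["loss"]

    def test_history_row_per_epoch_with_validation(self):
        tensor = _toy_windows()
        val = _toy_windows(seed=5)
        model = build_model(_toy_spec(), seed=1)
        history = train(model, tensor, val=val,
                        cfg=TrainConfig(learning_rate=1e-3, epochs=3, batch_size=8, seed=1))
        assert len(history) == 3
        assert {"loss", "accuracy", "val_loss", "val_accuracy"} <= set(history[0])

    def test_zero_epochs_leaves_model_unchanged(self):
        model = build_model(_toy_spec(), seed=2)
        before = {k: v.copy() for k, v in model.net.state_arrays().items()}
        train(model, _toy_windows(), cfg=TrainConfig(epochs=0))
        after = model.net.state_arrays()
        for key in before:
            np.testing.assert_array_equal(before[key], after[key])

    def test_same_seed_reproduces_training_exactly(self):
        histories = []
        weights = []
        for _ in range(2):
            model = build_model(_toy_spec(), seed=3)
            h = train(model, _toy_windows(),
                      cfg=TrainConfig(learning_rate=1e-3, epochs=2, batch_size=8, seed=3))
            histories.append(h)
            weights.append(model.net.state_arrays())
        assert histories[0] == histories[1]
        for key in weights[0]:
            np.testing.assert_array_equal(weights[0][key], weights[1][key])

    def test_shape_mismatch_rejected(self):
        model = build_model(_toy_spec(seq_len=31))
        bad = _toy_windows(seq_len=25)
        with pytest.raises(ValueError):
            train(model, bad)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        model = build_model(_toy_spec(), phase="MidS", seed=4)
        train(model, _toy_windows(),
              cfg=TrainConfig(learning_rate=1e-3, epochs=1, batch_size=8, seed=4))
        model.save(tmp_path / "m")
        back = PhaseModel.load(tmp_path / "m")
        assert back.phase == "MidS"
        assert back.spec == model.spec
        x = np.random.default_rng(0).normal(size=(3, 31, 3))
        np.testing.assert_array_equal(model.net.predict_proba(x), back.net.predict_proba(x))


class TestPrediction:
    def _features(self, n, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, n)
        return FeatureSet(side="left", ang_vel_mag=x, free_acc_mag=x, rot_mat_mag=x,
                          raw_ang_vel_mag=x)

    def test_minimum_length_gives_single_probability(self):
        model = build_model(_toy_spec(seq_len=251, units=(3,)))
        trace = predict_trace(model, self._features(251))
        assert trace.n_values == 1
        assert trace.first_center_frame == 125

    def test_trace_length_and_range(self):
        model = build_model(_toy_spec(seq_len=251, units=(3,)))
        trace = predict_trace(model, self._features(400))
        assert trace.n_values == 400 - 250
        assert np.all((trace.probabilities >= 0) & (trace.probabilities <= 1))

    def test_too_short_input_rejected(self):
        model = build_model(_toy_spec(seq_len=251, units=(3,)))
        with pytest.raises(ValueError):
            predict_trace(model, self._features(250))

    def test_combine_traces_geometric_mean(self):
        a = PredictionTrace(phase="FC", probabilities=np.array([0.9, 0.1, 0.5]))
        b = PredictionTrace(phase="FC", probabilities=np.array([0.4, 0.1, 0.5]))
        out = combine_traces([a, b])
        np.testing.assert_allclose(out.probabilities, np.sqrt([0.36, 0.01, 0.25]))

    def test_combine_rejects_misaligned_traces(self):
        a = PredictionTrace(phase="FC", probabilities=np.zeros(3))
        b = PredictionTrace(phase="FO", probabilities=np.zeros(3))
        with pytest.raises(ValueError):
            combine_traces([a, b])


class TestFrameMetrics:
    def _labels(self, n, frames=()):
        fo = np.zeros(n, dtype=np.int8)
        fo[list(frames)] = 1
        return LabeledSeries(fo=fo, mids=np.zeros(n, dtype=np.int8),
                             fc=np.zeros(n, dtype=np.int8))

    def test_zero_trace_on_all_negative_labels(self):
        trace = PredictionTrace(phase="FO", probabilities=np.zeros(100))
        out = frame_metrics(trace, self._labels(350), "FO")
        assert out["accuracy"] == 1.0
        assert out["bce_loss"] == pytest.approx(0.0, abs=1e-5)

    def test_half_trace_gives_ln2_loss_and_baseline_accuracy(self):
        trace = PredictionTrace(phase="FO", probabilities=np.full(200, 0.5))
        labels = self._labels(450, frames=[130, 140])
        out = frame_metrics(trace, labels, "FO")
        assert out["bce_loss"] == pytest.approx(np.log(2.0), rel=1e-6)
        assert out["accuracy"] == out["all_negative_baseline"] == 198 / 200

    def test_matches_hand_computed_toy_bce(self):
        p = np.array([0.9, 0.2, 0.7, 0.4, 0.99, 0.01, 0.5, 0.5, 0.3, 0.8])
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0, 0, 1])
        trace = PredictionTrace(phase="FO", probabilities=p)
        labels = self._labels(300, frames=(np.flatnonzero(y) + 125).tolist())
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        out = frame_metrics(trace, labels, "FO")
        assert out["bce_loss"] == pytest.approx(expected, rel=1e-9)
        assert out["accuracy"] == 0.9  # strict > 0.5 rule; exactly one mismatch
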