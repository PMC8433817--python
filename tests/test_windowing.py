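import numpy as np
import pytest

from gaitphase.features import FeatureSet
from gaitphase.gait_labeler import LabeledSeries
from gaitphase.windowing import (
    WINDOW_LENGTH,
    balance_windows,
    concatenate_windows,
    make_windows,
    split_by_recording,
)


def _features(n, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureSet(
        side="left",
        ang_vel_mag=rng.uniform(0, 400, n),
        free_acc_mag=rng.uniform(0, 20, n),
        rot_mat_mag=rng.uniform(0, 1.4, n),
        raw_ang_vel_mag=rng.uniform(0, 400, n),
    )


def _labels(n, event_frames):
    fo = np.zeros(n, dtype=np.int8)
    fo[list(event_frames)] = 1
    return LabeledSeries(fo=fo, mids=np.zeros(n, dtype=np.int8), fc=np.zeros(n, dtype=np.int8))


def brute_force_windows(matrix, labels, length):
    """Oracle slicer: explicit loop over every window."""
    center = (length - 1) // 2
    wins, targs, frames = [], [], []
    for start in range(matrix.shape[0] - length + 1):
        wins.append(matrix[start:start + length])
        frames.append(start + center)
        targs.append(labels[start + center])
    return np.array(wins), np.array(targs), np.array(frames)


class TestMakeWindows:
    def test_minimum_length_recording_gives_single_centered_window(self):
        n = WINDOW_LENGTH
        tensor = make_windows(_features(n), _labels(n, [125]), "FO")
        assert tensor.n_windows == 1
        assert tensor.source_frames[0] == 125
        assert tensor.targets[0] == 1

    def test_window_count_formula(self):
        tensor = make_windows(_features(300), _labels(300, []), "FO")
        assert tensor.n_windows == 300 - WINDOW_LENGTH + 1 == 50

    def test_matches_brute_force_slicer(self):
        n = 280
        features = _features(n, seed=3)
        labels = _labels(n, [130, 140, 150])
        tensor = make_windows(features, labels, "FO")
        wins, targs, frames = brute_force_windows(
            features.as_matrix(), labels.fo, WINDOW_LENGTH)
        np.testing.assert_allclose(tensor.windows, wins)
        np.testing.assert_array_equal(tensor.targets, targs)
        np.testing.assert_array_equal(tensor.source_frames, frames)

    def test_positive_count_is_in_range_events_only(self):
        n = 600
        # events at 50 and 520 are within 125 frames of an edge -> unreachable
        events = [50, 200, 300, 520]
        tensor = make_windows(_features(n), _labels(n, events), "FO")
        in_range = [f for f in events if 125 <= f <= n - 126]
        assert tensor.n_positive == len(in_range) == 2

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            make_windows(_features(250), _labels(250, []), "FO")


class TestBalance:
    def _tensor(self, n=700, events=(200, 300, 400)):
        return make_windows(_features(n), _labels(n, events), "FO")

    def test_none_is_identity(self):
        t = self._tensor()
        out = balance_windows(t, strategy="none")
        assert out is t

    def test_undersample_ratio_arithmetic(self):
        t = self._tensor()
        out = balance_windows(t, strategy="undersample", ratio=5.0, seed=1)
        assert out.n_positive == 3
        assert out.n_windows == 3 + 15

    def test_same_seed_same_selection(self):
        t = self._tensor()
        a = balance_windows(t, strategy="undersample", ratio=3.0, seed=9)
        b = balance_windows(t, strategy="undersample", ratio=3.0, seed=9)
        np.testing.assert_array_equal(a.source_frames, b.source_frames)

    def test_target_dilation_widens_positives(self):
        t = self._tensor(events=(300,))
        out = balance_windows(t, strategy="target_dilation", ratio=1.0,
                              dilation_radius=2, seed=0)
        assert out.n_positive == 5  # 300 +/- 2
        centers = out.source_frames[out.targets == 1]
        assert set(centers) == {298, 299, 300, 301, 302}

    def test_hard_negative_sampling_prefers_event_neighborhood(self):
        t = self._tensor(n=2000, events=(400,))
        out = balance_windows(t, strategy="undersample", ratio=20.0,
                              hard_negative_radius=50, hard_fraction=0.5, seed=4)
        negatives = out.source_frames[out.targets == 0]
        near = np.abs(negatives - 400) <= 50
        assert near.sum() >= 0.4 * negatives.size  # half budget, pool permitting

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            balance_windows(self._tensor(), strategy="smote")


class TestSplitAndConcat:
    def test_partition_is_disjoint_and_complete(self):
        tensors = {f"rec{i}": None for i in range(4)}
        train, val = split_by_recording(tensors, train_fraction=0.75, seed=0)
        assert len(train) == 3 and len(val) == 1
        assert set(train) | set(val) == set(tensors)
        assert not set(train) & set(val)

    def test_same_seed_same_partition(self):
        tensors = {f"rec{i}": None for i in range(6)}
        assert split_by_recording(tensors, seed=2) == split_by_recording(tensors, seed=2)

    def test_single_recording_rejected(self):
        with pytest.raises(ValueError):
            split_by_recording({"only": None})

    def test_window_counts_conserved_by_concatenation(self):
        a = make_windows(_features(300, 1), _labels(300, [150]), "FO")
        b = make_windows(_features(280, 2), _labels(280, [140]), "FO")
        both = concatenate_windows([a, b])
        assert both.n_windows == a.n_windows + b.n_windows
        assert both.n_positive == a.n_positive + b.n_positive
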