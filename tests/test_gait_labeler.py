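import numpy as np
import pytest

from gaitphase.gait_labeler import (
    GaitEvent,
    LabelerConfig,
    StepSegment,
    classify_step_type,
    detect_fo_fc,
    detect_mids,
    detect_turning,
    label_recording,
    make_label_channels,
    validate_steps,
)
from gaitphase.gait_synth import SynthConfig, synth_features
from gaitphase.preprocess import smooth_gaussian


def _step(fo, mids, fc, side="left", valid=True):
    return StepSegment(
        fo=GaitEvent(frame=fo, phase="FO", side=side, valid=valid),
        mids=GaitEvent(frame=mids, phase="MidS", side=side, valid=valid),
        fc=GaitEvent(frame=fc, phase="FC", side=side, valid=valid),
        valid=valid,
    )


class TestDetectMids:
    def test_flat_signal_yields_nothing(self):
        assert detect_mids(np.zeros(1000)).size == 0

    def test_recovers_generator_swing_peaks(self):
        features, truth, _ = synth_features(SynthConfig(seed=7))
        mids_truth = [e.frame for e in truth if e.side == "left" and e.phase == "MidS" and e.valid]
        detected = detect_mids(features["left"].ang_vel_mag)
        for frame in mids_truth:
            assert np.abs(detected - frame).min() <= 2

    def test_amplitude_scale_free(self, default_features):
        features, _, _ = default_features
        x = features["left"].ang_vel_mag
        np.testing.assert_array_equal(detect_mids(x), detect_mids(2.0 * x))


class TestDetectFoFc:
    def test_recovers_generator_flanks(self):
        features, truth, _ = synth_features(SynthConfig(seed=3))
        x = features["left"].ang_vel_mag
        triples = detect_fo_fc(x, detect_mids(x))
        steady = [e for e in truth if e.side == "left" and e.valid]
        fo_truth = sorted(e.frame for e in steady if e.phase == "FO")
        fc_truth = sorted(e.frame for e in steady if e.phase == "FC")
        det_fo = np.array(sorted(t[0] for t in triples))
        det_fc = np.array(sorted(t[2] for t in triples))
        for frame in fo_truth:
            assert np.abs(det_fo - frame).min() <= 3
        for frame in fc_truth:
            assert np.abs(det_fc - frame).min() <= 3

    def test_initial_step_with_reduced_fo_still_found(self):
        features, truth, _ = synth_features(SynthConfig(seed=11, n_bouts=1))
        x = features["left"].ang_vel_mag
        triples = detect_fo_fc(x, detect_mids(x))
        first_fo = min(e.frame for e in truth if e.side == "left" and e.phase == "FO")
        assert min(abs(t[0] - first_fo) for t in triples) <= 3

    def test_mids_near_edge_without_flank_dropped(self):
        # single bump at frame 10: a MidS with no left-flank peak
        x = np.zeros(500)
        x[8:13] = [1.0, 2.0, 3.0, 2.0, 1.0]
        x = smooth_gaussian(x, 9.0)
        assert detect_fo_fc(x, [10]) == []


class TestDetectTurning:
    def test_constant_heading_gives_no_intervals(self):
        assert detect_turning(np.full(2000, 1.27)) == []

    def test_heading_sweep_covered_by_one_interval(self):
        # both legs' direction cosines sweep 0.9 -> -0.9 over 2 s
        fs = 100.0
        n = 1000
        r11 = np.full(n, 0.9)
        sweep = np.linspace(np.arccos(0.9), np.arccos(-0.9), 200)
        r11[400:600] = np.cos(sweep)
        mag = smooth_gaussian(np.sqrt(2.0) * np.abs(r11), 9.0)
        intervals = detect_turning(mag, sampling_rate_hz=fs)
        assert len(intervals) == 1
        lo, hi = intervals[0]
        covered = max(0, min(hi, 600) - max(lo, 400))
        assert covered >= 0.8 * 200

    def test_two_separated_turns_give_two_intervals(self):
        features, _, turning = synth_features(SynthConfig(seed=5, n_bouts=3))
        assert len(turning) == 2
        detected = detect_turning(features["left"].rot_mat_mag)
        assert len(detected) == 2
        for (dlo, dhi), (tlo, thi) in zip(detected, turning):
            assert tlo - 50 <= dlo <= thi and tlo <= dhi <= thi + 50


class TestStepTyping:
    def test_six_step_bout_types(self):
        steps = [_step(100 * k, 100 * k + 20, 100 * k + 45) for k in range(6)]
        types = [s.step_type for s in classify_step_type(steps)]
        assert types == ["initial", "steady", "steady", "steady", "steady", "terminal"]

    def test_second_bout_starts_initial_after_rest(self):
        bout1 = [_step(100 * k, 100 * k + 20, 100 * k + 45) for k in range(3)]
        bout2 = [_step(600 + 100 * k, 620 + 100 * k, 645 + 100 * k) for k in range(3)]
        types = [s.step_type for s in classify_step_type(bout1 + bout2)]
        assert types[3] == "initial" and types[2] == "terminal"

    def test_lone_step_is_terminal(self):
        assert classify_step_type([_step(100, 120, 145)])[0].step_type == "terminal"


class TestValidation:
    def test_step_invalidated_iff_event_inside_turning(self):
        steps = [_step(100, 120, 145), _step(300, 320, 345)]
        out = validate_steps(steps, [(310, 330)])
        assert out[0].valid and not out[1].valid
        assert not out[1].mids.valid  # events share the step's flag

    def test_no_intervals_keeps_all_valid(self):
        steps = [_step(100, 120, 145)]
        assert all(s.valid for s in validate_steps(steps, []))


class TestLabelChannels:
    def test_channel_sums_count_valid_steps(self):
        steps = [_step(100 * k, 100 * k + 20, 100 * k + 45) for k in range(5)]
        labels = make_label_channels(steps, 1000)
        assert labels.fo.sum() == labels.mids.sum() == labels.fc.sum() == 5
        assert set(np.unique(labels.fo)) <= {0, 1}

    def test_invalid_steps_excluded(self):
        steps = [_step(100, 120, 145, valid=False)]
        labels = make_label_channels(steps, 300)
        assert labels.fo.sum() == labels.mids.sum() == labels.fc.sum() == 0

    def test_event_beyond_series_rejected(self):
        with pytest.raises(ValueError):
            make_label_channels([_step(100, 120, 145)], 120)


class TestEndToEnd:
    def test_full_labeling_of_default_trial(self, default_features):
        features, truth, turning = default_features
        for side in ("left", "right"):
            steps, labels, detected = label_recording(features[side])
            # ordering invariant
            for s in steps:
                assert s.fo.frame < s.mids.frame < s.fc.frame
            # equal per-phase counts
            n = sum(s.valid for s in steps)
            assert labels.fo.sum() == labels.mids.sum() == labels.fc.sum() == n
            # no labeled event inside a truth turning interval
            for channel in (labels.fo, labels.mids, labels.fc):
                for lo, hi in turning:
                    assert channel[lo:hi].sum() == 0

    def test_in_place_stepping_marked_invalid_in_truth(self):
        cfg = SynthConfig(seed=9, n_bouts=1, in_place_segments=((20.0, 4),))
        _, truth, _ = synth_features(cfg)
        invalid = [e for e in truth if not e.valid]
        assert len(invalid) == 12  # 4 steps x 3 phases
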