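"""Synthetic bilateral IMU gait recordings with ground-truth events.

Emulates, at signal-morphology level, the movement repertoire the
pipeline must handle: straight walking bouts at configurable cadence
(slow / convenient / fast), 180°/360° turns with small steps, optional
in-place stepping, and gait initiation/termination.  Each step writes two
negative pulses (toe-off and heel-strike surrogates) flanking one positive
swing pulse onto Gyr_Z, so the angular-velocity magnitude shows the
characteristic FO–MidS–FC triple-peak; free-acceleration bursts coincide
with FO and FC; the direction-cosine element is cos(heading), constant
during straight bouts and sweeping during turns.  Pulses are Gaussian
bumps, not recorded gait shapes — downstream code may only rely on the
triple-peak morphology, which is exactly what they provide.

Step-type morphology: an initial step's FO pulse is attenuated (70% of
steady) and a terminal step's FC pulse strongly so (30% of steady), the
two shapes that make naive peak pickers fail at bout boundaries.

Ground truth records the exact pulse-center frames; events inside turning
or in-place segments are marked invalid.  Everything is driven by one
seed, so identical configs produce bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitphase.features import build_feature_set
from gaitphase.gait_labeler import GaitEvent, LabeledSeries
from gaitphase.imu_io import ImuRecording, PairedRecording
from gaitphase.preprocess import PreprocessConfig, clean_recording
from gaitphase.windowing import WindowTensor, balance_windows, concatenate_windows, make_windows

#: Within-step event timing as fractions of the per-leg step period
#: (stride time): the FO->FC swing occupies ~45% of the stride
#: with mid-swing near its middle, close to the stance/swing split of
#: normal gait while keeping the three smoothed peaks resolvable at the
#: fastest protocol cadence.
_MIDS_FRACTION = 0.20
_FC_FRACTION = 0.45

#: Gaussian pulse widths (seconds).
_GYR_PULSE_SIGMA_S = 0.04
_ACC_PULSE_SIGMA_S = 0.04


@dataclass(frozen=True)
class StepTemplate:
    """Peak amplitudes (deg/s) of the FO / MidS / FC pulses of one step type."""

    fo: float
    mids: float
    fc: float


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of one synthetic trial.

    The default is a straight-walk-and-return trial: two 8-step-per-leg
    bouts at a convenient 1.0 steps/s per leg, separated by a 2.5 s 180°
    turn taken with small steps, with 2 s rests around the turn.  Turning
    segments are placed automatically between consecutive bouts unless
    given explicitly (seconds-based (start_s, duration_s, angle_deg)
    triples).  ``in_place_segments`` adds bursts of stepping without
    displacement ((start_s, n_steps) pairs); those events are invalid
    truth, like turn steps.
    """

    seed: int = 0
    sampling_rate_hz: float = 100.0
    n_steps_per_bout: int = 8
    n_bouts: int = 2
    cadence_steps_per_s: float | tuple[float, ...] = 1.0
    step_templates: dict = field(default_factory=lambda: {
        "initial": StepTemplate(fo=210.0, mids=420.0, fc=260.0),
        "steady": StepTemplate(fo=300.0, mids=420.0, fc=260.0),
        "terminal": StepTemplate(fo=300.0, mids=420.0, fc=78.0),
    })
    turn_step_amplitude: float = 0.55    # fraction of steady amplitudes
    turn_step_period_s: float = 0.7
    noise_sd_gyr: float = 8.0            # deg/s
    noise_sd_acc: float = 0.5            # m/s²
    noise_sd_r11: float = 0.01
    #: Step-to-step timing variability as a fraction of the step period;
    #: healthy over-ground walking shows a step-time CV of roughly 2-4%,
    #: and a strictly metronomic simulation would let sequence models
    #: exploit periodicity instead of step morphology.
    step_time_jitter: float = 0.03
    acc_burst_fo: float = 12.0           # m/s²
    acc_burst_fc: float = 20.0
    rest_gap_s: float = 2.0
    lead_s: float = 3.0                  # quiet standing before/after
    turn_duration_s: float = 2.5
    turn_angle_deg: float = 180.0
    heading0_rad: float = float(np.arccos(0.9))
    turning_segments: tuple | None = None
    in_place_segments: tuple = ()

    def __post_init__(self) -> None:
        if self.n_steps_per_bout < 1 or self.n_bouts < 1:
            raise ValueError("need at least one step and one bout")
        if self.rest_gap_s < 2.0:
            raise ValueError("rest_gap_s below the 2 s protocol rest")
        for c in self.cadences:
            if not 0 < c <= 1.4:
                raise ValueError(
                    f"cadence {c} steps/s per leg is infeasible: step pulses would overlap"
                )

    @property
    def cadences(self) -> tuple[float, ...]:
        c = self.cadence_steps_per_s
        if isinstance(c, (int, float)):
            return (float(c),) * self.n_bouts
        if len(c) != self.n_bouts:
            raise ValueError("need one cadence per bout")
        return tuple(float(v) for v in c)


def _gauss_pulse(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def synth_walk(cfg: SynthConfig | None = None):
    """Generate one synthetic trial.

    Returns ``(paired, truth, turning_truth)``: the bilateral
    :class:`~gaitphase.imu_io.PairedRecording`, the ground-truth
    :class:`~gaitphase.gait_labeler.GaitEvent` list for both legs (invalid
    during turning / in-place segments) and the true turning intervals as
    (start_frame, end_frame) pairs.
    """
    cfg = cfg or SynthConfig()
    fs = cfg.sampling_rate_hz
    rng = np.random.default_rng(cfg.seed)
    # separate stream so timing jitter does not shift the sensor-noise draws
    jitter_rng = np.random.default_rng((cfg.seed, 0x9A17))

    # ---- timeline: bout start times, auto-placed turns ------------------
    bout_starts: list[float] = []
    turn_specs: list[tuple[float, float, float]] = []  # (start_s, duration_s, angle_deg)
    t_cursor = cfg.lead_s
    for b, cadence in enumerate(cfg.cadences):
        bout_starts.append(t_cursor)
        # per-leg steps at period 1/cadence; right leg offset by half period
        bout_len = (cfg.n_steps_per_bout - 1 + _FC_FRACTION) / cadence + 0.5 / cadence
        t_cursor += bout_len + cfg.rest_gap_s
        if b < len(cfg.cadences) - 1:
            if cfg.turning_segments is None:
                turn_specs.append((t_cursor, cfg.turn_duration_s, cfg.turn_angle_deg))
            t_cursor += cfg.turn_duration_s + cfg.rest_gap_s
    if cfg.turning_segments is not None:
        turn_specs = [tuple(map(float, seg)) for seg in cfg.turning_segments]
    total_s = t_cursor + cfg.lead_s
    for start_s, duration_s, _ in turn_specs:
        total_s = max(total_s, start_s + duration_s + cfg.lead_s)
    for start_s, n_steps in cfg.in_place_segments:
        total_s = max(total_s, start_s + n_steps * cfg.turn_step_period_s + cfg.lead_s)
    n_frames = int(round(total_s * fs))
    t = np.arange(n_frames) / fs

    gyr_z = {"left": np.zeros(n_frames), "right": np.zeros(n_frames)}
    acc_z = {"left": np.zeros(n_frames), "right": np.zeros(n_frames)}
    truth: list[GaitEvent] = []

    def add_step(side: str, fo_s: float, period_s: float, tpl: StepTemplate, valid: bool) -> None:
        fo_s = fo_s + jitter_rng.normal(0.0, cfg.step_time_jitter * period_s)
        mids_s = fo_s + _MIDS_FRACTION * period_s
        fc_s = fo_s + _FC_FRACTION * period_s
        sig = _GYR_PULSE_SIGMA_S
        gyr_z[side] -= tpl.fo * _gauss_pulse(t, fo_s, sig)
        gyr_z[side] += tpl.mids * _gauss_pulse(t, mids_s, sig)
        gyr_z[side] -= tpl.fc * _gauss_pulse(t, fc_s, sig)
        acc_z[side] += cfg.acc_burst_fo * _gauss_pulse(t, fo_s, _ACC_PULSE_SIGMA_S)
        acc_z[side] += cfg.acc_burst_fc * _gauss_pulse(t, fc_s, _ACC_PULSE_SIGMA_S)
        for phase, when in (("FO", fo_s), ("MidS", mids_s), ("FC", fc_s)):
            frame = int(round(when * fs))
            if 0 <= frame < n_frames:
                truth.append(GaitEvent(frame=frame, phase=phase, side=side, valid=valid))

    # ---- straight bouts --------------------------------------------------
    for start_s, cadence in zip(bout_starts, cfg.cadences):
        period = 1.0 / cadence
        for side, offset in (("left", 0.0), ("right", 0.5 * period)):
            for k in range(cfg.n_steps_per_bout):
                if k == 0:
                    tpl = cfg.step_templates["initial"]
                elif k == cfg.n_steps_per_bout - 1:
                    tpl = cfg.step_templates["terminal"]
                else:
                    tpl = cfg.step_templates["steady"]
                add_step(side, start_s + offset + k * period, period, tpl, valid=True)

    # ---- turning and in-place steps (invalid truth) ----------------------
    steady = cfg.step_templates["steady"]
    small = StepTemplate(
        fo=cfg.turn_step_amplitude * steady.fo,
        mids=cfg.turn_step_amplitude * steady.mids,
        fc=cfg.turn_step_amplitude * steady.fc,
    )
    for start_s, duration_s, _angle in turn_specs:
        # steps confined to the central 70% of the turn, where the heading
        # deviation is detectable
        core_start = start_s + 0.15 * duration_s
        core = 0.7 * duration_s
        n_steps = max(1, int(core / cfg.turn_step_period_s))
        for k in range(n_steps):
            side = ("left", "right")[k % 2]
            add_step(side, core_start + k * cfg.turn_step_period_s,
                     cfg.turn_step_period_s, small, valid=False)
    for start_s, n_steps in cfg.in_place_segments:
        for k in range(int(n_steps)):
            side = ("left", "right")[k % 2]
            add_step(side, start_s + k * cfg.turn_step_period_s,
                     cfg.turn_step_period_s, small, valid=False)

    # ---- heading / direction cosine --------------------------------------
    heading = np.full(n_frames, cfg.heading0_rad)
    for start_s, duration_s, angle in sorted(turn_specs):
        a = max(int(round(start_s * fs)), 0)
        b = min(int(round((start_s + duration_s) * fs)), n_frames)
        heading[a:b] += np.linspace(0.0, np.deg2rad(angle), max(b - a, 1))
        heading[b:] += np.deg2rad(angle)
    r11 = np.cos(heading)

    turning_truth = [
        (max(int(round(s * fs)), 0), min(int(round((s + d) * fs)), n_frames))
        for s, d, _ in sorted(turn_specs)
    ]

    # ---- assemble with sensor noise --------------------------------------
    recordings = {}
    for side in ("left", "right"):
        gyr = rng.normal(0.0, cfg.noise_sd_gyr, size=(n_frames, 3))
        gyr[:, 2] += gyr_z[side]
        acc = rng.normal(0.0, cfg.noise_sd_acc, size=(n_frames, 3))
        acc[:, 2] += acc_z[side]
        r = np.clip(r11 + rng.normal(0.0, cfg.noise_sd_r11, size=n_frames), -1.0, 1.0)
        recordings[side] = ImuRecording(
            side=side, sampling_rate_hz=fs, gyr=gyr, free_acc=acc, rot_mat_11=r,
        )
    paired = PairedRecording(left=recordings["left"], right=recordings["right"])
    truth.sort(key=lambda e: (e.frame, e.side, e.phase))
    return paired, truth, turning_truth


def truth_label_channels(truth: list[GaitEvent], side: str, n_frames: int) -> LabeledSeries:
    """Binary per-phase channels from valid ground-truth events of one leg."""
    channels = {"FO": np.zeros(n_frames, dtype=np.int8),
                "MidS": np.zeros(n_frames, dtype=np.int8),
                "FC": np.zeros(n_frames, dtype=np.int8)}
    for e in truth:
        if e.side == side and e.valid:
            channels[e.phase][e.frame] = 1
    return LabeledSeries(fo=channels["FO"], mids=channels["MidS"], fc=channels["FC"])


def synth_features(cfg: SynthConfig, preprocess_cfg: PreprocessConfig | None = None):
    """Convenience: simulate, clean and featurize one trial.

    Returns ``(features_by_side, truth, turning_truth)``.
    """
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    paired, truth, turning = synth_walk(cfg)
    cleaned = PairedRecording(
        left=clean_recording(paired.left, preprocess_cfg),
        right=clean_recording(paired.right, preprocess_cfg),
    )
    features = {side: build_feature_set(cleaned, side, preprocess_cfg)
                for side in ("left", "right")}
    return features, truth, turning


def synth_training_set(cfgs: list[SynthConfig], phase: str,
                       balance_strategy: str = "none", ratio: float = 5.0,
                       dilation_radius: int = 2,
                       hard_negative_radius: int | None = None,
                       hard_fraction: float = 0.5, seed: int = 0,
                       sides: tuple[str, ...] = ("left", "right")) -> WindowTensor:
    """Windows pooled over simulated trials with truth-derived targets.

    Targets come from the generator's ground truth, not from the labeler,
    giving a labeler-independent training surface.  Balancing (see
    :func:`~gaitphase.windowing.balance_windows`) is applied per trial and
    leg with a seed derived from ``seed`` so the composition is
    reproducible; all truth events of the leg — including events
    invalidated by turning — serve as hard-negative centers.
    """
    tensors: list[WindowTensor] = []
    counter = 0
    for cfg in cfgs:
        features, truth, _ = synth_features(cfg)
        for side in sides:
            labels = truth_label_channels(truth, side, features[side].n_frames)
            tensor = make_windows(features[side], labels, phase)
            tensor = balance_windows(tensor, strategy=balance_strategy, ratio=ratio,
                                     dilation_radius=dilation_radius,
                                     hard_negative_radius=hard_negative_radius,
                                     hard_fraction=hard_fraction,
                                     hard_centers=[e.frame for e in truth if e.side == side],
                                     seed=(seed * 1000003 + counter) % (2**31))
            tensors.append(tensor)
            counter += 1
    return concatenate_windows(tensors)
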