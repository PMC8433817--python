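"""Deterministic peak-based labeling of FO, MidS and FC.

On the smoothed angular-velocity magnitude each step appears as a
triple-peak: a swing-phase maximum (mid-swing, MidS) flanked by a smaller
peak when the foot leaves the ground (foot-off, FO) and another when it
contacts the ground again (foot-contact, FC).  MidS peaks are found first
— they dominate their neighborhood — and FO/FC are then the most
prominent flanking peaks on either side.  Steps are typed by their
position in a walking bout (initial / steady / terminal) and invalidated
when they fall inside a turning interval detected from the bilateral
rotation-matrix magnitude; only valid steps contribute to the binary
per-phase label channels used for model training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from gaitphase.features import FeatureSet
from gaitphase.imu_io import PHASES, SIDES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaitEvent:
    """A single labeled gait-phase timepoint (0-based frame index)."""

    frame: int
    phase: str  # FO | MidS | FC
    side: str   # left | right
    valid: bool = True

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.frame < 0:
            raise ValueError("frame must be nonnegative")


@dataclass(frozen=True)
class StepSegment:
    """A FO -> MidS -> FC step with a type and validity flag."""

    fo: GaitEvent
    mids: GaitEvent
    fc: GaitEvent
    step_type: str = "steady"  # initial | steady | terminal
    valid: bool = True

    def __post_init__(self) -> None:
        if not (self.fo.frame < self.mids.frame < self.fc.frame):
            raise ValueError("step events must satisfy FO < MidS < FC")
        if not (self.fo.side == self.mids.side == self.fc.side):
            raise ValueError("step events must share a side")

    @property
    def events(self) -> tuple[GaitEvent, GaitEvent, GaitEvent]:
        return (self.fo, self.mids, self.fc)

    def with_flags(self, step_type: str | None = None, valid: bool | None = None) -> "StepSegment":
        st = self.step_type if step_type is None else step_type
        v = self.valid if valid is None else valid
        return StepSegment(
            fo=replace(self.fo, valid=v),
            mids=replace(self.mids, valid=v),
            fc=replace(self.fc, valid=v),
            step_type=st,
            valid=v,
        )


@dataclass(frozen=True)
class LabelerConfig:
    """Detection parameters (the frame-rate-free ones are in seconds).

    None of these are dictated by the underlying event definitions; they
    are engineering defaults and every run should log them.
    """

    mids_min_prominence: float = 0.1      # fraction of signal range
    mids_min_separation_s: float = 0.4
    flank_search_max_s: float = 0.8
    flank_min_prominence: float = 0.02    # fraction of signal range
    turning_threshold: float = 0.25       # RotMatMag deviation from baseline
    turning_hysteresis: float = 0.2       # exit threshold as fraction of entry
    turning_min_duration_s: float = 0.5
    rest_gap_s: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "mids_min_prominence", "mids_min_separation_s", "flank_search_max_s",
            "flank_min_prominence", "turning_threshold", "turning_hysteresis",
            "turning_min_duration_s", "rest_gap_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class LabeledSeries:
    """Binary per-phase label channels: 1 exactly at valid event frames."""

    fo: np.ndarray
    mids: np.ndarray
    fc: np.ndarray

    def channel(self, phase: str) -> np.ndarray:
        return {"FO": self.fo, "MidS": self.mids, "FC": self.fc}[phase]

    @property
    def n_frames(self) -> int:
        return self.fo.shape[0]


def detect_mids(ang_vel_mag_smoothed: np.ndarray, cfg: LabelerConfig | None = None,
                sampling_rate_hz: float = 100.0) -> np.ndarray:
    """Frames of mid-swing peaks on the smoothed angular-velocity magnitude.

    A MidS candidate is a local maximum whose prominence exceeds
    ``mids_min_prominence`` of the signal range; candidates closer than
    ``mids_min_separation_s`` are resolved in favor of the higher peak,
    which also discards the smaller FO/FC flank peaks.  Detection is
    amplitude-scale-free (prominence is range-relative).
    """
    cfg = cfg or LabelerConfig()
    x = np.asarray(ang_vel_mag_smoothed, dtype=float)
    rng = x.max() - x.min()
    if rng <= 0:
        return np.array([], dtype=int)
    distance = max(1, round(cfg.mids_min_separation_s * sampling_rate_hz))
    peaks, _ = find_peaks(x, prominence=cfg.mids_min_prominence * rng, distance=distance)
    return peaks.astype(int)


def detect_fo_fc(ang_vel_mag_smoothed: np.ndarray, mids_frames, cfg: LabelerConfig | None = None,
                 sampling_rate_hz: float = 100.0) -> list[tuple[int, int, int]]:
    """Flanking FO/FC peaks for each MidS; returns (fo, mids, fc) triples.

    The search window extends at most ``flank_search_max_s`` from the MidS
    frame but never past the midpoint to the adjacent MidS, so a flank is
    always attributed to its own step (the next step's FO can otherwise be
    more prominent than this step's FC and lie inside the window).  Within
    the window the most prominent local maximum wins; ties break toward
    the frame nearest MidS.  A MidS lacking either flank is dropped.
    """
    cfg = cfg or LabelerConfig()
    x = np.asarray(ang_vel_mag_smoothed, dtype=float)
    mids_frames = np.asarray(mids_frames, dtype=int)
    rng = x.max() - x.min()
    if rng <= 0 or mids_frames.size == 0:
        return []
    max_flank = max(1, round(cfg.flank_search_max_s * sampling_rate_hz))
    # flank candidates: every local maximum above a permissive prominence
    cand, props = find_peaks(x, prominence=cfg.flank_min_prominence * rng)
    prom = props["prominences"]

    def best_flank(lo: int, hi: int, mids: int) -> int | None:
        sel = (cand > lo) & (cand < hi) & (cand != mids)
        if not sel.any():
            return None
        frames, proms = cand[sel], prom[sel]
        best = proms.max()
        tied = frames[proms >= best - 1e-12 * max(best, 1.0)]
        return int(tied[np.argmin(np.abs(tied - mids))])

    triples: list[tuple[int, int, int]] = []
    for k, m in enumerate(mids_frames):
        gap_l = m - mids_frames[k - 1] if k > 0 else 2 * max_flank
        gap_r = mids_frames[k + 1] - m if k < mids_frames.size - 1 else 2 * max_flank
        lo = m - min(max_flank, gap_l // 2)
        hi = m + min(max_flank, gap_r // 2)
        fo = best_flank(lo, m, m)
        fc = best_flank(m, hi, m)
        if fo is None or fc is None:
            logger.info("MidS at frame %d dropped: missing %s flank", m,
                        "left" if fo is None else "right")
            continue
        triples.append((fo, int(m), fc))
    return triples


def detect_turning(rot_mat_mag_smoothed: np.ndarray, cfg: LabelerConfig | None = None,
                   sampling_rate_hz: float = 100.0) -> list[tuple[int, int]]:
    """Maximal turning intervals [start, end) from the bilateral RotMatMag.

    Two-pass baseline: candidate frames are those deviating from the global
    median by more than ``turning_threshold``; the straight-walking
    baseline is then re-estimated as the median of the remaining frames.
    Final intervals are entered where the deviation from that baseline
    exceeds the threshold for at least ``turning_min_duration_s`` and
    extended outward (hysteresis) while it stays above
    ``turning_hysteresis``×threshold, which captures the full extent of a
    gradual heading sweep.
    """
    cfg = cfg or LabelerConfig()
    x = np.asarray(rot_mat_mag_smoothed, dtype=float)
    if x.size == 0:
        return []
    dev = np.abs(x - np.median(x))
    inside = dev <= cfg.turning_threshold
    baseline = np.median(x[inside]) if inside.any() else np.median(x)
    dev = np.abs(x - baseline)
    core = dev > cfg.turning_threshold
    if not core.any():
        return []
    low = dev > cfg.turning_hysteresis * cfg.turning_threshold
    min_len = max(1, round(cfg.turning_min_duration_s * sampling_rate_hz))
    intervals: list[tuple[int, int]] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], core.astype(int), [0]))))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start < min_len:
            continue
        while start > 0 and low[start - 1]:
            start -= 1
        while end < x.size and low[end]:
            end += 1
        if intervals and start <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], end))
        else:
            intervals.append((int(start), int(end)))
    return intervals


def classify_step_type(steps: list[StepSegment], cfg: LabelerConfig | None = None,
                       sampling_rate_hz: float = 100.0) -> list[StepSegment]:
    """Assign initial / steady / terminal types by inter-step rest gaps.

    A step is *initial* if no step ends within ``rest_gap_s`` before its
    FO and *terminal* if no step begins within ``rest_gap_s`` after its
    FC; a lone step qualifying as both is labeled terminal.
    """
    cfg = cfg or LabelerConfig()
    gap = cfg.rest_gap_s * sampling_rate_hz
    steps = sorted(steps, key=lambda s: s.fo.frame)
    out: list[StepSegment] = []
    for k, step in enumerate(steps):
        is_initial = k == 0 or step.fo.frame - steps[k - 1].fc.frame > gap
        is_terminal = k == len(steps) - 1 or steps[k + 1].fo.frame - step.fc.frame > gap
        if is_terminal:
            step_type = "terminal"
        elif is_initial:
            step_type = "initial"
        else:
            step_type = "steady"
        out.append(step.with_flags(step_type=step_type))
    return out


def validate_steps(steps: list[StepSegment], turning_intervals) -> list[StepSegment]:
    """Invalidate any step with an event frame inside a turning interval."""
    out = []
    for step in steps:
        invalid = any(
            lo <= e.frame < hi for e in step.events for lo, hi in turning_intervals
        )
        out.append(step.with_flags(valid=not invalid))
    return out


def make_label_channels(steps: list[StepSegment], n_frames: int) -> LabeledSeries:
    """Binary per-phase channels with 1 exactly at valid events' frames."""
    channels = {p: np.zeros(n_frames, dtype=np.int8) for p in PHASES}
    for step in steps:
        if not step.valid:
            continue
        for event in step.events:
            if event.frame >= n_frames:
                raise ValueError(f"event frame {event.frame} beyond series length {n_frames}")
            channels[event.phase][event.frame] = 1
    return LabeledSeries(fo=channels["FO"], mids=channels["MidS"], fc=channels["FC"])


def label_recording(features: FeatureSet, cfg: LabelerConfig | None = None):
    """Run the full labeling chain for one leg.

    Returns ``(steps, labels, turning_intervals)`` where *steps* carry
    types and validity, *labels* is the :class:`LabeledSeries` over valid
    steps only, and *turning_intervals* are the detected heading-change
    intervals.
    """
    cfg = cfg or LabelerConfig()
    fs = features.sampling_rate_hz
    mids = detect_mids(features.ang_vel_mag, cfg, fs)
    triples = detect_fo_fc(features.ang_vel_mag, mids, cfg, fs)
    steps = [
        StepSegment(
            fo=GaitEvent(frame=fo, phase="FO", side=features.side),
            mids=GaitEvent(frame=m, phase="MidS", side=features.side),
            fc=GaitEvent(frame=fc, phase="FC", side=features.side),
        )
        for fo, m, fc in triples
    ]
    steps = classify_step_type(steps, cfg, fs)
    turning = detect_turning(features.rot_mat_mag, cfg, fs)
    steps = validate_steps(steps, turning)
    labels = make_label_channels(steps, features.n_frames)
    return steps, labels, turning
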