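"""Center-labeled sliding windows for training and inference.

Each training example is a contiguous slice of L = 251 feature frames
(~2.5 s at 100 Hz) whose binary target states whether the gait phase of
interest occurs at the slice's middle frame (0-based offset 125).  Every
possible window of a recording is generated — N = n_frames − L + 1 — and
windows never cross recording boundaries.  Because labeled event frames
are a ~0.1–1% minority, balancing strategies (seeded negative
undersampling, optional target dilation around events) are provided for
desk-scale training; strategy ``none`` preserves the raw imbalanced
stream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from gaitphase.features import FeatureSet
from gaitphase.gait_labeler import LabeledSeries

WINDOW_LENGTH = 251
CENTER_OFFSET = (WINDOW_LENGTH - 1) // 2


@dataclass(frozen=True)
class WindowTensor:
    """Sliding windows (N, L, C), binary center-frame targets and provenance."""

    windows: np.ndarray        # (N, L, C) float
    targets: np.ndarray        # (N,) int8
    source_frames: np.ndarray  # (N,) center frame of each window
    phase: str
    center_offset: int = CENTER_OFFSET

    def __post_init__(self) -> None:
        n, L, _ = self.windows.shape
        if L % 2 != 1 or self.center_offset != (L - 1) // 2:
            raise ValueError("window length must be odd with the target at its center")
        if self.targets.shape != (n,) or self.source_frames.shape != (n,):
            raise ValueError("targets/source_frames must have one entry per window")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_positive(self) -> int:
        return int(self.targets.sum())


def make_windows(features: FeatureSet, labels: LabeledSeries, phase: str,
                 length: int = WINDOW_LENGTH, scaled: bool = True) -> WindowTensor:
    """All length-L windows of a recording with center-frame targets.

    The feature matrix is the (AngVelMag, FreeAccMag, RotMatMag) triple,
    min–max scaled per recording by default.  Window i covers frames
    [i, i+L) and its target is the phase's label at frame i + (L−1)/2, so
    events within (L−1)/2 frames of either edge can never be positives.
    """
    if length % 2 != 1:
        raise ValueError("window length must be odd")
    matrix = features.as_matrix(scaled=scaled)
    n = matrix.shape[0]
    if n < length:
        raise ValueError(f"recording has {n} frames; need at least {length}")
    center = (length - 1) // 2
    windows = np.lib.stride_tricks.sliding_window_view(matrix, length, axis=0)
    windows = np.ascontiguousarray(windows.transpose(0, 2, 1))  # (N, L, C)
    source_frames = np.arange(center, n - center)
    targets = labels.channel(phase)[source_frames].astype(np.int8)
    return WindowTensor(windows=windows, targets=targets,
                        source_frames=source_frames, phase=phase, center_offset=center)


def balance_windows(tensor: WindowTensor, strategy: str = "undersample",
                    ratio: float = 5.0, dilation_radius: int = 2,
                    hard_negative_radius: int | None = None,
                    hard_fraction: float = 0.5, seed: int = 0,
                    hard_centers=None) -> WindowTensor:
    """Rebalance the positive/negative composition of a window tensor.

    ``none``
        identity.
    ``undersample``
        keep all positives plus a seeded subset of negatives of size
        ``ratio`` × positives (window order preserved).  When
        ``hard_negative_radius`` is set, up to ``hard_fraction`` of the
        negative budget is drawn from *hard* negatives — center frames
        within that radius of a positive, or of any frame in
        ``hard_centers`` (e.g. events invalidated by turning, which the
        model must learn to suppress) — which teaches the model to
        localize events sharply instead of merely recognizing gait
        context; the remainder is sampled uniformly.
    ``target_dilation``
        first mark targets positive within ±``dilation_radius`` frames of
        each event (events are sparse, so dilated blocks never merge in
        practice), then undersample as above.  Dilation turns the
        single-frame target into a short plateau, which both eases
        learning and matches the tolerance of event-level scoring.
    """
    if strategy == "none":
        return tensor
    if strategy not in ("undersample", "target_dilation"):
        raise ValueError(f"unknown balancing strategy {strategy!r}")
    targets = tensor.targets.astype(np.int8)
    if strategy == "target_dilation":
        pos = np.flatnonzero(targets)
        dilated = targets.copy()
        for p in pos:
            lo = max(0, p - dilation_radius)
            dilated[lo:p + dilation_radius + 1] = 1
        targets = dilated
    pos_idx = np.flatnonzero(targets == 1)
    neg_idx = np.flatnonzero(targets == 0)
    rng = np.random.default_rng(seed)
    n_neg = min(neg_idx.size, int(round(ratio * pos_idx.size)))
    if hard_negative_radius is not None and pos_idx.size and n_neg:
        near = np.zeros(tensor.n_windows, dtype=bool)
        for p in pos_idx:
            lo = max(0, p - hard_negative_radius)
            near[lo:p + hard_negative_radius + 1] = True
        if hard_centers is not None:
            frames = tensor.source_frames
            for c in hard_centers:
                near |= np.abs(frames - c) <= hard_negative_radius
        hard_idx = neg_idx[near[neg_idx]]
        easy_idx = neg_idx[~near[neg_idx]]
        n_hard = min(hard_idx.size, int(round(hard_fraction * n_neg)))
        n_easy = min(easy_idx.size, n_neg - n_hard)
        keep_neg = np.concatenate([
            rng.choice(hard_idx, size=n_hard, replace=False),
            rng.choice(easy_idx, size=n_easy, replace=False),
        ])
    else:
        keep_neg = rng.choice(neg_idx, size=n_neg, replace=False)
    keep = np.sort(np.concatenate([pos_idx, keep_neg]))
    return replace(
        tensor,
        windows=tensor.windows[keep],
        targets=targets[keep],
        source_frames=tensor.source_frames[keep],
    )


def split_by_recording(tensors: dict, train_fraction: float = 0.75, seed: int = 0):
    """Partition recordings (not windows) into train and validation sets.

    Returns ``(train_keys, val_keys)`` — disjoint, covering all keys; at
    least one recording lands on each side.  Splitting at recording
    granularity keeps windows from one trial out of both sides.
    """
    keys = sorted(tensors)
    if len(keys) < 2:
        raise ValueError("need at least 2 recordings to split")
    rng = np.random.default_rng(seed)
    order = [keys[i] for i in rng.permutation(len(keys))]
    n_train = int(round(train_fraction * len(keys)))
    n_train = min(max(n_train, 1), len(keys) - 1)
    return sorted(order[:n_train]), sorted(order[n_train:])


def concatenate_windows(tensors: list[WindowTensor]) -> WindowTensor:
    """Stack window tensors of the same phase (source frames kept per tensor)."""
    phases = {t.phase for t in tensors}
    if len(phases) != 1:
        raise ValueError("cannot concatenate tensors of different phases")
    return WindowTensor(
        windows=np.concatenate([t.windows for t in tensors]),
        targets=np.concatenate([t.targets for t in tensors]),
        source_frames=np.concatenate([t.source_frames for t in tensors]),
        phase=tensors[0].phase,
        center_offset=tensors[0].center_offset,
    )
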