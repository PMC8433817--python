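"""Orientation-invariant magnitude features.

A shank-mounted sensor's mediolateral gyroscope axis carries the classic
gait-event peaks, but only if the sensor is mounted in a known orientation.
Taking Euclidean norms removes that dependence: the angular-velocity
magnitude (AngVelMag) and free-acceleration magnitude (FreeAccMag) are
invariant under any fixed rotation of the sensor axes.  The bilateral
rotation-matrix magnitude (RotMatMag) combines the direction-cosine [1][1]
element of both legs, sqrt(left² + right²), and deviates from its
straight-walking level whenever heading changes — the turning cue.

The per-leg model input is the triple (smoothed AngVelMag, smoothed
FreeAccMag, smoothed bilateral RotMatMag), min–max scaled per recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gaitphase.imu_io import PairedRecording
from gaitphase.preprocess import PreprocessConfig, smooth_gaussian

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class FeatureSet:
    """Per-frame smoothed magnitude features for one leg.

    ``rot_mat_mag`` is bilateral (shared between the two legs' feature
    sets); the other two channels belong to ``side``.  ``raw_ang_vel_mag``
    keeps the unsmoothed norm for event-time refinement.
    """

    side: str
    ang_vel_mag: np.ndarray    # deg/s, smoothed
    free_acc_mag: np.ndarray   # m/s², smoothed
    rot_mat_mag: np.ndarray    # dimensionless, smoothed, <= sqrt(2)
    raw_ang_vel_mag: np.ndarray
    sampling_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        n = self.ang_vel_mag.shape[0]
        for name in ("free_acc_mag", "rot_mat_mag", "raw_ang_vel_mag"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length differs from ang_vel_mag")

    @property
    def n_frames(self) -> int:
        return self.ang_vel_mag.shape[0]

    def as_matrix(self, scaled: bool = True) -> np.ndarray:
        """Stack the three channels as an (n_frames, 3) model-input matrix."""
        cols = (self.ang_vel_mag, self.free_acc_mag, self.rot_mat_mag)
        if scaled:
            cols = tuple(scale_unit_interval(c) for c in cols)
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "ang_vel_mag": self.ang_vel_mag,
                "free_acc_mag": self.free_acc_mag,
                "rot_mat_mag": self.rot_mat_mag,
                "side": self.side,
            }
        )


def ang_vel_mag(gx, gy, gz) -> np.ndarray:
    """Angular-velocity magnitude sqrt(gx² + gy² + gz²), deg/s."""
    return np.sqrt(np.square(gx) + np.square(gy) + np.square(gz))


def free_acc_mag(ax, ay, az) -> np.ndarray:
    """Free-acceleration magnitude sqrt(ax² + ay² + az²), m/s²."""
    return np.sqrt(np.square(ax) + np.square(ay) + np.square(az))


def rot_mat_mag(left_r11, right_r11) -> np.ndarray:
    """Bilateral direction-cosine magnitude sqrt(left² + right²).

    Inputs must already be cleaned to [-1, 1]; the result is <= sqrt(2).
    """
    left_r11 = np.asarray(left_r11, dtype=float)
    right_r11 = np.asarray(right_r11, dtype=float)
    if np.any(np.abs(left_r11) > 1.0) or np.any(np.abs(right_r11) > 1.0):
        raise ValueError("direction-cosine values outside [-1, 1]; clean the recording first")
    return np.sqrt(np.square(left_r11) + np.square(right_r11))


def scale_unit_interval(series: np.ndarray) -> np.ndarray:
    """Min–max scale to [0, 1]; a constant series maps to all zeros."""
    x = np.asarray(series, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def build_feature_set(paired: PairedRecording, side: str, cfg: PreprocessConfig | None = None) -> FeatureSet:
    """Compute the three smoothed magnitude channels for one leg.

    The paired recording must already be cleaned (imputed, outlier-free,
    direction cosines in [-1, 1]).  Magnitudes are computed from the raw
    channels and then Gaussian-smoothed — the labeler and the models
    operate on smoothed magnitudes, not on norms of smoothed channels.
    """
    cfg = cfg or PreprocessConfig()
    rec = getattr(paired, side)
    avm = ang_vel_mag(rec.gyr[:, 0], rec.gyr[:, 1], rec.gyr[:, 2])
    fam = free_acc_mag(rec.free_acc[:, 0], rec.free_acc[:, 1], rec.free_acc[:, 2])
    rmm = rot_mat_mag(paired.left.rot_mat_11, paired.right.rot_mat_11)
    f = cfg.smoothing_fwhm_frames
    return FeatureSet(
        side=side,
        ang_vel_mag=smooth_gaussian(avm, f),
        free_acc_mag=smooth_gaussian(fam, f),
        rot_mat_mag=smooth_gaussian(rmm, f),
        raw_ang_vel_mag=avm,
        sampling_rate_hz=paired.sampling_rate_hz,
    )
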