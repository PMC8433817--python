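"""Channel cleaning and Gaussian smoothing.

Cleaning follows the manufacturer's validity guidance for the supported
trackers: accelerometer samples outside ±160 m/s² and gyroscope samples
outside ±2000 deg/s are physically implausible and are removed.  Removed
samples (and any missing values) are imputed with a forward fill ("pad"):
each gap takes the nearest preceding valid value, and a leading gap takes
the first valid value.  Signals are then smoothed with a normalized
Gaussian kernel specified by its full width at half maximum (FWHM) in
frames; FWHM = 9 at 100 Hz is a ~90 ms kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

#: FWHM = 2·sqrt(2·ln 2)·sigma for a Gaussian.
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning and smoothing parameters.

    acc_valid_range / gyr_valid_range are half-widths of symmetric validity
    intervals about zero (m/s² and deg/s); smoothing_fwhm_frames is the
    Gaussian kernel FWHM in samples.
    """

    acc_valid_range: float = 160.0
    gyr_valid_range: float = 2000.0
    smoothing_fwhm_frames: float = 9.0
    #: Also smooth the raw channels before computing magnitudes (fidelity
    #: experiments); magnitudes themselves are always smoothed downstream.
    smooth_raw_channels: bool = False

    def __post_init__(self) -> None:
        if self.acc_valid_range <= 0 or self.gyr_valid_range <= 0:
            raise ValueError("validity ranges must be positive half-widths")
        if self.smoothing_fwhm_frames <= 0:
            raise ValueError("smoothing_fwhm_frames must be positive")


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian standard deviation for a given full width at half maximum."""
    return fwhm / _FWHM_PER_SIGMA


def impute_pad(series: np.ndarray) -> np.ndarray:
    """Forward-fill missing (NaN) values; a leading gap takes the first valid value.

    Raises if every value is missing.
    """
    x = np.asarray(series, dtype=float).copy()
    valid = ~np.isnan(x)
    if not valid.any():
        raise ValueError("cannot impute a series with no valid values")
    # forward fill: index of most recent valid sample at or before each frame
    idx = np.where(valid, np.arange(x.size), -1)
    idx = np.maximum.accumulate(idx)
    first_valid = np.argmax(valid)
    idx[idx < 0] = first_valid  # leading gap -> back-fill with first valid
    return x[idx]


def remove_outliers(series: np.ndarray, kind: str, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Replace physically out-of-range samples with the preceding valid value.

    ``kind`` selects the validity range: 'acc' (±acc_valid_range m/s²) or
    'gyr' (±gyr_valid_range deg/s).  Out-of-range samples are marked
    missing and imputed by :func:`impute_pad`; in-range samples are
    untouched, so the operation is idempotent.
    """
    cfg = cfg or PreprocessConfig()
    if kind == "acc":
        bound = cfg.acc_valid_range
    elif kind == "gyr":
        bound = cfg.gyr_valid_range
    else:
        raise ValueError(f"kind must be 'acc' or 'gyr', got {kind!r}")
    x = np.asarray(series, dtype=float).copy()
    x[np.abs(x) > bound] = np.nan
    return impute_pad(x)


def smooth_gaussian(series: np.ndarray, fwhm_frames: float) -> np.ndarray:
    """Convolve with a normalized Gaussian kernel of the given FWHM (frames).

    sigma = FWHM / (2·sqrt(2·ln 2)); the kernel is truncated at 4·sigma per
    side and boundaries are handled by reflection, which avoids edge droop
    in short trials.  Output length equals input length; a constant series
    is returned unchanged (normalized kernel).
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("smooth_gaussian requires finite input")
    if fwhm_frames <= 0:
        raise ValueError("fwhm_frames must be positive")
    return gaussian_filter1d(x, sigma=fwhm_to_sigma(fwhm_frames), mode="reflect", truncate=4.0)


def clean_recording(recording, cfg: PreprocessConfig | None = None):
    """Impute and outlier-clean all channels of an :class:`~gaitphase.imu_io.ImuRecording`.

    Gyroscope and accelerometer channels go through range-based outlier
    removal (which includes pad imputation); the direction-cosine channel
    is imputed and clipped to [-1, 1].  If ``cfg.smooth_raw_channels`` is
    set, every cleaned channel is additionally Gaussian-smoothed.
    """
    cfg = cfg or PreprocessConfig()
    gyr = np.column_stack([remove_outliers(recording.gyr[:, i], "gyr", cfg) for i in range(3)])
    acc = np.column_stack([remove_outliers(recording.free_acc[:, i], "acc", cfg) for i in range(3)])
    r11 = np.clip(impute_pad(recording.rot_mat_11), -1.0, 1.0)
    if cfg.smooth_raw_channels:
        f = cfg.smoothing_fwhm_frames
        gyr = np.column_stack([smooth_gaussian(gyr[:, i], f) for i in range(3)])
        acc = np.column_stack([smooth_gaussian(acc[:, i], f) for i in range(3)])
        r11 = smooth_gaussian(r11, f)
    return replace(recording, gyr=gyr, free_acc=acc, rot_mat_11=r11)
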