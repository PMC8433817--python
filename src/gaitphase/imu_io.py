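"""Reading, writing and pairing of per-leg IMU channel CSVs and event tables.

One recording holds the seven channels the pipeline consumes: the 3-D
angular velocity (``Gyr_X/Y/Z``, deg/s), the 3-D free acceleration
(``FreeAcc_X/Y/Z``, m/s², gravity already removed by the device) and the
``Mat[1][1]`` element of the sensor's direction-cosine matrix, which varies
with heading and is used downstream for turning detection.  Files follow
the comma-separated export dialect of common motion-tracker manager
software; column-name dialects are configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GYR_COLUMNS = ("Gyr_X", "Gyr_Y", "Gyr_Z")
FREE_ACC_COLUMNS = ("FreeAcc_X", "FreeAcc_Y", "FreeAcc_Z")

#: Accepted spellings of the direction-cosine [1][1] column, by exporter
#: version.  The first entry is the canonical name used when writing.
ROT_MAT_ALIASES = ("Mat[1][1]", "Mat_1_1")

PHASES = ("FO", "MidS", "FC")
SIDES = ("left", "right")


@dataclass(frozen=True)
class ImuRecording:
    """One leg's raw channel time series at a fixed sampling rate.

    All channels are 1-D float arrays of equal length ``n_frames``.  Frame
    index is the only time coordinate used internally (0-based); seconds
    appear only in exported tables.
    """

    side: str
    sampling_rate_hz: float
    gyr: np.ndarray          # shape (n_frames, 3), deg/s
    free_acc: np.ndarray     # shape (n_frames, 3), m/s²
    rot_mat_11: np.ndarray   # shape (n_frames,), dimensionless

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(self, "gyr", np.asarray(self.gyr, dtype=float))
        object.__setattr__(self, "free_acc", np.asarray(self.free_acc, dtype=float))
        object.__setattr__(self, "rot_mat_11", np.asarray(self.rot_mat_11, dtype=float))
        n = self.rot_mat_11.shape[0]
        if self.gyr.shape != (n, 3) or self.free_acc.shape != (n, 3):
            raise ValueError(
                f"channel length mismatch: gyr {self.gyr.shape}, "
                f"free_acc {self.free_acc.shape}, rot_mat_11 ({n},)"
            )

    @property
    def n_frames(self) -> int:
        return self.rot_mat_11.shape[0]

    def truncated(self, n_frames: int) -> "ImuRecording":
        return replace(
            self,
            gyr=self.gyr[:n_frames],
            free_acc=self.free_acc[:n_frames],
            rot_mat_11=self.rot_mat_11[:n_frames],
        )


@dataclass(frozen=True)
class PairedRecording:
    """Frame-aligned left and right recordings (equal length and rate)."""

    left: ImuRecording
    right: ImuRecording

    def __post_init__(self) -> None:
        if self.left.n_frames != self.right.n_frames:
            raise ValueError("paired recordings must have equal n_frames")
        if self.left.sampling_rate_hz != self.right.sampling_rate_hz:
            raise ValueError("paired recordings must share a sampling rate")

    @property
    def n_frames(self) -> int:
        return self.left.n_frames

    @property
    def sampling_rate_hz(self) -> float:
        return self.left.sampling_rate_hz


def _resolve_rot_mat_column(columns, dialect: dict | None) -> str:
    candidates = list(ROT_MAT_ALIASES)
    if dialect and "rot_mat_11" in dialect:
        candidates.insert(0, dialect["rot_mat_11"])
    for name in candidates:
        if name in columns:
            return name
    raise KeyError(
        f"missing rotation-matrix column (any of {candidates}); found {list(columns)}"
    )


def read_recording(
    path,
    side: str,
    sampling_rate_hz: float = 100.0,
    dialect: dict | None = None,
) -> ImuRecording:
    """Read one leg's channel CSV into an :class:`ImuRecording`.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.  Required columns: Gyr_X/Y/Z,
        FreeAcc_X/Y/Z and the direction-cosine column (``Mat[1][1]`` or
        ``Mat_1_1``; override via ``dialect={'rot_mat_11': name, ...}``).
        Extra columns are ignored; row order is preserved.
    side : {'left', 'right'}
    sampling_rate_hz : float
        Device sampling rate; 100 Hz for the supported trackers.
    dialect : dict, optional
        Maps canonical channel names to file column names.
    """
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"empty input file: {path}")
    dialect = dialect or {}
    missing = [
        dialect.get(c, c)
        for c in (*GYR_COLUMNS, *FREE_ACC_COLUMNS)
        if dialect.get(c, c) not in frame.columns
    ]
    if missing:
        raise KeyError(f"missing required column(s) {missing} in {path}")
    rot_col = _resolve_rot_mat_column(frame.columns, dialect)
    gyr = frame[[dialect.get(c, c) for c in GYR_COLUMNS]].to_numpy(dtype=float)
    acc = frame[[dialect.get(c, c) for c in FREE_ACC_COLUMNS]].to_numpy(dtype=float)
    return ImuRecording(
        side=side,
        sampling_rate_hz=sampling_rate_hz,
        gyr=gyr,
        free_acc=acc,
        rot_mat_11=frame[rot_col].to_numpy(dtype=float),
    )


def write_recording(recording: ImuRecording, path) -> None:
    """Write a recording back to the CSV dialect :func:`read_recording` accepts."""
    data = {c: recording.gyr[:, i] for i, c in enumerate(GYR_COLUMNS)}
    data.update({c: recording.free_acc[:, i] for i, c in enumerate(FREE_ACC_COLUMNS)})
    data[ROT_MAT_ALIASES[0]] = recording.rot_mat_11
    pd.DataFrame(data).to_csv(path, index=False)


def pair_recordings(left: ImuRecording, right: ImuRecording) -> PairedRecording:
    """Frame-align two legs; unequal lengths are truncated to the shorter.

    Wireless sensors commonly drop trailing frames, so a length mismatch is
    resolved (with a warning) rather than rejected.  Differing sampling
    rates are an error.
    """
    if left.sampling_rate_hz != right.sampling_rate_hz:
        raise ValueError(
            f"sampling rates differ: left {left.sampling_rate_hz} Hz, "
            f"right {right.sampling_rate_hz} Hz"
        )
    n = min(left.n_frames, right.n_frames)
    if left.n_frames != right.n_frames:
        warnings.warn(
            f"leg lengths differ ({left.n_frames} vs {right.n_frames}); "
            f"truncating both to {n} frames",
            stacklevel=2,
        )
    return PairedRecording(left=left.truncated(n), right=right.truncated(n))


def write_events(events, path, sampling_rate_hz: float = 100.0) -> None:
    """Write gait events as CSV (frame, time_s, side, phase, valid).

    Events are stably sorted by frame on write; ``time_s`` is
    ``frame / sampling_rate_hz``.
    """
    rows = sorted(events, key=lambda e: e.frame)
    frame = pd.DataFrame(
        {
            "frame": [e.frame for e in rows],
            "time_s": [e.frame / sampling_rate_hz for e in rows],
            "side": [e.side for e in rows],
            "phase": [e.phase for e in rows],
            "valid": [int(e.valid) for e in rows],
        }
    )
    frame.to_csv(path, index=False)


def read_events(path):
    """Read an event CSV written by :func:`write_events`."""
    from gaitphase.gait_labeler import GaitEvent

    frame = pd.read_csv(path)
    return [
        GaitEvent(
            frame=int(r.frame),
            phase=str(r.phase),
            side=str(r.side),
            valid=bool(r.valid),
        )
        for r in frame.itertuples()
    ]
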