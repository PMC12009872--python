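"""Read and write OpenFace-dialect landmark/AU tables.

OpenFace writes one CSV row per video frame with the 68-point facial grid
(``x_0..x_67``, ``y_0..y_67`` in pixels), per-frame tracking ``confidence``
and ``success`` flags, 18 binary action-unit presence columns (``AU*_c``)
and 17 continuous intensity columns (``AU*_r``).  Headers carry a leading
space (`` x_0``), which this reader tolerates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from facemms import errors

N_LANDMARKS = 68

TASKS = (
    "resting",
    "anger",
    "contempt",
    "disgust",
    "fear",
    "happiness",
    "sadness",
    "surprise",
)

GROUPS = (
    "TD",
    "TD-Mom",
    "TD-MomM",
    "TD-Dad",
    "ASD-LS",
    "ASD-HS",
    "ASD-HS-apraxia",
)

# OpenFace 2.x action-unit sets: 17 AUs with continuous intensity (_r),
# 18 with binary presence (_c: the same 17 plus AU28 lip-suck).
AU_INTENSITY_IDS = (
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09", "AU10",
    "AU12", "AU14", "AU15", "AU17", "AU20", "AU23", "AU25", "AU26", "AU45",
)
AU_PRESENCE_IDS = (
    "AU01", "AU02", "AU04", "AU05", "AU06", "AU07", "AU09", "AU10",
    "AU12", "AU14", "AU15", "AU17", "AU20", "AU23", "AU25", "AU26",
    "AU28", "AU45",
)

# Floats printed with enough significant digits that write->read agrees
# to 1e-9 relative; 9 digits falls just short near mantissa 1.0.
FLOAT_FORMAT = "%.12g"

MIN_CONFIDENCE = 0.75
MAX_BAD_FRAME_FRACTION = 0.10


@dataclasses.dataclass
class LandmarkFrameSeries:
    """One 5-second recording: landmark trajectories plus AU matrices.

    coords is (F, 68, 2) with the last axis ordered (x, y), pixels.
    au_presence is (F, 18) binary; au_intensity is (F, 17), values >= 0.
    """

    participant_id: str
    task: str
    group: str
    timestamps: np.ndarray
    coords: np.ndarray
    confidence: np.ndarray
    success: np.ndarray
    au_presence: np.ndarray
    au_intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise errors.DomainError(f"unknown task {self.task!r}")
        if self.group not in GROUPS:
            raise errors.DomainError(f"unknown group {self.group!r}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.success = np.asarray(self.success, dtype=int)
        self.au_presence = np.asarray(self.au_presence)
        self.au_intensity = np.asarray(self.au_intensity, dtype=float)
        f = self.timestamps.shape[0]
        if f == 0:
            raise errors.EmptyInputError("recording has no frames")
        if self.coords.shape != (f, N_LANDMARKS, 2):
            raise errors.FormatError(
                f"coords shape {self.coords.shape}, expected ({f}, 68, 2)"
            )
        if self.au_presence.shape != (f, len(AU_PRESENCE_IDS)):
            raise errors.FormatError(
                f"au_presence shape {self.au_presence.shape}, expected ({f}, 18)"
            )
        if self.au_intensity.shape != (f, len(AU_INTENSITY_IDS)):
            raise errors.FormatError(
                f"au_intensity shape {self.au_intensity.shape}, expected ({f}, 17)"
            )
        if not np.isin(self.au_presence, (0, 1)).all():
            raise errors.FormatError("au_presence must be {0,1}-valued")
        self.au_presence = self.au_presence.astype(int)
        if (self.au_intensity < 0).any():
            raise errors.DataQualityError("negative AU intensity")
        if np.any(np.diff(self.timestamps) <= 0):
            raise errors.OrderingError("timestamps not strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.timestamps.shape[0]


def _coord_columns() -> list[str]:
    return [f"x_{i}" for i in range(N_LANDMARKS)] + [
        f"y_{i}" for i in range(N_LANDMARKS)
    ]


def read_openface_csv(
    path: str | Path,
    participant_id: str,
    task: str,
    group: str,
) -> LandmarkFrameSeries:
    """Read one OpenFace per-frame CSV into a validated LandmarkFrameSeries.

    Frames with success=0 or confidence below 0.75 have their landmark
    coordinates linearly interpolated from neighbouring good frames if they
    make up less than 10% of the recording; otherwise the recording is
    rejected with a DataQualityError.  AU rows of such frames are kept as-is.
    """
    path = Path(path)
    if not path.exists():
        raise errors.FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    if len(df) == 0:
        raise errors.EmptyInputError(f"{path} has no data rows")

    for col in ("timestamp", "confidence", "success"):
        if col not in df.columns:
            raise errors.FormatError(f"missing column {col!r}")
    for col in _coord_columns():
        if col not in df.columns:
            raise errors.FormatError(f"missing landmark column {col!r}")
    extra = [
        c
        for c in df.columns
        if (c.startswith("x_") or c.startswith("y_"))
        and c not in _coord_columns()
    ]
    if extra:
        raise errors.FormatError(f"unexpected landmark column {extra[0]!r}")
    pres_cols = [f"{au}_c" for au in AU_PRESENCE_IDS]
    int_cols = [f"{au}_r" for au in AU_INTENSITY_IDS]
    for col in pres_cols + int_cols:
        if col not in df.columns:
            raise errors.FormatError(f"missing AU column {col!r}")

    timestamps = df["timestamp"].to_numpy(dtype=float)
    if np.any(np.diff(timestamps) <= 0):
        raise errors.OrderingError("timestamps not strictly increasing")

    xs = df[[f"x_{i}" for i in range(N_LANDMARKS)]].to_numpy(dtype=float)
    ys = df[[f"y_{i}" for i in range(N_LANDMARKS)]].to_numpy(dtype=float)
    coords = np.stack([xs, ys], axis=-1)
    confidence = df["confidence"].to_numpy(dtype=float)
    success = df["success"].to_numpy(dtype=int)

    bad = (success == 0) | (confidence < MIN_CONFIDENCE)
    if bad.any():
        frac = bad.mean()
        if frac >= MAX_BAD_FRAME_FRACTION:
            raise errors.DataQualityError(
                f"{frac:.0%} of frames failed tracking (limit "
                f"{MAX_BAD_FRAME_FRACTION:.0%})"
            )
        if bad.all() or (~bad).sum() < 2:
            raise errors.DataQualityError("not enough good frames to interpolate")
        good_idx = np.flatnonzero(~bad)
        for p in range(N_LANDMARKS):
            for ax in range(2):
                coords[bad, p, ax] = np.interp(
                    timestamps[bad], timestamps[good_idx], coords[good_idx, p, ax]
                )

    return LandmarkFrameSeries(
        participant_id=participant_id,
        task=task,
        group=group,
        timestamps=timestamps,
        coords=coords,
        confidence=confidence,
        success=success,
        au_presence=df[pres_cols].to_numpy(),
        au_intensity=df[int_cols].to_numpy(dtype=float),
    )


def write_openface_csv(series: LandmarkFrameSeries, path: str | Path) -> None:
    """Write a recording back out in the OpenFace column dialect."""
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(1, series.n_frames + 1),
        "timestamp": series.timestamps,
        "confidence": series.confidence,
        "success": series.success,
    }
    for i in range(N_LANDMARKS):
        cols[f"x_{i}"] = series.coords[:, i, 0]
    for i in range(N_LANDMARKS):
        cols[f"y_{i}"] = series.coords[:, i, 1]
    for j, au in enumerate(AU_INTENSITY_IDS):
        cols[f"{au}_r"] = series.au_intensity[:, j]
    for j, au in enumerate(AU_PRESENCE_IDS):
        cols[f"{au}_c"] = series.au_presence[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_table(records, path: str | Path) -> None:
    """Write any pipeline tabular artifact as a comma-delimited UTF-8 file.

    Accepts a pandas DataFrame or any pipeline object exposing
    ``to_frame()`` (EMDMatrix, ClusterReport, ...).
    """
    if hasattr(records, "to_frame") and not isinstance(records, pd.DataFrame):
        frame = records.to_frame()
    elif isinstance(records, pd.DataFrame):
        frame = records
    else:
        raise errors.DomainError(
            f"cannot serialise object of type {type(records).__name__}"
        )
    path = Path(path)
    try:
        frame.to_csv(path, index=isinstance(frame.index, pd.MultiIndex)
                     or frame.index.name is not None,
                     float_format=FLOAT_FORMAT, encoding="utf-8")
    except OSError as exc:
        raise errors.FaceMMSError(f"cannot write {path}: {exc}") from exc


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, encoding="utf-8")
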