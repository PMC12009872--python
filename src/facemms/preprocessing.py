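"""Frame normalization, trigeminal parcellation, smoothing, speed.

Each video frame's 68 landmark coordinates are z-scored per axis
(zx = (x - mu_x)/sigma_x, zy likewise), removing translation and the
subject's distance to the camera.  The grid is parcelled into three
subregions following the trigeminal nerve's innervation territories:
V1 (ophthalmic: brows and eyes), V2 (maxillary: nose and upper lip),
V3 (mandibular: jaw line and lower lip).  Trajectories are interpolated
with cubic splines and differentiated analytically to obtain per-landmark
speed at the original frame times.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import CubicSpline

from facemms import errors
from facemms.openface_io import N_LANDMARKS, LandmarkFrameSeries

# Trigeminal parcellation of the 68-point grid.  Landmark 33 (nose tip)
# is maxillary and sits in V2; this makes the region sizes 26/17/25.
_V1 = tuple(range(17, 31)) + tuple(range(36, 48))
_V2 = (31, 32, 33, 34, 35) + tuple(range(48, 55)) + tuple(range(60, 65))
_V3 = tuple(range(0, 17)) + tuple(range(55, 60)) + (65, 66, 67)

REGION_NAMES = ("V1", "V2", "V3")


@dataclasses.dataclass(frozen=True)
class RegionPartition:
    """Ordered assignment of landmark indices 0-67 to face regions."""

    regions: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, idx in self.regions.items():
            idx_set = set(idx)
            if len(idx_set) != len(idx):
                raise errors.DomainError(f"duplicate index within region {name}")
            if seen & idx_set:
                raise errors.DomainError(f"region {name} overlaps another region")
            seen |= idx_set
        if seen != set(range(N_LANDMARKS)):
            raise errors.DomainError("partition must cover indices 0..67 exactly")

    def __getitem__(self, name: str) -> tuple[int, ...]:
        return self.regions[name]

    def names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def region_of(self, landmark: int) -> str:
        for name, idx in self.regions.items():
            if landmark in idx:
                return name
        raise errors.DomainError(f"landmark {landmark} not in partition")


def default_partition() -> RegionPartition:
    """The trigeminal V1/V2/V3 parcellation (sizes 26, 17, 25)."""
    return RegionPartition(
        regions={
            "V1": tuple(sorted(_V1)),
            "V2": tuple(sorted(_V2)),
            "V3": tuple(sorted(_V3)),
        }
    )


@dataclasses.dataclass
class NormalizedFrameSeries:
    """Z-scored landmark trajectories: each frame has mean 0, sd 1 per axis."""

    participant_id: str
    task: str
    group: str
    timestamps: np.ndarray
    coords: np.ndarray  # (F, 68, 2), unitless

    @property
    def n_frames(self) -> int:
        return self.timestamps.shape[0]


@dataclasses.dataclass
class SpeedSeries:
    """Per-landmark speed sampled at the original frame timestamps.

    values is (68, F), normalized units per second, all finite and >= 0.
    """

    participant_id: str
    task: str
    group: str
    timestamps: np.ndarray
    values: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.timestamps.shape[0]


def zscore_frames(series: LandmarkFrameSeries) -> NormalizedFrameSeries:
    """Z-score each frame's coordinates per axis (population sd, n=68)."""
    coords = series.coords
    mean = coords.mean(axis=1, keepdims=True)
    sd = coords.std(axis=1, keepdims=True)  # ddof=0: unit sd per frame
    if np.any(sd <= 0):
        bad = int(np.argwhere(sd.reshape(series.n_frames, 2) <= 0)[0][0])
        raise errors.DegenerateFrameError(
            f"frame {bad} has zero coordinate variance"
        )
    return NormalizedFrameSeries(
        participant_id=series.participant_id,
        task=series.task,
        group=series.group,
        timestamps=series.timestamps.copy(),
        coords=(coords - mean) / sd,
    )


def smooth_trajectory(timestamps: np.ndarray, values: np.ndarray) -> CubicSpline:
    """Interpolating cubic spline (not-a-knot ends) through one coordinate.

    The returned curve is twice differentiable, passes through the samples,
    and exposes value and derivative at arbitrary t via the spline object.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values, dtype=float)
    if timestamps.shape[0] < 4:
        raise errors.InsufficientDataError(
            f"need >= 4 samples for spline, got {timestamps.shape[0]}"
        )
    if np.any(np.diff(timestamps) <= 0):
        raise errors.OrderingError("timestamps not strictly increasing")
    return CubicSpline(timestamps, values, bc_type="not-a-knot")


def compute_speed(
    series: NormalizedFrameSeries,
    partition: RegionPartition | None = None,
) -> SpeedSeries:
    """Differentiate splined trajectories to speed at the frame timestamps.

    speed(t) = sqrt(zx'(t)^2 + zy'(t)^2), evaluated at the original F
    frame times so each landmark contributes exactly F speed samples.
    The partition argument restricts computation to its landmarks; by
    default all 68 are processed (rows of excluded landmarks are NaN-free
    zeros only when restricted — callers glue by region regardless).
    """
    t = series.timestamps
    landmarks = (
        sorted(i for idx in partition.regions.values() for i in idx)
        if partition is not None
        else range(N_LANDMARKS)
    )
    values = np.zeros((N_LANDMARKS, t.shape[0]))
    for i in landmarks:
        dx = smooth_trajectory(t, series.coords[:, i, 0]).derivative()(t)
        dy = smooth_trajectory(t, series.coords[:, i, 1]).derivative()(t)
        values[i] = np.hypot(dx, dy)
    return SpeedSeries(
        participant_id=series.participant_id,
        task=series.task,
        group=series.group,
        timestamps=t.copy(),
        values=values,
    )


def speed_table(speed: SpeedSeries, partition: RegionPartition):
    """Long-format speed table: one row per (landmark, frame)."""
    import pandas as pd

    rows = []
    for name in partition.names():
        for lm in partition[name]:
            for f, (ti, v) in enumerate(zip(speed.timestamps, speed.values[lm])):
                rows.append(
                    (speed.participant_id, speed.task, name, lm, f, ti, v)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "task", "region", "landmark",
            "frame_index", "t", "speed",
        ],
    )
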