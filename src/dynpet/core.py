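"""Core in-memory containers for dynamic PET analysis.

Conventions used throughout the package:

* frame timing is stored in **seconds** post-injection (sidecar convention),
  while every analysis-facing quantity (mid-frame times, slopes, onsets) is
  reported in **minutes**;
* activity concentration is stored in Bq/mL, decay-corrected to injection
  time; SUL (standardized uptake value normalized to lean body mass) is the
  dimensionless analysis unit;
* the representative time of a frame is its mid-point, ``start + duration/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "FrameSchedule",
    "SubjectMeta",
    "DynamicImage",
    "LabelMap",
    "TimeActivityCurve",
    "DynpetError",
    "ParameterError",
    "InputError",
    "FormatError",
]


class DynpetError(Exception):
    """Base class for all package errors."""


class ParameterError(DynpetError, ValueError):
    """A model or subject parameter violates its physical constraints."""


class InputError(DynpetError, ValueError):
    """Analysis input (arrays, grids, pairings) is malformed."""


class FormatError(DynpetError, ValueError):
    """On-disk data is internally inconsistent (e.g. sidecar vs image)."""


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition time bins: per-frame start and duration, seconds p.i.

    Frames must be strictly ordered and non-overlapping; gaps are allowed
    (e.g. a late static frame appended to a dynamic series).
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or duration.ndim != 1:
            raise InputError("frame start/duration must be 1-D")
        if start.size != duration.size:
            raise InputError(
                f"schedule lengths differ: {start.size} starts, "
                f"{duration.size} durations"
            )
        if start.size == 0:
            raise InputError("schedule must contain at least one frame")
        if np.any(duration <= 0):
            raise InputError("frame durations must be > 0")
        if np.any(np.diff(start) <= 0):
            raise InputError("frame starts must be strictly increasing")
        if np.any(start[:-1] + duration[:-1] > start[1:] + 1e-9):
            raise InputError("frames overlap")

    @classmethod
    def uniform(cls, n_frames: int, frame_seconds: float = 60.0,
                t0_seconds: float = 0.0) -> "FrameSchedule":
        """Contiguous schedule of ``n_frames`` equal frames."""
        start = t0_seconds + frame_seconds * np.arange(n_frames, dtype=float)
        return cls(start=start, duration=np.full(n_frames, float(frame_seconds)))

    def __len__(self) -> int:
        return int(self.start.size)

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def mid_minutes(self) -> np.ndarray:
        """Mid-frame times in minutes p.i. — the package-wide time axis."""
        return (self.start + self.duration / 2.0) / 60.0

    @property
    def duration_minutes(self) -> np.ndarray:
        return self.duration / 60.0


@dataclass(frozen=True)
class SubjectMeta:
    """Subject data required for SUL normalization."""

    weight_kg: float
    height_cm: float
    sex: str
    injected_activity_mbq: float
    injection_time: str = "1970-01-01T00:00:00"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ParameterError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (self.weight_kg > 0 and np.isfinite(self.weight_kg)):
            raise ParameterError(f"weight must be > 0 kg, got {self.weight_kg}")
        if not (self.height_cm > 0 and np.isfinite(self.height_cm)):
            raise ParameterError(f"height must be > 0 cm, got {self.height_cm}")
        if not (self.injected_activity_mbq > 0):
            raise ParameterError(
                f"injected activity must be > 0 MBq, got {self.injected_activity_mbq}"
            )


@dataclass
class DynamicImage:
    """4-D decay-corrected activity-concentration volume (Bq/mL).

    ``values`` is indexed ``[x, y, z, frame]``; the frame axis length must
    match the schedule.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule
    subject: SubjectMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise InputError("DynamicImage.values must be 4-D (x, y, z, frame)")
        if self.values.shape[3] != self.schedule.n_frames:
            raise FormatError(
                f"image has {self.values.shape[3]} frames but schedule has "
                f"{self.schedule.n_frames}"
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ParameterError(f"voxel sizes must be > 0, got {self.voxel_size_mm}")

    @property
    def voxel_volume_ml(self) -> float:
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz / 1000.0

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.values.shape[:3]


@dataclass
class LabelMap:
    """3-D integer region map plus id→name table; id 0 is background."""

    labels: np.ndarray
    names: Mapping[int, str]
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InputError("LabelMap.labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InputError("LabelMap.labels must be an integer volume")
        self.names = dict(self.names)
        if 0 in self.names:
            raise InputError("label id 0 is reserved for background")
        vals = set(self.names.values())
        if len(vals) != len(self.names):
            raise InputError("region names must be unique")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def voxel_volume_ml(self) -> float:
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz / 1000.0

    def id_of(self, region: str) -> int:
        for k, v in self.names.items():
            if v == region:
                return int(k)
        raise InputError(f"region {region!r} not in label map "
                         f"(have {sorted(self.names.values())})")

    def mask(self, region: str) -> np.ndarray:
        return self.labels == self.id_of(region)


@dataclass
class TimeActivityCurve:
    """Per-region tracer concentration vs mid-frame time.

    ``conc`` is Bq/mL, ``sul`` the lean-body-mass normalized value; both are
    frame means over the ROI. ``n_voxels``/``roi_volume_ml`` are 0/0.0 for
    purely synthetic (non-voxelized) curves. ``undersized`` flags ROIs below
    the minimum-diameter rule — the curve is still usable, by design.
    """

    region: str
    t_mid: np.ndarray
    conc: np.ndarray
    sul: np.ndarray
    n_voxels: int = 0
    roi_volume_ml: float = 0.0
    undersized: bool = False

    def __post_init__(self) -> None:
        self.t_mid = np.asarray(self.t_mid, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        self.sul = np.asarray(self.sul, dtype=float)
        n = self.t_mid.size
        if self.conc.size != n or self.sul.size != n:
            raise InputError("TAC arrays must have equal length")
        if n == 0:
            raise InputError("TAC must contain at least one frame")
        if np.any(np.diff(self.t_mid) <= 0):
            raise InputError("TAC mid-times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t_mid.size)
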