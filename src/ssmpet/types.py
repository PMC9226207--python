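"""Shared domain types for the disease-pattern pipeline.

All images in a study live on one common voxel grid (the pipeline performs no
registration or resampling); voxel coordinates are 0-based array indices and
voxel sizes are in millimetres.  Frame times are stored in seconds; kinetic
rate constants are expressed in inverse minutes, and the conversion happens
only inside the kinetics module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridMismatchError(ValueError):
    """Raised when images that must share a voxel grid do not."""


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values in arbitrary image units.
    voxel_size : tuple of float
        Voxel edge lengths in mm per axis.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume needs a 3D array, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("all grid dimensions must be >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.voxel_size)) / 1000.0


@dataclass
class FrameSchedule:
    """Per-frame start/end times in seconds.

    Frames must be in temporal order and non-overlapping; gaps are allowed.
    """

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        if self.starts.ndim != 1 or self.starts.shape != self.ends.shape:
            raise ValueError("starts and ends must be 1D arrays of equal length")
        if len(self.starts) == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(self.ends <= self.starts):
            raise ValueError("frame ends must exceed frame starts")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("frames must not overlap")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def total_end(self) -> float:
        return float(self.ends[-1])


@dataclass
class DynamicImage:
    """A 4D dynamic image: voxel grid x frames, with its frame schedule."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DynamicImage needs a 4D array, got {self.data.ndim}D")
        if self.data.shape[3] != len(self.schedule):
            raise ValueError(
                f"frame count {self.data.shape[3]} does not match schedule "
                f"length {len(self.schedule)}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class AtlasDefinition:
    """A labelled atlas volume with a region -> lobe combination table.

    ``labels`` holds one integer label per voxel (0 = outside any region);
    every nonzero label must be named in ``region_names`` and every region
    must belong to exactly one lobe in ``lobe_map``.
    """

    labels: np.ndarray
    region_names: dict[int, str]
    lobe_map: dict[str, str]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D integer array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.region_names)
        if missing:
            raise ValueError(f"labels without a region name: {sorted(missing)}")
        unmapped = set(self.region_names.values()) - set(self.lobe_map)
        if unmapped:
            raise ValueError(f"regions without a lobe: {sorted(unmapped)}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def lobes(self) -> list[str]:
        return sorted(set(self.lobe_map.values()))

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def lobe_mask(self, lobe: str) -> np.ndarray:
        labels = [
            lab for lab, name in self.region_names.items() if self.lobe_map[name] == lobe
        ]
        return np.isin(self.labels, labels)


GROUPS = ("AD", "MCI+", "MCI-", "HC")


@dataclass
class Subject:
    subject_id: str
    group: str
    image: ImageVolume

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")


@dataclass
class Cohort:
    """A set of subjects sharing one grid, plus the analysis brain mask."""

    subjects: list[Subject]
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("cohort mask is empty")
        for s in self.subjects:
            if s.image.grid_shape != self.mask.shape:
                raise GridMismatchError(
                    f"subject {s.subject_id} grid {s.image.grid_shape} does not "
                    f"match mask grid {self.mask.shape}"
                )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.subjects]

    @property
    def ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def select(self, groups) -> "Cohort":
        keep = [s for s in self.subjects if s.group in set(groups)]
        return Cohort(keep, self.mask, self.voxel_size, dict(self.metadata))


def apply_mask(volume: ImageVolume, mask: np.ndarray) -> ImageVolume:
    """Zero every voxel outside ``mask``.  Idempotent."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.grid_shape:
        raise GridMismatchError("mask grid does not match volume grid")
    out = np.where(mask, volume.data, 0.0)
    return ImageVolume(out, volume.voxel_size)
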