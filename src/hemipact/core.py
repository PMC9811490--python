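"""Core in-memory containers: scalar 3D volumes and time series of volumes.

Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)`` along ``(x, y, z)``;
* physical coordinates are in millimetres; ``origin_mm`` is the physical
  position of the *center* of voxel ``(0, 0, 0)``;
* the z axis points from the pole of the hemispherical array toward the
  imaging volume, so the array sits at negative z and the reconstruction
  grid is centered near the center of curvature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["Volume", "VolumeSequence", "GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a voxel grid: shape, voxel pitch and physical origin."""

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_mm: float = 0.1
    origin_mm: tuple[float, float, float] | None = None

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if self.voxel_mm <= 0:
            raise ValueError(f"voxel_mm must be positive, got {self.voxel_mm}")
        if self.origin_mm is None:
            # Default: grid centered on the physical origin (center of curvature).
            half = tuple(-(s - 1) / 2.0 * self.voxel_mm for s in self.shape)
            object.__setattr__(self, "origin_mm", half)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_mm for s in self.shape)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.voxel_mm * np.arange(n)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij indexing) of voxel-center coordinates in mm."""
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2), indexing="ij"
        )


@dataclass
class Volume:
    """A scalar 3D grid with physical metadata.

    ``values`` carries arbitrary photoacoustic amplitude units.  Phantom
    volumes are non-negative; reconstructions may be signed (the magnitude
    is taken only for display and metrics).
    """

    values: np.ndarray
    voxel_mm: float = 0.1
    origin_mm: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"Volume values must be 3D, got ndim={self.values.ndim}")
        if self.voxel_mm <= 0:
            raise ValueError(f"voxel_mm must be positive, got {self.voxel_mm}")
        if self.origin_mm is None:
            self.origin_mm = tuple(
                -(s - 1) / 2.0 * self.voxel_mm for s in self.values.shape
            )
        else:
            self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.values.shape, self.voxel_mm, self.origin_mm)

    def with_values(self, values: np.ndarray) -> "Volume":
        return Volume(values, self.voxel_mm, self.origin_mm)

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.voxel_mm, self.origin_mm)


@dataclass
class VolumeSequence:
    """An ordered series of volumes sharing grid metadata.

    ``wavelength_nm`` optionally records the optical wavelength of each
    frame (used by the dual-wavelength functional protocol).
    """

    frames: list[Volume]
    frame_rate_hz: float
    wavelength_nm: Sequence[float] | None = None

    def __post_init__(self):
        if not self.frames:
            raise ValueError("VolumeSequence needs at least one frame")
        if self.frame_rate_hz <= 0:
            raise ValueError(f"frame_rate_hz must be positive, got {self.frame_rate_hz}")
        first = self.frames[0]
        for f in self.frames[1:]:
            if f.shape != first.shape or f.voxel_mm != first.voxel_mm:
                raise ValueError("all frames must share shape and voxel size")
        if self.wavelength_nm is not None and len(self.wavelength_nm) != len(self.frames):
            raise ValueError("wavelength_nm must have one entry per frame")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> Volume:
        return self.frames[i]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.frames)) / self.frame_rate_hz

    def as_array(self) -> np.ndarray:
        """Stack frames into a (t, nx, ny, nz) array (copy)."""
        return np.stack([f.values for f in self.frames], axis=0)
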