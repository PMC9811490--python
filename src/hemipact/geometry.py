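"""Hemispherical detector geometry, aperture subsets, and acquisition timing.

The array is a spherical cap of transducer elements at radius ``R`` from
the center of curvature (the physical origin).  The pole of the cap sits
at ``(0, 0, -R)`` and the z axis points from the pole toward the imaging
volume.  Element centers follow a Fibonacci (golden-angle) spiral laid
out *equal-area in solid angle*: element ``i`` (1-based) has polar angle

    cos(theta_i) = 1 - (i / N) * (1 - cos(Theta)),

where ``Theta`` is the cap half-angle of the outermost center.  With this
layout the first ``k`` channels cover exactly a fraction ``k/N`` of the
cap's solid angle, so the contiguous prefix of channels 1..N/4 forms the
polar "cluster" aperture and the stride-4 subset forms the "sparse"
aperture of the same channel count.

Each element footprint of area ``A`` has angular radius ``delta`` with
``2 pi R^2 (1 - cos delta) = A``.  The solid angle covered by a subset is
the analytic cap subtended by (outermost selected center angle + delta):

    Omega = 2 pi (1 - cos(theta_out + delta)).

With the defaults (R = 60 mm, N = 1024, A = 12 mm^2, Theta = 63.6 deg)
the full aperture covers 1.17 pi sr and the 256-channel polar cluster
covers 0.31 pi sr.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "ArrayGeometry",
    "ElementSubset",
    "SubsetMode",
    "TimingModel",
    "build_array",
    "select_subset",
    "covered_solid_angle",
    "effective_frame_rate",
]

GOLDEN_ANGLE_RAD = np.pi * (3.0 - np.sqrt(5.0))


class SubsetMode(str, Enum):
    FULL = "full"
    CLUSTER = "cluster"
    SPARSE = "sparse"


@dataclass(frozen=True)
class ArrayGeometry:
    """Element layout on the hemispherical cap.

    ``element_positions`` is an (N, 3) array in mm, ordered by physical
    channel index (``element_order`` maps layout rank -> channel index and
    is the identity for the canonical spiral, which is generated already
    sorted by polar angle).
    """

    radius_mm: float
    n_elements: int
    element_area_mm2: float
    element_positions: np.ndarray
    element_order: np.ndarray
    cap_half_angle_deg: float
    element_angular_radius_rad: float

    @property
    def polar_angles_rad(self) -> np.ndarray:
        """Polar angle of each element center, measured from the -z pole."""
        z = self.element_positions[:, 2]
        return np.arccos(np.clip(-z / self.radius_mm, -1.0, 1.0))


@dataclass(frozen=True)
class ElementSubset:
    """An aperture: which channels of the array are active.

    ``indices`` are 1-based channel indices, in acquisition order.
    """

    mode: SubsetMode
    indices: np.ndarray

    def positions(self, geom: ArrayGeometry) -> np.ndarray:
        return geom.element_positions[self.indices - 1]

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class TimingModel:
    """Acquisition timing under channel multiplexing.

    A 20 Hz laser with 4:1 multiplexing needs four shots per full-view
    frame (5 Hz), while the non-multiplexed cluster view runs at the
    laser rate (20 Hz).
    """

    laser_rate_hz: float
    mux_ratio: int
    frame_rate_hz: float


def element_angular_radius(radius_mm: float, element_area_mm2: float) -> float:
    """Angular radius delta of one element footprint: 2 pi R^2 (1-cos d) = A."""
    x = 1.0 - element_area_mm2 / (2.0 * np.pi * radius_mm**2)
    if x < -1.0:
        raise ValueError("element area exceeds the full sphere")
    return float(np.arccos(x))


def build_array(
    radius_mm: float = 60.0,
    n_elements: int = 1024,
    element_area_mm2: float = 12.0,
    cap_half_angle_deg: float = 63.6,
) -> ArrayGeometry:
    """Construct the golden-angle spiral layout on the spherical cap.

    Channel order ascends in polar angle from the pole, so channels
    ``1..N/4`` form the polar cluster.  A single-element array degenerates
    to one element at the pole.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius_mm must be positive, got {radius_mm}")
    if n_elements < 1:
        raise ValueError(f"n_elements must be >= 1, got {n_elements}")
    if element_area_mm2 < 0:
        raise ValueError("element_area_mm2 must be non-negative")
    theta_cap = np.deg2rad(cap_half_angle_deg)
    delta = element_angular_radius(radius_mm, element_area_mm2)
    if theta_cap + delta > np.pi:
        raise ValueError("element area too large for the requested cap")

    if n_elements == 1:
        pos = np.array([[0.0, 0.0, -radius_mm]])
    else:
        i = np.arange(1, n_elements + 1, dtype=float)
        cos_theta = 1.0 - (i / n_elements) * (1.0 - np.cos(theta_cap))
        theta = np.arccos(np.clip(cos_theta, -1.0, 1.0))
        phi = i * GOLDEN_ANGLE_RAD
        sin_theta = np.sin(theta)
        pos = radius_mm * np.stack(
            [sin_theta * np.cos(phi), sin_theta * np.sin(phi), -cos_theta], axis=1
        )
    order = np.arange(1, n_elements + 1)
    return ArrayGeometry(
        radius_mm=float(radius_mm),
        n_elements=int(n_elements),
        element_area_mm2=float(element_area_mm2),
        element_positions=pos,
        element_order=order,
        cap_half_angle_deg=float(cap_half_angle_deg),
        element_angular_radius_rad=delta,
    )


def select_subset(geom: ArrayGeometry, mode: SubsetMode | str) -> ElementSubset:
    """Select the full, cluster (polar prefix), or sparse (stride-4) aperture."""
    mode = SubsetMode(mode)
    n = geom.n_elements
    if mode is SubsetMode.FULL:
        idx = np.arange(1, n + 1)
    else:
        if n % 4 != 0:
            raise ValueError(
                f"cluster/sparse subsets need n_elements divisible by 4, got {n}"
            )
        if mode is SubsetMode.CLUSTER:
            idx = np.arange(1, n // 4 + 1)
        else:
            idx = np.arange(1, n + 1, 4)
    return ElementSubset(mode=mode, indices=idx)


def covered_solid_angle(geom: ArrayGeometry, subset: ElementSubset) -> float:
    """Solid angle (sr) of the union of the selected element footprints.

    Computed analytically as the spherical cap out to the outermost
    selected center's polar angle plus the element angular radius.
    Returns 0 for an empty subset.
    """
    if len(subset) == 0:
        return 0.0
    if subset.indices.min() < 1 or subset.indices.max() > geom.n_elements:
        raise ValueError("subset indices out of range for this geometry")
    theta = geom.polar_angles_rad[subset.indices - 1]
    theta_out = float(theta.max()) + geom.element_angular_radius_rad
    theta_out = min(theta_out, np.pi)
    return float(2.0 * np.pi * (1.0 - np.cos(theta_out)))


def effective_frame_rate(laser_rate_hz: float = 20.0, mux_ratio: int = 4) -> TimingModel:
    """Volumetric frame rate under mux_ratio:1 multiplexing of the DAQ."""
    if laser_rate_hz <= 0:
        raise ValueError(f"laser_rate_hz must be positive, got {laser_rate_hz}")
    if int(mux_ratio) != mux_ratio or mux_ratio < 1:
        raise ValueError(f"mux_ratio must be a positive integer, got {mux_ratio}")
    return TimingModel(
        laser_rate_hz=float(laser_rate_hz),
        mux_ratio=int(mux_ratio),
        frame_rate_hz=float(laser_rate_hz) / int(mux_ratio),
    )
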