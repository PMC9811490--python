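"""3D delay-and-sum reconstruction, stitching, projections, and resolution.

The delay-and-sum (DAS) estimate at voxel x is the plain unapodized sum

    v(x) = sum_i s_i(t = |x - p_i| / c),

with linear interpolation between time samples and zero contribution for
times of flight outside the recorded window.  The output is kept signed;
magnitude is taken only for display and metrics.  Whole-body volumes are
stitched from overlapping single volumes by maximum compounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from hemipact.core import GridSpec, Volume
from hemipact.forward import SignalFrame
from hemipact.geometry import ArrayGeometry

__all__ = [
    "ReconGrid",
    "MAPImage",
    "DepthEncodedImage",
    "das_reconstruct",
    "stitch_max",
    "map_projection",
    "depth_encode",
    "measure_fwhm",
]

_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


@dataclass(frozen=True)
class ReconGrid:
    """Reconstruction lattice: a GridSpec plus the assumed speed of sound."""

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_mm: float = 0.1
    origin_mm: tuple[float, float, float] | None = None
    speed_of_sound_m_s: float = 1500.0

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.shape, self.voxel_mm, self.origin_mm)


@dataclass(frozen=True)
class MAPImage:
    """Maximum amplitude projection along one axis."""

    data: np.ndarray
    axis: int
    voxel_mm: float


@dataclass(frozen=True)
class DepthEncodedImage:
    """MAP with per-pixel depth of the maximum encoded as color.

    ``rgb`` is H x W x 3 in [0, 1]: hue from the colormap at the argmax
    depth (first maximum on ties), brightness scaled by the normalized
    maximum amplitude.  All-zero columns are black.
    """

    rgb: np.ndarray
    depth_mm: np.ndarray
    amplitude: np.ndarray
    axis: int
    voxel_mm: float


@njit(cache=True)
def _das_kernel(samples, el_pos, fs, t0, sos_mm_s, x0, y0, z0, dv, nx, ny, nz):
    out = np.zeros((nx, ny, nz))
    n_el = el_pos.shape[0]
    n_t = samples.shape[1]
    for e in range(n_el):
        ex, ey, ez = el_pos[e, 0], el_pos[e, 1], el_pos[e, 2]
        for ix in range(nx):
            px = x0 + dv * ix - ex
            px2 = px * px
            for iy in range(ny):
                py = y0 + dv * iy - ey
                pxy2 = px2 + py * py
                for iz in range(nz):
                    pz = z0 + dv * iz - ez
                    r = np.sqrt(pxy2 + pz * pz)
                    p = (r / sos_mm_s - t0) * fs
                    j = int(np.floor(p))
                    if 0 <= j < n_t - 1:
                        f = p - j
                        out[ix, iy, iz] += samples[e, j] * (1.0 - f) + samples[e, j + 1] * f
    return out


def das_reconstruct(frame: SignalFrame, geom: ArrayGeometry, grid: ReconGrid) -> Volume:
    """Delay-and-sum back-projection of one frame onto the grid."""
    g = grid.grid
    el_pos = np.ascontiguousarray(frame.subset.positions(geom), dtype=np.float64)
    values = _das_kernel(
        np.ascontiguousarray(frame.samples, dtype=np.float64),
        el_pos,
        frame.sample_rate_hz,
        frame.t0_s,
        grid.speed_of_sound_m_s * 1e3,
        g.origin_mm[0],
        g.origin_mm[1],
        g.origin_mm[2],
        g.voxel_mm,
        g.shape[0],
        g.shape[1],
        g.shape[2],
    )
    return Volume(values, voxel_mm=g.voxel_mm, origin_mm=g.origin_mm)


def stitch_max(volumes: list[Volume], offsets_mm: list[tuple[float, float, float]]) -> Volume:
    """Maximum compounding of overlapping volumes on a common lattice.

    ``offsets_mm[i]`` translates volume ``i``; all offsets must be integer
    multiples of the shared voxel size.  Voxels covered by no volume are 0.
    """
    if len(volumes) != len(offsets_mm) or not volumes:
        raise ValueError("need one offset per volume and at least one volume")
    dv = volumes[0].voxel_mm
    if any(v.voxel_mm != dv for v in volumes):
        raise ValueError("all volumes must share the voxel size")
    shifts = []
    for off in offsets_mm:
        s = np.asarray(off, dtype=float) / dv
        if np.max(np.abs(s - np.round(s))) > 1e-6:
            raise ValueError(f"offset {off} is not commensurate with voxel size {dv}")
        shifts.append(np.round(s).astype(int))
    shifts = np.array(shifts)
    los = shifts
    his = shifts + np.array([v.shape for v in volumes])
    lo = los.min(axis=0)
    hi = his.max(axis=0)
    out = np.full(tuple(hi - lo), -np.inf)
    for v, s in zip(volumes, shifts):
        sl = tuple(slice(s[a] - lo[a], s[a] - lo[a] + v.shape[a]) for a in range(3))
        np.maximum(out[sl], v.values, out=out[sl])
    out[np.isinf(out)] = 0.0
    origin = tuple(np.asarray(volumes[0].origin_mm) + (lo - shifts[0]) * dv)
    return Volume(out, voxel_mm=dv, origin_mm=origin)


def map_projection(volume: Volume, axis: int | str = "z") -> MAPImage:
    """Per-pixel maximum of |values| along the projection axis."""
    ax = _AXES[axis]
    data = np.max(np.abs(volume.values), axis=ax)
    return MAPImage(data=data, axis=ax, voxel_mm=volume.voxel_mm)


def depth_encode(volume: Volume, axis: int | str = "z", colormap: str = "jet") -> DepthEncodedImage:
    """Color-code the depth of each MAP pixel's maximum along ``axis``."""
    from matplotlib import colormaps

    ax = _AXES[axis]
    mag = np.abs(volume.values)
    amp = mag.max(axis=ax)
    idx = mag.argmax(axis=ax)  # first maximum on ties
    extent = volume.shape[ax] * volume.voxel_mm
    depth_mm = idx * volume.voxel_mm
    cmap = colormaps[colormap]
    frac = depth_mm / extent if extent > 0 else depth_mm
    rgb = np.asarray(cmap(frac))[..., :3]
    peak = amp.max()
    bright = amp / peak if peak > 0 else amp
    rgb = rgb * bright[..., None]
    rgb[amp == 0] = 0.0
    return DepthEncodedImage(
        rgb=rgb, depth_mm=depth_mm, amplitude=amp, axis=ax, voxel_mm=volume.voxel_mm
    )


def measure_fwhm(
    volume: Volume, axis: int | str, through_point: tuple[int, int, int]
) -> float:
    """Full width at half maximum (mm) of |amplitude| along one grid line.

    The 1D profile passes through ``through_point`` (voxel indices); the
    width is measured around the profile's maximum with linear
    interpolation at the half-maximum crossings, walking outward from the
    peak (so side lobes beyond the first crossing are ignored).
    """
    ax = _AXES[axis]
    idx = list(through_point)
    sl = tuple(slice(None) if a == ax else idx[a] for a in range(3))
    profile = np.abs(volume.values[sl]).astype(float)
    n = len(profile)
    p = int(np.argmax(profile))
    peak = profile[p]
    if peak <= 0:
        raise ValueError("profile has no positive maximum")
    half = peak / 2.0

    def _cross(start: int, step: int) -> float:
        i = start
        while 0 <= i + step < n:
            j = i + step
            if profile[j] < half:
                # linear interpolation between i and j
                f = (profile[i] - half) / (profile[i] - profile[j])
                return i + step * f
            i = j
        raise ValueError("profile never falls below half maximum within the grid")

    left = _cross(p, -1)
    right = _cross(p, +1)
    return float((right - left) * volume.voxel_mm)
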