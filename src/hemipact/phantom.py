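"""Synthetic absorption phantoms and dynamic / multi-wavelength sequences.

These generators stand in for in vivo data: calibration microspheres
(point targets), branching vessel trees with ellipsoidal organ blobs,
indocyanine-green (ICG) bolus-perfusion sequences with vessel -> kidney
-> liver kinetics plus respiration/cardiac modulation, and dual-
wavelength (750/850 nm) hemoglobin sequences under a hyperoxia/hypoxia
protocol.  Every generator is a pure function of its parameters and
seed, and dynamic generators emit their ground truth (labels, curves,
sO2 schedule) so each downstream stage has an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from hemipact.core import GridSpec, Volume, VolumeSequence
from hemipact.unmixing import ExtinctionTable

__all__ = [
    "CompartmentModel",
    "Modulation",
    "OxygenChallengeProtocol",
    "OxygenChallengeResult",
    "make_point_phantom",
    "rasterize_tube",
    "rasterize_ellipsoid",
    "make_vessel_phantom",
    "gamma_variate",
    "default_icg_compartments",
    "make_icg_sequence",
    "make_oxygen_challenge",
]


def make_point_phantom(
    grid_spec: GridSpec,
    center_mm: tuple[float, float, float],
    diameter_um: float,
    amplitude: float = 1.0,
) -> Volume:
    """Rasterize a microsphere; sub-voxel spheres occupy the nearest voxel."""
    g = grid_spec
    center = np.asarray(center_mm, dtype=float)
    lo = np.asarray(g.origin_mm)
    hi = lo + (np.asarray(g.shape) - 1) * g.voxel_mm
    if np.any(center < lo - g.voxel_mm / 2) or np.any(center > hi + g.voxel_mm / 2):
        raise ValueError(f"center {center_mm} outside grid")
    values = np.zeros(g.shape)
    radius_mm = diameter_um * 1e-3 / 2.0
    if amplitude == 0:
        return Volume(values, g.voxel_mm, g.origin_mm)
    xs, ys, zs = (g.axis_coords(a) for a in range(3))
    dist2 = (
        (xs[:, None, None] - center[0]) ** 2
        + (ys[None, :, None] - center[1]) ** 2
        + (zs[None, None, :] - center[2]) ** 2
    )
    mask = dist2 <= radius_mm**2
    if not mask.any():
        nearest = np.unravel_index(np.argmin(dist2), g.shape)
        values[nearest] = amplitude
    else:
        values[mask] = amplitude
    return Volume(values, g.voxel_mm, g.origin_mm)


def rasterize_tube(
    values: np.ndarray,
    grid_spec: GridSpec,
    p0_mm: np.ndarray,
    p1_mm: np.ndarray,
    radius_mm: float,
    amplitude: float = 1.0,
) -> None:
    """Add a cylindrical tube (with rounded caps) to ``values`` in place."""
    g = grid_spec
    p0 = np.asarray(p0_mm, dtype=float)
    p1 = np.asarray(p1_mm, dtype=float)
    lo_mm = np.minimum(p0, p1) - radius_mm
    hi_mm = np.maximum(p0, p1) + radius_mm
    lo = np.maximum(np.floor((lo_mm - g.origin_mm) / g.voxel_mm).astype(int), 0)
    hi = np.minimum(np.ceil((hi_mm - g.origin_mm) / g.voxel_mm).astype(int) + 1, g.shape)
    if np.any(lo >= hi):
        return
    axes = [g.axis_coords(a)[lo[a] : hi[a]] for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - p0) @ d) / dd, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    mask = np.sum((pts - closest) ** 2, axis=-1) <= radius_mm**2
    region = values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    region[mask] = np.maximum(region[mask], amplitude)


def rasterize_ellipsoid(
    values: np.ndarray,
    grid_spec: GridSpec,
    center_mm: np.ndarray,
    semiaxes_mm: np.ndarray,
    amplitude: float = 1.0,
) -> None:
    """Add an axis-aligned ellipsoid blob to ``values`` in place."""
    g = grid_spec
    c = np.asarray(center_mm, dtype=float)
    s = np.asarray(semiaxes_mm, dtype=float)
    xs, ys, zs = (g.axis_coords(a) for a in range(3))
    q = (
        ((xs[:, None, None] - c[0]) / s[0]) ** 2
        + ((ys[None, :, None] - c[1]) / s[1]) ** 2
        + ((zs[None, None, :] - c[2]) / s[2]) ** 2
    )
    mask = q <= 1.0
    values[mask] = np.maximum(values[mask], amplitude)


def make_vessel_phantom(
    grid_spec: GridSpec,
    seed: int,
    n_branches: int = 6,
    radius_range_mm: tuple[float, float] = (0.15, 0.45),
    n_organ_blobs: int = 0,
    amplitude_range: tuple[float, float] = (0.5, 1.0),
) -> Volume:
    """Random branching vessel tree (plus optional organ blobs).

    Deterministic for a fixed seed.  Branches start from random points,
    wander with correlated random directions, and occasionally split;
    radii taper toward branch tips.
    """
    if radius_range_mm[0] <= 0 or radius_range_mm[1] < radius_range_mm[0]:
        raise ValueError(f"degenerate radius range {radius_range_mm}")
    g = grid_spec
    rng = np.random.default_rng(seed)
    values = np.zeros(g.shape)
    lo = np.asarray(g.origin_mm)
    extent = np.asarray(g.extent_mm)
    hi = lo + extent

    def random_unit():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    stack = []
    for _ in range(n_branches):
        start = lo + rng.uniform(0.15, 0.85, size=3) * extent
        radius = rng.uniform(*radius_range_mm)
        stack.append((start, random_unit(), radius, rng.uniform(*amplitude_range), 0))

    seg_len = max(extent.max() / 8.0, 2.0 * g.voxel_mm)
    while stack:
        p, direction, radius, amp, depth = stack.pop()
        n_seg = int(rng.integers(3, 7))
        for _ in range(n_seg):
            direction = direction + 0.6 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            q = p + direction * seg_len
            q = np.clip(q, lo, hi)
            rasterize_tube(values, g, p, q, radius, amp)
            p = q
            if depth < 2 and rng.random() < 0.3:
                child_r = max(radius * rng.uniform(0.5, 0.8), radius_range_mm[0] / 2)
                stack.append((p.copy(), random_unit(), child_r, amp, depth + 1))
            radius = max(radius * 0.92, radius_range_mm[0] / 2)

    for _ in range(n_organ_blobs):
        c = lo + rng.uniform(0.25, 0.75, size=3) * extent
        semi = rng.uniform(0.08, 0.18, size=3) * extent
        rasterize_ellipsoid(values, g, c, semi, rng.uniform(0.2, 0.5))

    return Volume(values, g.voxel_mm, g.origin_mm)


def gamma_variate(t, t0: float, alpha: float, beta: float):
    """Peak-normalized gamma-variate bolus curve.

    0 for t <= t0 and ((t-t0)/(alpha beta))^alpha * exp(alpha - (t-t0)/beta)
    afterwards; the maximum value 1 occurs at t = t0 + alpha*beta.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(dt)
    pos = dt > 0
    out[pos] = (dt[pos] / (alpha * beta)) ** alpha * np.exp(alpha - dt[pos] / beta)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class Modulation:
    """Multiplicative physiological modulation of a dynamic sequence."""

    respiration_hz: float = 0.7
    cardiac_hz: float = 5.0
    respiration_depth: float = 0.05
    cardiac_depth: float = 0.02

    def factor(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            1.0
            + self.respiration_depth * np.sin(2.0 * np.pi * self.respiration_hz * t)
            + self.cardiac_depth * np.sin(2.0 * np.pi * self.cardiac_hz * t)
        )


@dataclass
class CompartmentModel:
    """Labelled anatomy with per-label time-activity curves."""

    label_map: Volume  # integer labels; 0 = background
    curves: dict[int, Callable[[np.ndarray], np.ndarray]]
    modulation: Modulation = field(default_factory=Modulation)
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        labels = set(np.unique(self.label_map.values)) - {0}
        missing = labels - set(self.curves)
        if missing:
            raise ValueError(f"labels without a curve: {sorted(missing)}")


VESSEL, KIDNEY, LIVER = 1, 2, 3


def default_icg_compartments(
    grid_spec: GridSpec | None = None,
    baseline: float = 0.3,
    dose: float = 1.0,
) -> CompartmentModel:
    """Default ICG kinetics: bolus reaching vessel, then kidney, then liver.

    Gamma-variate uptake per compartment, peaking at ~5 s (vessel), ~20 s
    (kidney) and ~60 s (liver) after a t0 = 2 s injection delay, on top
    of a constant blood baseline.  Geometry: a vessel tube crossing the
    volume and two ellipsoidal organs.
    """
    g = grid_spec or GridSpec()
    values = np.zeros(g.shape, dtype=np.int16)
    lo = np.asarray(g.origin_mm)
    extent = np.asarray(g.extent_mm)

    organ = np.zeros(g.shape)
    # kidney: ellipsoid in one half; liver: larger ellipsoid in the other
    rasterize_ellipsoid(organ, g, lo + extent * [0.3, 0.35, 0.45], extent * [0.13, 0.11, 0.11])
    values[organ > 0] = KIDNEY
    organ[:] = 0
    rasterize_ellipsoid(organ, g, lo + extent * [0.68, 0.62, 0.5], extent * [0.17, 0.15, 0.13])
    values[organ > 0] = LIVER
    organ[:] = 0
    # vessel tube across the volume, drawn last so it wins overlaps
    rasterize_tube(
        organ,
        g,
        lo + extent * [0.1, 0.8, 0.62],
        lo + extent * [0.9, 0.25, 0.62],
        0.035 * extent.min(),
    )
    values[organ > 0] = VESSEL

    label_map = Volume(values, g.voxel_mm, g.origin_mm)
    curves = {
        VESSEL: lambda t: baseline + dose * gamma_variate(t, 2.0, 3.0, 1.0),  # peak 5 s
        KIDNEY: lambda t: baseline + dose * gamma_variate(t, 5.0, 3.0, 5.0),  # peak 20 s
        LIVER: lambda t: baseline + 0.8 * dose * gamma_variate(t, 10.0, 3.0, 50.0 / 3.0),  # peak 60 s
    }
    names = {VESSEL: "vessel", KIDNEY: "kidney", LIVER: "liver"}
    return CompartmentModel(label_map=label_map, curves=curves, label_names=names)


def make_icg_sequence(
    compartments: CompartmentModel,
    duration_s: float = 60.0,
    frame_rate_hz: float = 5.0,
) -> VolumeSequence:
    """Dynamic contrast sequence: per-label curves times the label masks,
    multiplied by the respiration/cardiac modulation factor."""
    if frame_rate_hz <= 0:
        raise ValueError(f"frame_rate_hz must be positive, got {frame_rate_hz}")
    n_frames = int(round(duration_s * frame_rate_hz))
    times = np.arange(n_frames) / frame_rate_hz
    lm = compartments.label_map
    masks = {lab: lm.values == lab for lab in compartments.curves}
    mod = compartments.modulation.factor(times)
    frames = []
    for t, m in zip(times, mod):
        vals = np.zeros(lm.shape)
        for lab, curve in compartments.curves.items():
            vals[masks[lab]] = curve(np.asarray(t))
        frames.append(Volume(vals * m, lm.voxel_mm, lm.origin_mm))
    return VolumeSequence(frames=frames, frame_rate_hz=frame_rate_hz)


@dataclass(frozen=True)
class OxygenChallengeProtocol:
    """Inhaled-gas schedule: list of (duration_s, sO2 level) segments.

    The published protocol alternates 2 min of hyperoxia with 2 min of
    hypoxia and back.
    """

    segments: tuple[tuple[float, float], ...] = ((120.0, 0.95), (120.0, 0.70), (120.0, 0.95))
    wavelengths_nm: tuple[float, float] = (750.0, 850.0)

    def __post_init__(self):
        for dur, s in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if not 0.0 <= s <= 1.0:
                raise ValueError("sO2 levels must be within [0, 1]")

    def so2_at(self, t) -> np.ndarray:
        """Piecewise-constant sO2 level at time t (last level persists)."""
        t = np.asarray(t, dtype=float)
        edges = np.cumsum([d for d, _ in self.segments])
        idx = np.searchsorted(edges, t, side="right")
        idx = np.minimum(idx, len(self.segments) - 1)
        levels = np.array([s for _, s in self.segments])
        return levels[idx]

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for d, _ in self.segments))


@dataclass
class OxygenChallengeResult:
    """Dual-wavelength sequences and the generating ground truth."""

    seq_750: VolumeSequence
    seq_850: VolumeSequence
    so2_true: np.ndarray  # per-frame sO2 level
    hbt_map: Volume  # total hemoglobin spatial map
    c_hbo_true: VolumeSequence
    c_hbr_true: VolumeSequence


def make_oxygen_challenge(
    label_map: Volume,
    protocol: OxygenChallengeProtocol,
    extinction_table: ExtinctionTable,
    frame_rate_hz: float = 0.1,
    hbt_amplitude: float = 1.0,
) -> OxygenChallengeResult:
    """Compose dual-wavelength amplitude sequences from the sO2 schedule.

    Per voxel and frame, PA_lambda = eps_HbO(lambda) * C_HbO + eps_HbR(lambda)
    * C_HbR with C_HbO = sO2(t) * HbT and C_HbR = (1 - sO2(t)) * HbT on the
    labelled (vessel) voxels.
    """
    for wl in protocol.wavelengths_nm:
        if wl not in extinction_table.wavelengths_nm:
            raise ValueError(f"extinction table missing wavelength {wl} nm")
    n_frames = max(int(round(protocol.total_duration_s * frame_rate_hz)), 1)
    times = np.arange(n_frames) / frame_rate_hz
    so2 = protocol.so2_at(times)
    hbt = (label_map.values > 0).astype(float) * hbt_amplitude
    hbt_map = Volume(hbt, label_map.voxel_mm, label_map.origin_mm)
    wl_lo, wl_hi = protocol.wavelengths_nm
    frames = {wl_lo: [], wl_hi: []}
    c_hbo_frames, c_hbr_frames = [], []
    for s in so2:
        c_hbo = s * hbt
        c_hbr = (1.0 - s) * hbt
        c_hbo_frames.append(Volume(c_hbo, label_map.voxel_mm, label_map.origin_mm))
        c_hbr_frames.append(Volume(c_hbr, label_map.voxel_mm, label_map.origin_mm))
        for wl in (wl_lo, wl_hi):
            e_hbo, e_hbr = extinction_table.coefficients(wl)
            pa = e_hbo * c_hbo + e_hbr * c_hbr
            frames[wl].append(Volume(pa, label_map.voxel_mm, label_map.origin_mm))
    return OxygenChallengeResult(
        seq_750=VolumeSequence(frames[wl_lo], frame_rate_hz, [wl_lo] * n_frames),
        seq_850=VolumeSequence(frames[wl_hi], frame_rate_hz, [wl_hi] * n_frames),
        so2_true=so2,
        hbt_map=hbt_map,
        c_hbo_true=VolumeSequence(c_hbo_frames, frame_rate_hz),
        c_hbr_true=VolumeSequence(c_hbr_frames, frame_rate_hz),
    )
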