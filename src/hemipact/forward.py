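"""Acoustic forward model: band-limited per-element time series from a volume.

Each absorbing voxel is treated as a point source under uniform optical
fluence (amplitude = absorption).  A voxel with amplitude ``A`` at
distance ``r`` from a (point-detector) element contributes

    A * (r_ref / r) * h(t - r / c)

where ``h`` is the transducer impulse response (a Gaussian-enveloped
cosine whose -6 dB spectral band matches the stated fractional
bandwidth), ``c`` the homogeneous speed of sound, and ``r_ref`` the array
radius (spherical-spreading normalization so that amplitudes are O(1)
near the center of curvature).  The physical N-shaped photoacoustic
wavelet is folded into ``h`` (delta excitation through the band-pass),
which keeps the envelope peak of the received pulse at ``t = r/c`` — the
arrival time the delay-and-sum inverse assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from hemipact.core import Volume
from hemipact.geometry import ArrayGeometry, ElementSubset

__all__ = ["TransducerIR", "SignalFrame", "impulse_response", "simulate_signals", "add_noise"]


@dataclass(frozen=True)
class TransducerIR:
    """Transducer impulse response: analytic form plus discrete taps.

    ``kernel`` is the zero-mean (band-pass, no DC), unit-peak sampled
    version, centered so that tap ``(n_taps - 1) / 2`` is lag zero.
    ``envelope_sigma_s`` parameterizes the continuous Gaussian-cosine
    form, which the simulator evaluates at exact (sub-sample) lags: the
    carrier has only ~4 samples per cycle at the DAQ rate, so
    interpolating the discrete taps would attenuate contributions by a
    sub-sample-phase-dependent factor.
    """

    center_frequency_hz: float
    fractional_bandwidth: float
    sample_rate_hz: float
    kernel: np.ndarray
    envelope_sigma_s: float = 0.0

    @property
    def n_taps(self) -> int:
        return len(self.kernel)

    @property
    def half_duration_s(self) -> float:
        return (self.n_taps - 1) / 2.0 / self.sample_rate_hz


@dataclass
class SignalFrame:
    """Per-element time series for one laser shot / volumetric frame.

    ``samples`` rows follow ``subset.indices`` order.  The time of sample
    ``j`` is ``t0_s + j / sample_rate_hz``.
    """

    samples: np.ndarray
    sample_rate_hz: float
    t0_s: float
    subset: ElementSubset
    speed_of_sound_m_s: float
    wavelength_nm: float | None = None
    noise_seed: int | None = None

    @property
    def n_elements(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sample_rate_hz


def impulse_response(
    center_frequency_hz: float = 2.02e6,
    fractional_bandwidth: float = 0.54,
    sample_rate_hz: float = 8.33e6,
    n_taps: int = 255,
) -> TransducerIR:
    """Gaussian-enveloped cosine whose -6 dB band is fc * (1 +/- fbw / 2).

    For a Gaussian envelope exp(-t^2 / (2 sigma_t^2)) the magnitude
    spectrum around fc is Gaussian with sigma_f = 1 / (2 pi sigma_t); the
    -6 dB (half-magnitude) full width is 2 sigma_f sqrt(2 ln 2), which is
    equated to fc * fbw.  The small DC leakage of the truncated kernel is
    removed by mean subtraction before peak normalization.
    """
    if center_frequency_hz >= sample_rate_hz / 2.0:
        raise ValueError("center frequency must be below Nyquist")
    if not 0 < fractional_bandwidth:
        raise ValueError("fractional bandwidth must be positive")
    if n_taps < 3:
        raise ValueError("n_taps must be at least 3")
    sigma_f = center_frequency_hz * fractional_bandwidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    t = (np.arange(n_taps) - (n_taps - 1) / 2.0) / sample_rate_hz
    kernel = np.cos(2.0 * np.pi * center_frequency_hz * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = kernel - kernel.mean()
    kernel = kernel / np.abs(kernel).max()
    return TransducerIR(
        center_frequency_hz=float(center_frequency_hz),
        fractional_bandwidth=float(fractional_bandwidth),
        sample_rate_hz=float(sample_rate_hz),
        kernel=kernel,
        envelope_sigma_s=sigma_t,
    )


@njit(cache=True)
def _accumulate_signals(samples, vox_pos, amps, el_pos, fc, sigma_t, fs, t0, sos_mm_s, r_ref):
    n_el = el_pos.shape[0]
    n_vox = vox_pos.shape[0]
    n_t = samples.shape[1]
    half = 4.5 * sigma_t * fs  # Gaussian support in samples
    two_pi_fc = 2.0 * np.pi * fc
    inv_two_sig2 = 1.0 / (2.0 * sigma_t * sigma_t)
    dt = 1.0 / fs
    for e in range(n_el):
        ex, ey, ez = el_pos[e, 0], el_pos[e, 1], el_pos[e, 2]
        for v in range(n_vox):
            dx = vox_pos[v, 0] - ex
            dy = vox_pos[v, 1] - ey
            dz = vox_pos[v, 2] - ez
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            tau = (r / sos_mm_s - t0) * fs  # arrival time in samples
            w = amps[v] * (r_ref / r)
            j0 = int(np.ceil(tau - half))
            j1 = int(np.floor(tau + half))
            if j0 < 0:
                j0 = 0
            if j1 > n_t - 1:
                j1 = n_t - 1
            for j in range(j0, j1 + 1):
                lag = (j - tau) * dt
                samples[e, j] += w * np.cos(two_pi_fc * lag) * np.exp(-lag * lag * inv_two_sig2)


def _time_window(geom: ArrayGeometry, volume: Volume, ir: TransducerIR, sos_m_s: float):
    """Recording window covering every grid-corner time of flight.

    The window is computed from the *whole* array so frames simulated with
    different subsets of the same geometry share t0 and sample count (the
    cluster rows of a full frame are then exactly the cluster frame).
    """
    g = volume.grid
    corners = np.array(
        [
            [g.axis_coords(0)[i], g.axis_coords(1)[j], g.axis_coords(2)[k]]
            for i in (0, -1)
            for j in (0, -1)
            for k in (0, -1)
        ]
    )
    d = np.linalg.norm(corners[:, None, :] - geom.element_positions[None, :, :], axis=2)
    sos_mm_s = sos_m_s * 1e3
    t0 = d.min() / sos_mm_s - ir.half_duration_s
    t_end = d.max() / sos_mm_s + ir.half_duration_s
    n_samples = int(np.ceil((t_end - t0) * ir.sample_rate_hz)) + 1
    return t0, n_samples


def simulate_signals(
    volume: Volume,
    geom: ArrayGeometry,
    subset: ElementSubset,
    ir: TransducerIR,
    speed_of_sound_m_s: float = 1500.0,
    t_window: tuple[float, int] | None = None,
    wavelength_nm: float | None = None,
) -> SignalFrame:
    """Synthesize the band-limited per-element time series of a volume.

    ``t_window`` optionally fixes ``(t0_s, n_samples)``; by default the
    window covers the full grid's time-of-flight range for the whole
    array, so it is subset-independent.
    """
    if len(subset) == 0:
        raise ValueError("cannot simulate an empty element subset")
    if speed_of_sound_m_s <= 0:
        raise ValueError("speed of sound must be positive")

    if t_window is None:
        t0, n_samples = _time_window(geom, volume, ir, speed_of_sound_m_s)
    else:
        t0, n_samples = t_window

    nz = np.nonzero(volume.values)
    amps = np.ascontiguousarray(volume.values[nz], dtype=np.float64)
    g = volume.grid
    vox_pos = np.stack(
        [
            g.origin_mm[0] + g.voxel_mm * nz[0],
            g.origin_mm[1] + g.voxel_mm * nz[1],
            g.origin_mm[2] + g.voxel_mm * nz[2],
        ],
        axis=1,
    ).astype(np.float64)

    if len(amps) and np.linalg.norm(vox_pos, axis=1).max() > geom.radius_mm:
        warnings.warn("source voxels outside the hemisphere radius are dropped")
        keep = np.linalg.norm(vox_pos, axis=1) <= geom.radius_mm
        vox_pos, amps = vox_pos[keep], amps[keep]

    samples = np.zeros((len(subset), n_samples), dtype=np.float64)
    if len(amps):
        el_pos = np.ascontiguousarray(subset.positions(geom), dtype=np.float64)
        _accumulate_signals(
            samples,
            np.ascontiguousarray(vox_pos),
            amps,
            el_pos,
            ir.center_frequency_hz,
            ir.envelope_sigma_s,
            ir.sample_rate_hz,
            t0,
            speed_of_sound_m_s * 1e3,
            geom.radius_mm,
        )
    return SignalFrame(
        samples=samples,
        sample_rate_hz=ir.sample_rate_hz,
        t0_s=t0,
        subset=subset,
        speed_of_sound_m_s=float(speed_of_sound_m_s),
        wavelength_nm=wavelength_nm,
    )


def add_noise(frame: SignalFrame, snr_db: float, seed: int) -> SignalFrame:
    """Additive white Gaussian noise at the requested SNR (dB re frame RMS)."""
    if np.isinf(snr_db):
        return replace(frame, samples=frame.samples.copy(), noise_seed=seed)
    rms = np.sqrt(np.mean(frame.samples**2))
    if rms == 0:
        raise ValueError("cannot set a finite SNR on a zero-power frame")
    sigma = rms * 10.0 ** (-snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noisy = frame.samples + rng.normal(0.0, sigma, size=frame.samples.shape)
    return replace(frame, samples=noisy, noise_seed=seed)
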