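"""Full-reference image-quality metrics for volumes.

SSIM of two windows x, y:

    SSIM = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
           / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)),

with C1 = (K1 L)^2, C2 = (K2 L)^2, L the data range, and the windowed
moments mu, sigma^2, sigma_xy taken under a normalized box or Gaussian
window.  The volumetric score is the mean of the SSIM map.  MS-SSIM
combines the contrast-structure term across dyadic scales (low-pass +
2x downsampling) with the luminance term at the coarsest scale, raised
to the canonical scale weights; the published configuration is
``num_scales=4, scale_sigma=8`` with the default weight vector.

PSNR = 10 log10(peakval^2 / MSE); RMSE = sqrt(mean squared difference);
the error ratio of a dynamic trace is |mean_voi(x) - mean_voi(ref)| /
mean_voi(ref).

Metrics are intended to run on magnitude volumes under the same
normalization used for the training pairs (peakval defaults to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from hemipact.core import Volume

__all__ = [
    "SSIMConfig",
    "QualityReport",
    "ssim3d",
    "ms_ssim",
    "psnr",
    "rmse",
    "error_ratio",
]

# Canonical 5-scale MS-SSIM weights; truncated and renormalized for fewer scales.
_CANONICAL_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])


@dataclass(frozen=True)
class SSIMConfig:
    """Window and stability settings for SSIM / MS-SSIM.

    ``boundary`` selects how windows near the edge are handled: "valid"
    averages the SSIM map only where the window fits entirely inside the
    volume (metric default); "pad" uses zero-padded windows everywhere,
    which is the differentiable convention shared with the training loss.
    """

    data_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    window: str = "gaussian"  # "gaussian" | "box"
    sigma: float = 1.5
    window_size: int | None = None
    boundary: str = "valid"  # "valid" | "pad"
    num_scales: int = 4
    scale_sigma: float = 8.0
    scale_weights: tuple[float, ...] | None = None

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2

    def resolved_window_size(self, sigma: float | None = None) -> int:
        if self.window_size is not None:
            return self.window_size
        if self.window == "box":
            return 3
        s = self.sigma if sigma is None else sigma
        return 2 * int(np.ceil(3.0 * s)) + 1

    def resolved_weights(self) -> np.ndarray:
        if self.scale_weights is not None:
            w = np.asarray(self.scale_weights, dtype=float)
        else:
            w = _CANONICAL_WEIGHTS[: self.num_scales].copy()
        return w / w.sum()


@dataclass
class QualityReport:
    """MS-SSIM / PSNR / RMSE of one volume against its reference."""

    ms_ssim: float
    psnr_db: float
    rmse: float
    pred_id: str = ""
    ref_id: str = ""

    def as_dict(self) -> dict:
        return {
            "ms_ssim": self.ms_ssim,
            "psnr_db": self.psnr_db,
            "rmse": self.rmse,
            "pred_id": self.pred_id,
            "ref_id": self.ref_id,
        }


def gaussian_kernel1d(sigma: float, size: int) -> np.ndarray:
    """Normalized 1D Gaussian window of odd length ``size``."""
    if size % 2 != 1:
        raise ValueError("window size must be odd")
    x = np.arange(size) - size // 2
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def window_kernel1d(config: SSIMConfig, sigma: float | None = None) -> np.ndarray:
    size = config.resolved_window_size(sigma)
    if config.window == "box":
        return np.full(size, 1.0 / size)
    if config.window == "gaussian":
        return gaussian_kernel1d(config.sigma if sigma is None else sigma, size)
    raise ValueError(f"unknown window kind {config.window!r}")


def blur3d(x: np.ndarray, kernel1d: np.ndarray) -> np.ndarray:
    """Separable zero-padded correlation with the same 1D kernel on each axis."""
    out = x
    for ax in range(3):
        out = ndimage.correlate1d(out, kernel1d, axis=ax, mode="constant", cval=0.0)
    return out


def _as_array(v) -> np.ndarray:
    return v.values if isinstance(v, Volume) else np.asarray(v)


def ssim_components(x: np.ndarray, y: np.ndarray, config: SSIMConfig, sigma: float | None = None):
    """Windowed luminance and contrast-structure maps (pre-averaging)."""
    k = window_kernel1d(config, sigma)
    mu_x = blur3d(x, k)
    mu_y = blur3d(y, k)
    sxx = blur3d(x * x, k) - mu_x * mu_x
    syy = blur3d(y * y, k) - mu_y * mu_y
    sxy = blur3d(x * y, k) - mu_x * mu_y
    c1, c2 = config.c1, config.c2
    lum = (2.0 * mu_x * mu_y + c1) / (mu_x * mu_x + mu_y * mu_y + c1)
    cs = (2.0 * sxy + c2) / (sxx + syy + c2)
    if config.boundary == "valid":
        r = len(k) // 2
        if any(s <= 2 * r for s in x.shape):
            raise ValueError(
                f"volume of shape {x.shape} too small for window size {len(k)} in valid mode"
            )
        sl = tuple(slice(r, s - r) for s in x.shape)
        lum, cs = lum[sl], cs[sl]
    elif config.boundary != "pad":
        raise ValueError(f"unknown boundary mode {config.boundary!r}")
    return lum, cs


def ssim3d(x, y, config: SSIMConfig | None = None) -> float:
    """Mean windowed SSIM of two equally shaped volumes."""
    config = config or SSIMConfig()
    xa, ya = _as_array(x).astype(float), _as_array(y).astype(float)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    lum, cs = ssim_components(xa, ya, config)
    return float(np.mean(lum * cs))


def _downsample2(x: np.ndarray) -> np.ndarray:
    """2x low pass + dyadic subsampling (block mean over 2^3 cells)."""
    trim = tuple(slice(0, s - (s % 2)) for s in x.shape)
    x = x[trim]
    s = x.shape
    return x.reshape(s[0] // 2, 2, s[1] // 2, 2, s[2] // 2, 2).mean(axis=(1, 3, 5))


def ms_ssim(x, y, config: SSIMConfig | None = None) -> float:
    """Multi-scale SSIM across ``num_scales`` dyadic scales."""
    config = config or SSIMConfig()
    xa, ya = _as_array(x).astype(float), _as_array(y).astype(float)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    wsize = config.resolved_window_size(config.scale_sigma)
    min_edge = 2 ** (config.num_scales - 1) * wsize
    if min(xa.shape) < min_edge:
        raise ValueError(
            f"volume edge {min(xa.shape)} too small for {config.num_scales} scales "
            f"with window {wsize} (needs >= {min_edge})"
        )
    weights = config.resolved_weights()
    scale_cfg = replace(config, sigma=config.scale_sigma, window="gaussian")
    score = 1.0
    for i in range(config.num_scales):
        lum, cs = ssim_components(xa, ya, scale_cfg)
        mcs = max(float(np.mean(cs)), 0.0)
        if i == config.num_scales - 1:
            ml = max(float(np.mean(lum * cs)), 0.0)
            score *= ml ** weights[i]
        else:
            score *= mcs ** weights[i]
            xa, ya = _downsample2(xa), _downsample2(ya)
    return float(score)


def rmse(x, gt) -> float:
    """Root-mean-square voxel difference."""
    xa, ga = _as_array(x).astype(float), _as_array(gt).astype(float)
    if xa.shape != ga.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ga.shape}")
    return float(np.sqrt(np.mean((xa - ga) ** 2)))


def psnr(x, gt, peakval: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical volumes."""
    mse = rmse(x, gt) ** 2
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peakval**2 / mse))


def error_ratio(x, reference, voi=None) -> float:
    """|mean_voi(x) - mean_voi(ref)| / mean_voi(ref) at one time point.

    ``voi`` may be a tuple of slices, an object with a ``slices``
    attribute, or None (whole volume).
    """
    xa, ra = _as_array(x).astype(float), _as_array(reference).astype(float)
    sl = getattr(voi, "slices", voi)
    if sl is not None:
        xa, ra = xa[sl], ra[sl]
    ref_mean = ra.mean()
    if ref_mean == 0:
        raise ValueError("reference VOI mean is zero; error ratio undefined")
    return float(abs(xa.mean() - ref_mean) / ref_mean)


def quality_report(pred, ref, config: SSIMConfig | None = None, peakval: float = 1.0,
                   pred_id: str = "", ref_id: str = "") -> QualityReport:
    return QualityReport(
        ms_ssim=ms_ssim(pred, ref, config),
        psnr_db=psnr(pred, ref, peakval),
        rmse=rmse(pred, ref),
        pred_id=pred_id,
        ref_id=ref_id,
    )
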