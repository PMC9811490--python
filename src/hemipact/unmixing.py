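"""Two-wavelength linear spectral unmixing and oxygen-saturation mapping.

With photoacoustic amplitude volumes at 750 and 850 nm and the molar
extinction coefficients of oxy- (HbO) and deoxy-hemoglobin (HbR), the
per-voxel concentrations solve the 2x2 linear system

    [C_HbO]   [eps_HbO(750)  eps_HbR(750)]^-1  [PA_750]
    [C_HbR] = [eps_HbO(850)  eps_HbR(850)]     [PA_850],

and the oxygen saturation is sO2 = C_HbO / (C_HbO + C_HbR).  Before
unmixing, negative amplitudes are clipped to zero and a 3x3x3 median
filter suppresses voxel-wise mismatch between the two wavelengths.  A
total-hemoglobin (HbT) threshold mask separates vessel voxels from
background before sO2 statistics are taken.

Two negative-concentration policies are provided: the default clips the
unconstrained least-squares solution at zero post hoc; the "nnls" mode
solves the per-voxel non-negative least-squares problem exactly (for a
2x2 system the two coincide except where a sign constraint is active).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from hemipact.core import Volume

__all__ = [
    "ExtinctionTable",
    "FunctionalMaps",
    "default_extinction_table",
    "preprocess_functional",
    "unmix_two_wavelength",
    "compute_so2",
    "hbt_mask",
    "functional_maps",
]


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients per wavelength (relative units).

    ``table`` maps wavelength (nm) -> (eps_HbO, eps_HbR).
    """

    table: tuple[tuple[float, float, float], ...]  # (wavelength, eps_HbO, eps_HbR)

    @property
    def wavelengths_nm(self) -> tuple[float, ...]:
        return tuple(row[0] for row in self.table)

    def coefficients(self, wavelength_nm: float) -> tuple[float, float]:
        for wl, e_hbo, e_hbr in self.table:
            if wl == wavelength_nm:
                return e_hbo, e_hbr
        raise KeyError(f"wavelength {wavelength_nm} nm not in table")

    def matrix(self, wl_pair: tuple[float, float]) -> np.ndarray:
        """2x2 extinction matrix E with rows [eps_HbO, eps_HbR] per wavelength."""
        return np.array([self.coefficients(wl) for wl in wl_pair], dtype=float)

    def condition_number(self, wl_pair: tuple[float, float] = (750.0, 850.0)) -> float:
        return float(np.linalg.cond(self.matrix(wl_pair)))


def default_extinction_table() -> ExtinctionTable:
    """Literature molar extinction coefficients (cm^-1 / M) at 750/850 nm.

    Values from the standard compiled hemoglobin spectra; only their
    ratios matter for sO2, and all round-trip tests are table-agnostic.
    """
    return ExtinctionTable(table=((750.0, 518.0, 1405.0), (850.0, 1058.0, 691.0)))


@dataclass
class FunctionalMaps:
    """Per-voxel chromophore concentrations and oxygen saturation."""

    c_hbo: Volume
    c_hbr: Volume
    hbt: Volume
    so2: Volume  # defined (finite) only on the mask
    mask: Volume  # boolean


def preprocess_functional(volume: Volume, size: int = 3) -> Volume:
    """Clip negatives to zero, then apply a cubic median filter."""
    v = np.clip(volume.values, 0.0, None)
    v = ndimage.median_filter(v, size=size, mode="nearest")
    return volume.with_values(v)


def unmix_two_wavelength(
    pa750: Volume,
    pa850: Volume,
    table: ExtinctionTable,
    wl_pair: tuple[float, float] = (750.0, 850.0),
    mode: str = "clipped_lsq",
) -> tuple[Volume, Volume]:
    """Per-voxel inversion of the 2x2 extinction system.

    ``mode='clipped_lsq'`` (default) inverts E and clips negative
    concentrations to zero afterwards; ``mode='lsq'`` returns the raw
    solution; ``mode='nnls'`` solves the non-negative least-squares
    problem exactly (closed form for two chromophores).
    """
    if pa750.shape != pa850.shape:
        raise ValueError(f"shape mismatch: {pa750.shape} vs {pa850.shape}")
    E = table.matrix(wl_pair)
    cond = np.linalg.cond(E)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"extinction matrix is singular (condition number {cond:.3g})")
    pa = np.stack([pa750.values.ravel(), pa850.values.ravel()])
    c = np.linalg.solve(E, pa)
    if mode == "lsq":
        pass
    elif mode == "clipped_lsq":
        c = np.clip(c, 0.0, None)
    elif mode == "nnls":
        c = np.clip(c, 0.0, None)
        # Where a constraint is active, re-fit the free chromophore alone.
        for fixed, free in ((0, 1), (1, 0)):
            active = np.linalg.solve(E, pa)[fixed] < 0
            if active.any():
                col = E[:, free]
                c[free, active] = np.clip(col @ pa[:, active] / (col @ col), 0.0, None)
                c[fixed, active] = 0.0
    else:
        raise ValueError(f"unknown unmixing mode {mode!r}")
    shape = pa750.shape
    c_hbo = pa750.with_values(c[0].reshape(shape))
    c_hbr = pa750.with_values(c[1].reshape(shape))
    return c_hbo, c_hbr


def compute_so2(c_hbo: Volume, c_hbr: Volume) -> Volume:
    """sO2 = C_HbO / (C_HbO + C_HbR); NaN where HbT = 0."""
    hbt = c_hbo.values + c_hbr.values
    with np.errstate(divide="ignore", invalid="ignore"):
        so2 = np.where(hbt > 0, c_hbo.values / hbt, np.nan)
    return c_hbo.with_values(so2)


def hbt_mask(c_hbo: Volume, c_hbr: Volume, threshold_fraction: float = 0.1) -> Volume:
    """Vessel mask: HbT >= threshold_fraction * max(HbT).

    At threshold 0 the mask keeps all voxels with any hemoglobin
    (HbT > 0); an all-zero HbT yields an empty mask.
    """
    if not 0.0 <= threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be within [0, 1]")
    hbt = c_hbo.values + c_hbr.values
    peak = hbt.max()
    if peak <= 0:
        mask = np.zeros_like(hbt, dtype=bool)
    elif threshold_fraction == 0.0:
        mask = hbt > 0
    else:
        mask = hbt >= threshold_fraction * peak
    return c_hbo.with_values(mask)


def functional_maps(
    pa750: Volume,
    pa850: Volume,
    table: ExtinctionTable | None = None,
    threshold_fraction: float = 0.1,
    preprocess: bool = True,
    mode: str = "clipped_lsq",
) -> FunctionalMaps:
    """Full functional pipeline: preprocess, unmix, sO2, HbT mask."""
    table = table or default_extinction_table()
    if preprocess:
        pa750 = preprocess_functional(pa750)
        pa850 = preprocess_functional(pa850)
    c_hbo, c_hbr = unmix_two_wavelength(pa750, pa850, table, mode=mode)
    hbt = c_hbo.with_values(c_hbo.values + c_hbr.values)
    so2 = compute_so2(c_hbo, c_hbr)
    mask = hbt_mask(c_hbo, c_hbr, threshold_fraction)
    so2_masked = so2.values.copy()
    so2_masked[~mask.values.astype(bool)] = np.nan
    return FunctionalMaps(
        c_hbo=c_hbo,
        c_hbr=c_hbr,
        hbt=hbt,
        so2=so2.with_values(np.clip(so2_masked, 0.0, 1.0)),
        mask=mask,
    )
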