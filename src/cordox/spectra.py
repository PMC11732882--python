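"""Hemoglobin optical extinction spectra.

Oxygen-saturation imaging rests on the different near-infrared absorption of
oxygenated (HbO2) and deoxygenated (HbR) hemoglobin.  This module ships a
tabulated compilation of molar extinction coefficients for the two species
(cm^-1 M^-1, after the widely used literature compilations) covering
650-1000 nm, and a small container that interpolates it at arbitrary
wavelengths.  The five wavelengths used for spinal-cord oximetry
(700, 730, 760, 800 and 850 nm) are exact table rows.

Only ratios of extinction values matter downstream (concentrations are in
arbitrary units), so the table's role is to provide a realistic, full-rank
spectral design matrix with the correct qualitative structure: the HbR peak
near 760 nm, the isosbestic crossing near 800 nm and the HbO2-dominated
region above it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["ExtinctionTable", "load_default_extinction", "STUDY_WAVELENGTHS_NM"]

#: Wavelengths (nm) cycled during multispectral acquisition.
STUDY_WAVELENGTHS_NM = (700.0, 730.0, 760.0, 800.0, 850.0)


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction of HbO2 and HbR versus wavelength.

    Parameters
    ----------
    wavelengths : ndarray
        Strictly increasing wavelengths in nm.
    eps_hbo2, eps_hbr : ndarray
        Molar extinction coefficients (cm^-1 M^-1), strictly positive.
    """

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hbr: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        eo = np.asarray(self.eps_hbo2, dtype=float)
        er = np.asarray(self.eps_hbr, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("need at least two tabulated wavelengths")
        if not (wl.shape == eo.shape == er.shape):
            raise ValueError("wavelengths and extinction columns must align")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(eo <= 0) or np.any(er <= 0):
            raise ValueError("extinction coefficients must be positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "eps_hbo2", eo)
        object.__setattr__(self, "eps_hbr", er)

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def _check_range(self, wavelength_nm) -> np.ndarray:
        wl = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
        lo, hi = self.range_nm
        if np.any(wl < lo) or np.any(wl > hi):
            raise ValueError(
                f"wavelength outside tabulated range [{lo:g}, {hi:g}] nm"
            )
        return wl

    def extinction(self, wavelength_nm) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (eps_hbo2, eps_hbr) at the given wavelengths."""
        wl = self._check_range(wavelength_nm)
        eo = np.interp(wl, self.wavelengths, self.eps_hbo2)
        er = np.interp(wl, self.wavelengths, self.eps_hbr)
        if np.isscalar(wavelength_nm) or np.ndim(wavelength_nm) == 0:
            return float(eo[0]), float(er[0])
        return eo, er

    def design_matrix(self, wavelengths_nm) -> np.ndarray:
        """Spectral design matrix A with rows [eps_hbo2(l), eps_hbr(l)].

        Used both to synthesize absorption from concentrations and to invert
        measured spectra by least squares.
        """
        wl = self._check_range(wavelengths_nm)
        eo = np.interp(wl, self.wavelengths, self.eps_hbo2)
        er = np.interp(wl, self.wavelengths, self.eps_hbr)
        return np.column_stack([eo, er])


def load_default_extinction() -> ExtinctionTable:
    """Load the packaged HbO2/HbR extinction compilation (650-1000 nm)."""
    with resources.files("cordox.data").joinpath("hb_extinction.csv").open() as fh:
        raw = np.loadtxt(fh, delimiter=",", skiprows=1)
    return ExtinctionTable(raw[:, 0], raw[:, 1], raw[:, 2])
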