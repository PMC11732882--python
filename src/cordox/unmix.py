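"""Fluence normalization, linear spectral unmixing and the sO2 map.

Reconstructed amplitude at wavelength l is proportional to
mu_a(l) * Phi(l), so each volume is first divided by its optical fluence.
Per voxel the normalized spectrum m(l) then satisfies

    m(l) = eps_HbO2(l) * C_HbO2 + eps_HbR(l) * C_HbR

which is solved in the least-squares sense over all wavelengths (five by
default).  Oxygen saturation is the concentration ratio

    sO2 = HbO2 / (HbO2 + HbR)

stored on the 0-1 scale, defined only on voxels whose total hemoglobin
exceeds a fraction of the volume maximum (background stays undefined).
sO2 is invariant to any common rescaling of the five input volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import FluenceVolume
from .recon import ReconVolume
from .spectra import ExtinctionTable

__all__ = ["SpectralMaps", "fluence_normalize", "linear_unmix", "compute_so2"]


@dataclass
class SpectralMaps:
    """Unmixed chromophore volumes plus the masked sO2 map."""

    hbo2: np.ndarray
    hbr: np.ndarray
    hbt: np.ndarray
    so2: np.ndarray                     # NaN where undefined
    mask: np.ndarray                    # True where so2 is defined
    voxel_size: tuple[float, float, float] | None = None
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        defined = self.so2[self.mask]
        if defined.size and (np.nanmin(defined) < -1e-12
                             or np.nanmax(defined) > 1 + 1e-12):
            raise ValueError("defined sO2 values must lie in [0, 1]")
        if np.any(np.isfinite(self.so2) != self.mask):
            raise ValueError("so2 must be undefined exactly where mask is False")


def _as_array(vol) -> np.ndarray:
    if isinstance(vol, ReconVolume):
        return vol.values
    if isinstance(vol, FluenceVolume):
        return vol.phi
    return np.asarray(vol)


def fluence_normalize(
    volumes: dict[float, "ReconVolume | np.ndarray"],
    fluences: dict[float, "FluenceVolume | np.ndarray"],
    floor: float = 1e-3,
) -> tuple[dict[float, np.ndarray], np.ndarray]:
    """Divide each per-wavelength volume by its fluence, flooring low values.

    Returns the normalized arrays and a boolean map of voxels where any
    wavelength's fluence fell below ``floor`` (division clamped there).
    """
    out: dict[float, np.ndarray] = {}
    flagged = None
    for wl, vol in volumes.items():
        arr = _as_array(vol)
        phi = _as_array(fluences[wl])
        if phi.shape != arr.shape:
            raise ValueError(
                f"geometry mismatch at {wl} nm: {arr.shape} vs {phi.shape}"
            )
        low = phi < floor
        out[float(wl)] = arr / np.maximum(phi, floor)
        flagged = low if flagged is None else (flagged | low)
    return out, flagged


def linear_unmix(
    volumes: dict[float, "ReconVolume | np.ndarray"],
    table: ExtinctionTable,
    nonneg: str = "clip",
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise least-squares unmixing into (HbO2, HbR) concentrations.

    Parameters
    ----------
    volumes : mapping wavelength -> volume
        Fluence-normalized reconstructions; at least two wavelengths.
    nonneg : {"clip", "raw", "nnls"}
        ``clip`` (default) zeroes negative least-squares solutions,
        ``raw`` returns them untouched, ``nnls`` solves the constrained
        problem per voxel (slow; small volumes only).
    """
    wavelengths = sorted(float(w) for w in volumes)
    if len(wavelengths) < 2:
        raise ValueError("need at least two wavelengths to unmix")
    arrs = [_as_array(volumes[w]) for w in wavelengths]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("volumes must share a shape")
    A = table.design_matrix(wavelengths)
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError(
            f"spectral design matrix is rank-deficient for wavelengths "
            f"{wavelengths}"
        )
    M = np.stack([a.ravel() for a in arrs])            # (n_wl, n_vox)
    if nonneg == "nnls":
        from scipy.optimize import nnls

        C = np.empty((2, M.shape[1]))
        for j in range(M.shape[1]):
            C[:, j] = nnls(A, M[:, j])[0]
    else:
        C, *_ = np.linalg.lstsq(A, M, rcond=None)
        if nonneg == "clip":
            C = np.maximum(C, 0.0)
        elif nonneg != "raw":
            raise ValueError("nonneg must be 'clip', 'raw' or 'nnls'")
    return C[0].reshape(shape), C[1].reshape(shape)


def compute_so2(
    hbo2: np.ndarray,
    hbr: np.ndarray,
    hbt_threshold: float = 0.05,
    voxel_size=None,
    origin=None,
) -> SpectralMaps:
    """sO2 = HbO2 / (HbO2 + HbR) on voxels with HbT >= threshold * max(HbT).

    Voxels below the total-hemoglobin threshold are left undefined (NaN);
    the threshold is a fraction of the volume maximum, masking background.
    """
    if hbo2.shape != hbr.shape:
        raise ValueError("hbo2 and hbr must share a shape")
    if not 0.0 <= hbt_threshold < 1.0:
        raise ValueError("hbt_threshold must lie in [0, 1)")
    if np.any(hbo2 < 0) or np.any(hbr < 0):
        raise ValueError(
            "negative concentrations present; unmix with nonneg='clip' "
            "(or 'nnls') before computing sO2"
        )
    hbt = hbo2 + hbr
    hmax = hbt.max() if hbt.size else 0.0
    mask = (hbt > 0) & (hbt >= hbt_threshold * hmax)
    so2 = np.full(hbo2.shape, np.nan)
    np.divide(hbo2, hbt, out=so2, where=mask)
    if not np.any(mask):
        warnings.warn("no voxel exceeds the HbT threshold; sO2 is undefined "
                      "everywhere", stacklevel=2)
    return SpectralMaps(hbo2=hbo2, hbr=hbr, hbt=hbt, so2=so2, mask=mask,
                        voxel_size=voxel_size, origin=origin)
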