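"""Volumetric reconstruction: bandpass, deconvolution, delay-and-sum, stitch.

Per scan position the pipeline mirrors the instrument's processing chain:
traces are band-pass filtered (0.1-12 MHz, zero phase), Wiener-deconvolved
with the sensing-element response, and back-projected onto a voxel grid by
delay-and-sum, with each physical element split into 16 subelements tiling
its 7 mm^2 footprint.  Per-position volumes carry world origins and are
stitched along the scan axis with distance-to-frame-center weighting.

Everything here is linear in the input traces, which the unmixing stage
relies on: the same operator is applied at every wavelength, so voxel-wise
spectral ratios survive reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .forward import (
    AcquisitionConfig,
    DetectorArray,
    SinogramSet,
    subelement_positions,
)

__all__ = [
    "ReconConfig",
    "ReconVolume",
    "bandpass",
    "deconvolve",
    "backproject",
    "stitch",
    "reconstruct_sinograms",
    "save_volume_nifti",
]


@dataclass
class ReconConfig:
    bandpass_lo: float = 0.1e6
    bandpass_hi: float = 12e6
    wiener_reg: float = 1e-3
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    grid_center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # rel. to focus
    speed_of_sound: float = 1.5          # mm / us
    n_subelements: int = 16
    stitch_mode: str = "overlap_mean"
    interp: str = "linear"               # or "nearest"
    flavor: str = "das"                  # or "ubp" (derivative-weighted)

    def __post_init__(self) -> None:
        if not self.bandpass_lo < self.bandpass_hi:
            raise ValueError("bandpass_lo must be below bandpass_hi")
        m = int(round(np.sqrt(self.n_subelements)))
        if m * m != self.n_subelements:
            raise ValueError("n_subelements must be a perfect square")
        if self.stitch_mode not in ("overlap_mean", "overlap_max"):
            raise ValueError("stitch_mode must be overlap_mean or overlap_max")


@dataclass
class ReconVolume:
    """Reconstructed amplitudes with full world-geometry metadata."""

    values: np.ndarray
    wavelength: float
    origin: tuple[float, float, float]   # world coordinate of voxel (0,0,0) corner
    voxel_size: tuple[float, float, float]

    def voxel_centers(self) -> tuple[np.ndarray, ...]:
        return tuple(
            self.origin[a] + (np.arange(self.values.shape[a]) + 0.5)
            * self.voxel_size[a]
            for a in range(3)
        )


def bandpass(traces: np.ndarray, lo: float, hi: float, sampling_rate: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis (DC removed)."""
    nyq = sampling_rate / 2.0
    if not 0.0 < lo < hi < nyq:
        raise ValueError(
            f"band [{lo:g}, {hi:g}] Hz must lie inside (0, {nyq:g}) Hz"
        )
    sos = butter(order, [lo, hi], btype="bandpass", fs=sampling_rate,
                 output="sos")
    return sosfiltfilt(sos, traces, axis=-1)


def deconvolve(traces: np.ndarray, impulse_response: np.ndarray,
               wiener_reg: float = 1e-3) -> np.ndarray:
    """Wiener deconvolution H* / (|H|^2 + reg * max|H|^2) along the last axis.

    The kernel is treated as centered (zero-phase at its middle tap), so the
    group delay of the response is removed along with its shape.  With
    ``wiener_reg -> 0`` this inverts in-band content; with large reg it
    degenerates to a matched filter (correlation with the kernel).
    """
    h = np.asarray(impulse_response, dtype=float)
    if not np.any(h):
        raise ValueError("impulse response is identically zero")
    n = traces.shape[-1]
    kern = np.zeros(n)
    kern[: h.size] = h
    kern = np.roll(kern, -(h.size // 2))     # center tap to index 0
    H = np.fft.rfft(kern)
    denom = np.abs(H) ** 2 + wiener_reg * np.max(np.abs(H) ** 2)
    W = np.conj(H) / denom
    return np.fft.irfft(np.fft.rfft(traces, axis=-1) * W, n, axis=-1)


def _voxel_grid(config: ReconConfig, scan_position: float):
    shape = config.grid_shape
    vox = config.voxel_size
    center = np.array(config.grid_center) + np.array([0.0, 0.0, scan_position])
    origin = center - 0.5 * np.array(shape) * np.array(vox)
    axes = [origin[a] + (np.arange(shape[a]) + 0.5) * vox[a] for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    coords = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    return coords, tuple(origin)


def backproject(
    traces: np.ndarray,
    array: DetectorArray,
    config: ReconConfig,
    scan_position: float = 0.0,
    sampling_rate: float = 40e6,
    wavelength: float = float("nan"),
) -> ReconVolume:
    """Delay-and-sum back-projection of preprocessed traces onto a voxel grid.

    Each voxel accumulates, over all subelements, the trace value at the
    acoustic delay t = |r_voxel - r_subelement| / c (linear temporal
    interpolation by default).  The grid is centered on the acoustic focus
    at ``scan_position`` unless offset via ``config.grid_center``.
    """
    if traces.shape[0] != array.n_elements:
        raise ValueError("trace count does not match element count")
    n_samples = traces.shape[-1]
    coords, origin = _voxel_grid(config, scan_position)
    subel = subelement_positions(array, config.n_subelements)
    subel = subel + np.array([0.0, 0.0, scan_position])
    samples_per_mm = sampling_rate / (config.speed_of_sound * 1e6)

    # Guard: every voxel must be inside the recorded time-of-flight range.
    corners = origin + np.array(config.grid_shape) * np.array(config.voxel_size)
    bbox = np.array(np.meshgrid(*zip(origin, corners), indexing="ij")
                    ).reshape(3, -1).T
    elem = array.element_positions + np.array([0.0, 0.0, scan_position])
    max_r = np.linalg.norm(
        bbox[None, :, :] - elem[:, None, :], axis=2
    ).max() + np.sqrt(array.element_area_mm2)
    if max_r * samples_per_mm >= n_samples - 1:
        raise ValueError(
            f"voxel grid extends to {max_r:.1f} mm time-of-flight but traces "
            f"cover only {(n_samples - 1) / samples_per_mm:.1f} mm"
        )

    if config.flavor == "ubp":
        work = traces - np.gradient(traces, axis=-1) * np.arange(n_samples)
    elif config.flavor == "das":
        work = traces
    else:
        raise ValueError("flavor must be 'das' or 'ubp'")

    out = np.zeros(coords.shape[0])
    for e in range(array.n_elements):
        tr = work[e]
        for s in range(subel.shape[1]):
            r = np.linalg.norm(coords - subel[e, s], axis=1)
            tau = r * samples_per_mm
            if config.interp == "nearest":
                idx = np.clip(np.rint(tau).astype(np.intp), 0, n_samples - 1)
                out += tr[idx]
            else:
                i0 = np.clip(np.floor(tau).astype(np.intp), 0, n_samples - 2)
                frac = tau - i0
                out += tr[i0] * (1.0 - frac) + tr[i0 + 1] * frac
    out /= array.n_elements * subel.shape[1]
    return ReconVolume(
        values=out.reshape(config.grid_shape),
        wavelength=wavelength,
        origin=origin,
        voxel_size=tuple(config.voxel_size),
    )


def stitch(volumes: list[ReconVolume], mode: str = "overlap_mean") -> ReconVolume:
    """Combine per-position volumes on the union lattice along the scan axis.

    Overlapping voxels are blended by a triangular distance-to-frame-center
    weight along z (``overlap_mean``) or take the maximum (``overlap_max``);
    voxels covered by a single frame are copied unchanged.
    """
    if len(volumes) == 1:
        return volumes[0]
    vox = volumes[0].voxel_size
    wl = volumes[0].wavelength
    for v in volumes[1:]:
        if not np.allclose(v.voxel_size, vox):
            raise ValueError("stitched volumes must share voxel size")
    origins = np.array([v.origin for v in volumes])
    # All origins must sit on a common voxel lattice.
    steps = (origins - origins[0]) / np.array(vox)
    if not np.allclose(steps, np.round(steps), atol=1e-6):
        raise ValueError("volume origins are not commensurate with the lattice")
    steps = np.round(steps).astype(int)
    shapes = np.array([v.values.shape for v in volumes])
    lo = steps.min(axis=0)
    hi = (steps + shapes).max(axis=0)
    out_shape = tuple(hi - lo)
    origin = tuple(np.array(volumes[0].origin) + lo * np.array(vox))

    if mode == "overlap_max":
        acc = np.full(out_shape, -np.inf)
        seen = np.zeros(out_shape, dtype=bool)
        for v, st in zip(volumes, steps):
            sl = tuple(slice(s - l, s - l + n) for s, l, n in
                       zip(st, lo, v.values.shape))
            acc[sl] = np.maximum(acc[sl], v.values)
            seen[sl] = True
        acc[~seen] = 0.0
        return ReconVolume(acc, wl, origin, vox)

    acc = np.zeros(out_shape)
    wsum = np.zeros(out_shape)
    count = np.zeros(out_shape, dtype=np.int32)
    for v, st in zip(volumes, steps):
        nz = v.values.shape[2]
        zi = np.arange(nz)
        half = max((nz - 1) / 2.0, 1.0)
        w = 1.0 - np.abs(zi - (nz - 1) / 2.0) / half
        w = np.maximum(w, 1e-3)[None, None, :]
        sl = tuple(slice(s - l, s - l + n) for s, l, n in
                   zip(st, lo, v.values.shape))
        acc[sl] += v.values * w
        wsum[sl] += w
        count[sl] += 1
    out = np.where(wsum > 0, acc / np.maximum(wsum, 1e-30), 0.0)
    # Voxels covered by exactly one frame are copied bit-exactly.
    for v, st in zip(volumes, steps):
        sl = tuple(slice(s - l, s - l + n) for s, l, n in
                   zip(st, lo, v.values.shape))
        single = count[sl] == 1
        out[sl] = np.where(single, v.values, out[sl])
    return ReconVolume(out, wl, origin, vox)


def reconstruct_sinograms(
    sino: SinogramSet,
    config: ReconConfig,
    deconv_kernel: np.ndarray | None = None,
) -> dict[float, ReconVolume]:
    """Full per-wavelength chain: bandpass -> deconvolve -> DAS -> stitch."""
    acq: AcquisitionConfig = sino.config
    if deconv_kernel is None:
        deconv_kernel = acq.source_signature()
    out: dict[float, ReconVolume] = {}
    for iw, wl in enumerate(acq.wavelengths):
        per_pos = []
        for ip, zpos in enumerate(acq.scan_positions):
            tr = bandpass(sino.data[ip, iw], config.bandpass_lo,
                          config.bandpass_hi, acq.sampling_rate)
            tr = deconvolve(tr, deconv_kernel, config.wiener_reg)
            per_pos.append(
                backproject(tr, sino.array, config, scan_position=zpos,
                            sampling_rate=acq.sampling_rate, wavelength=wl)
            )
        out[float(wl)] = stitch(per_pos, mode=config.stitch_mode)
    return out


def save_volume_nifti(vol: ReconVolume, path) -> None:
    """Write a ReconVolume as NIfTI (mm units, right-handed, z scan axis)."""
    import nibabel as nib

    affine = np.diag(list(vol.voxel_size) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), path)
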