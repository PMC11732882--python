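"""Acoustic forward model for the spherical-array scanner.

Geometry follows the instrument: 512 piezo elements (~7 mm^2 each) on a
spherical cap of 40 mm radius with 110 degrees angular coverage (0.85 pi sr),
7 MHz center frequency, 2.6-8.6 MHz FWHM detection band, 40 MSps sampling,
five wavelengths cycled with 20 pulse averages each, and step-and-go scan
positions along the spine (z) axis.

Each nonzero voxel of an initial-pressure volume acts as a point source
whose contribution to an element at distance r is

    a(t) = p0 * dV / (4 pi r) * g'(t - r / c)

with g' the time-derivative of the band-limited element impulse response
(the familiar bipolar "N-shape" of a small absorber seen through a
band-pass transducer).  Traces are assembled by splatting the delta
amplitudes onto the time grid (linear interpolation) and convolving once
per trace with g'.  Pulse averaging is modeled by its sufficient statistic:
additive white Gaussian noise with standard deviation
noise_sigma / sqrt(n_averages).

Elements are point-like by default; an optional aperture mode averages each
element over a 4x4 tile of its 7 mm^2 footprint, which is what the
reconstruction-side subelement model is meant to undo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "DetectorArray",
    "AcquisitionConfig",
    "SinogramSet",
    "build_array",
    "element_impulse_response",
    "point_source_signature",
    "element_subelement_offsets",
    "simulate_signals",
    "scan_positions",
]

#: Golden angle used for the Fibonacci cap layout (radians).
_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class DetectorArray:
    """Elements on a spherical cap; the cap opens toward -y (the animal).

    Positions are relative to the acoustic focus (center of curvature) at
    the origin; scanning translates the whole array along z.
    """

    element_positions: np.ndarray
    element_normals: np.ndarray
    radius: float
    coverage_deg: float
    element_area_mm2: float = 7.0

    @property
    def n_elements(self) -> int:
        return self.element_positions.shape[0]

    @property
    def solid_angle_sr(self) -> float:
        """Cap solid angle 2 pi (1 - cos(coverage/2))."""
        half = np.deg2rad(self.coverage_deg / 2.0)
        return float(2.0 * np.pi * (1.0 - np.cos(half)))


@dataclass
class AcquisitionConfig:
    sampling_rate: float = 40e6          # samples / s
    n_samples: int = 2048
    wavelengths: tuple[float, ...] = (700.0, 730.0, 760.0, 800.0, 850.0)
    n_averages: int = 20
    noise_sigma: float = 0.0             # per single pulse
    speed_of_sound: float = 1.5          # mm / us
    scan_positions: tuple[float, ...] = (0.0,)
    seed: int = 0
    center_freq: float = 7e6
    band_lo: float = 2.6e6
    band_hi: float = 8.6e6
    ir_taps: int = 129

    def __post_init__(self) -> None:
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        if self.sampling_rate <= 2.0 * self.band_hi:
            raise ValueError("sampling_rate must exceed twice the upper band edge")

    def impulse_response(self) -> np.ndarray:
        return element_impulse_response(
            self.center_freq, self.band_lo, self.band_hi,
            self.sampling_rate, self.ir_taps,
        )

    def source_signature(self) -> np.ndarray:
        return point_source_signature(
            self.center_freq, self.band_lo, self.band_hi,
            self.sampling_rate, self.ir_taps,
        )


@dataclass
class SinogramSet:
    """Recorded traces indexed [scan_position, wavelength, element, sample]."""

    data: np.ndarray
    config: AcquisitionConfig
    array: DetectorArray

    def __post_init__(self) -> None:
        expected = (
            len(self.config.scan_positions),
            len(self.config.wavelengths),
            self.array.n_elements,
            self.config.n_samples,
        )
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} != {expected}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("geometry")
            g.create_dataset("element_positions", data=self.array.element_positions)
            g.create_dataset("element_normals", data=self.array.element_normals)
            g.attrs["radius_mm"] = self.array.radius
            g.attrs["coverage_deg"] = self.array.coverage_deg
            g.attrs["element_area_mm2"] = self.array.element_area_mm2
            c = f.create_group("config")
            c.attrs["sampling_rate_hz"] = self.config.sampling_rate
            c.attrs["n_samples"] = self.config.n_samples
            c.attrs["wavelengths_nm"] = self.config.wavelengths
            c.attrs["n_averages"] = self.config.n_averages
            c.attrs["noise_sigma"] = self.config.noise_sigma
            c.attrs["speed_of_sound_mm_us"] = self.config.speed_of_sound
            c.attrs["scan_positions_mm"] = self.config.scan_positions
            c.attrs["seed"] = self.config.seed
            c.attrs["center_freq_hz"] = self.config.center_freq
            c.attrs["band_lo_hz"] = self.config.band_lo
            c.attrs["band_hi_hz"] = self.config.band_hi
            c.attrs["ir_taps"] = self.config.ir_taps
            d = f.create_dataset("data", data=self.data)
            d.attrs["axes"] = "scan_position,wavelength,element,time_sample"

    @classmethod
    def from_hdf5(cls, path) -> "SinogramSet":
        import h5py

        with h5py.File(path, "r") as f:
            g, c = f["geometry"], f["config"]
            array = DetectorArray(
                element_positions=g["element_positions"][()],
                element_normals=g["element_normals"][()],
                radius=float(g.attrs["radius_mm"]),
                coverage_deg=float(g.attrs["coverage_deg"]),
                element_area_mm2=float(g.attrs["element_area_mm2"]),
            )
            config = AcquisitionConfig(
                sampling_rate=float(c.attrs["sampling_rate_hz"]),
                n_samples=int(c.attrs["n_samples"]),
                wavelengths=tuple(c.attrs["wavelengths_nm"]),
                n_averages=int(c.attrs["n_averages"]),
                noise_sigma=float(c.attrs["noise_sigma"]),
                speed_of_sound=float(c.attrs["speed_of_sound_mm_us"]),
                scan_positions=tuple(c.attrs["scan_positions_mm"]),
                seed=int(c.attrs["seed"]),
                center_freq=float(c.attrs["center_freq_hz"]),
                band_lo=float(c.attrs["band_lo_hz"]),
                band_hi=float(c.attrs["band_hi_hz"]),
                ir_taps=int(c.attrs["ir_taps"]),
            )
            return cls(data=f["data"][()], config=config, array=array)


def build_array(
    n_elements: int = 512,
    radius: float = 40.0,
    coverage_deg: float = 110.0,
    seed: int = 0,
    element_area_mm2: float = 7.0,
) -> DetectorArray:
    """Quasi-uniform Fibonacci-spiral element layout on a spherical cap.

    The cap axis points along +y (elements above the animal); every element
    sits exactly at ``radius`` from the focus, with polar angle at most
    ``coverage_deg / 2``.
    """
    if n_elements < 4:
        raise ValueError("need at least 4 elements")
    if not 0.0 < coverage_deg <= 180.0:
        raise ValueError("coverage_deg must lie in (0, 180]")
    half = np.deg2rad(coverage_deg / 2.0)
    i = np.arange(n_elements)
    # Uniform-in-area polar placement on the cap, golden-angle azimuths.
    cos_theta = 1.0 - (1.0 - np.cos(half)) * (i + 0.5) / n_elements
    theta = np.arccos(np.clip(cos_theta, -1.0, 1.0))
    phi0 = np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi)
    phi = phi0 + i * _GOLDEN_ANGLE
    sin_theta = np.sin(theta)
    pos = radius * np.column_stack([
        sin_theta * np.cos(phi),      # x
        np.cos(theta),                # y (cap axis)
        sin_theta * np.sin(phi),      # z (scan axis)
    ])
    normals = -pos / radius
    return DetectorArray(
        element_positions=pos,
        element_normals=normals,
        radius=float(radius),
        coverage_deg=float(coverage_deg),
        element_area_mm2=float(element_area_mm2),
    )


def _gaussian_band_spectrum(freqs, center_freq, band_lo, band_hi):
    # Split (two-sided) Gaussian: the detection band is not symmetric about
    # the center frequency (2.6-8.6 MHz around 7 MHz), so each flank gets
    # its own width, placing the half-maximum crossings exactly at the
    # band edges while the peak stays at center_freq.
    root = np.sqrt(2.0 * np.log(2.0))
    sigma_lo = (center_freq - band_lo) / root
    sigma_hi = (band_hi - center_freq) / root
    sigma = np.where(freqs < center_freq, sigma_lo, sigma_hi)
    return np.exp(-((freqs - center_freq) ** 2) / (2.0 * sigma**2))


def element_impulse_response(
    center_freq: float = 7e6,
    band_lo: float = 2.6e6,
    band_hi: float = 8.6e6,
    sampling_rate: float = 40e6,
    n_taps: int = 129,
) -> np.ndarray:
    """Band-limited element kernel with a Gaussian amplitude spectrum.

    The spectrum peaks (amplitude 1) at ``center_freq`` and crosses half
    maximum at ``band_lo`` and ``band_hi``; the returned time-domain kernel
    is zero-phase and centered at index ``n_taps // 2``.
    """
    if not band_lo < center_freq < band_hi:
        raise ValueError("need band_lo < center_freq < band_hi")
    if sampling_rate < 2.0 * band_hi:
        raise ValueError("sampling rate below 2x the upper band edge (aliasing)")
    freqs = np.fft.rfftfreq(n_taps, d=1.0 / sampling_rate)
    spectrum = _gaussian_band_spectrum(freqs, center_freq, band_lo, band_hi)
    kernel = np.fft.fftshift(np.fft.irfft(spectrum, n_taps))
    return kernel


def point_source_signature(
    center_freq: float = 7e6,
    band_lo: float = 2.6e6,
    band_hi: float = 8.6e6,
    sampling_rate: float = 40e6,
    n_taps: int = 129,
) -> np.ndarray:
    """Time-derivative of the element impulse response (N-shaped pulse).

    This is the trace a point absorber produces, and the kernel the
    reconstruction pipeline deconvolves with.  Scaled so its peak spectral
    amplitude is 1.
    """
    if not band_lo < center_freq < band_hi:
        raise ValueError("need band_lo < center_freq < band_hi")
    if sampling_rate < 2.0 * band_hi:
        raise ValueError("sampling rate below 2x the upper band edge (aliasing)")
    freqs = np.fft.rfftfreq(n_taps, d=1.0 / sampling_rate)
    spectrum = _gaussian_band_spectrum(freqs, center_freq, band_lo, band_hi)
    dspec = 2j * np.pi * freqs * spectrum
    dspec = dspec / np.max(np.abs(dspec))
    kernel = np.fft.fftshift(np.fft.irfft(dspec, n_taps))
    return kernel


def element_subelement_offsets(n_subelements: int, element_area_mm2: float) -> np.ndarray:
    """(n, 2) in-plane offsets tiling a square element footprint.

    ``n_subelements`` must be a perfect square; the m x m tile covers the
    element area, offsets relative to the element center in the tangent
    plane of the cap.
    """
    m = int(round(np.sqrt(n_subelements)))
    if m * m != n_subelements:
        raise ValueError("n_subelements must be a perfect square")
    side = np.sqrt(element_area_mm2)
    coords = (np.arange(m) + 0.5) / m - 0.5
    u, v = np.meshgrid(coords * side, coords * side, indexing="ij")
    return np.column_stack([u.ravel(), v.ravel()])


def tangent_basis(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis vectors perpendicular to each normal."""
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(normals), 1))
    near_z = np.abs(normals[:, 2]) > 0.9
    ref[near_z] = [1.0, 0.0, 0.0]
    u = np.cross(normals, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(normals, u)
    return u, v


def subelement_positions(
    array: DetectorArray, n_subelements: int
) -> np.ndarray:
    """World positions (n_elements, n_subelements, 3) of subelement centers."""
    if n_subelements == 1:
        return array.element_positions[:, None, :]
    offsets = element_subelement_offsets(n_subelements, array.element_area_mm2)
    u, v = tangent_basis(array.element_normals)
    return (
        array.element_positions[:, None, :]
        + offsets[None, :, 0, None] * u[:, None, :]
        + offsets[None, :, 1, None] * v[:, None, :]
    )


def scan_positions(start: float, step: float, count: int) -> np.ndarray:
    """Arithmetic sequence of array-focus offsets along the spine axis (mm)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    return start + step * np.arange(count, dtype=float)


def _splat_traces(
    source_xyz: np.ndarray,
    amplitudes: np.ndarray,
    detector_xyz: np.ndarray,
    n_samples: int,
    samples_per_mm: float,
) -> np.ndarray:
    """Accumulate 1/(4 pi r)-weighted deltas at time-of-flight delays."""
    traces = np.zeros((detector_xyz.shape[0], n_samples))
    for e, det in enumerate(detector_xyz):
        r = np.linalg.norm(source_xyz - det, axis=1)
        r = np.maximum(r, 1e-6)
        tau = r * samples_per_mm
        amp = amplitudes / (4.0 * np.pi * r)
        i0 = np.floor(tau).astype(np.intp)
        frac = tau - i0
        ok = i0 < n_samples - 1
        traces[e] += np.bincount(i0[ok], weights=amp[ok] * (1.0 - frac[ok]),
                                 minlength=n_samples)[:n_samples]
        traces[e] += np.bincount(i0[ok] + 1, weights=amp[ok] * frac[ok],
                                 minlength=n_samples)[:n_samples]
    return traces


def simulate_signals(
    p0_volumes,
    array: DetectorArray,
    config: AcquisitionConfig,
    model_aperture: bool = False,
    n_aperture_samples: int = 16,
) -> SinogramSet:
    """Simulate multiwavelength, multi-position detector traces.

    Parameters
    ----------
    p0_volumes : mapping wavelength -> InitialPressureVolume
        Initial-pressure grids sharing geometry.
    model_aperture : bool
        If True, average each element's response over ``n_aperture_samples``
        points tiling its footprint (finite-aperture blur); default treats
        elements as points.
    """
    wavelengths = tuple(config.wavelengths)
    missing = [wl for wl in wavelengths if float(wl) not in
               {float(k) for k in p0_volumes}]
    if missing:
        raise ValueError(f"missing p0 volumes for wavelengths {missing}")
    vols = {float(k): v for k, v in p0_volumes.items()}
    ref = vols[float(wavelengths[0])]
    for v in vols.values():
        if v.p0.shape != ref.p0.shape or v.voxel_size != ref.voxel_size:
            raise ValueError("p0 grids must share geometry")

    dvox = float(np.prod(ref.voxel_size))
    samples_per_mm = config.sampling_rate / (config.speed_of_sound * 1e6)
    signature = config.source_signature()
    rng = np.random.default_rng(config.seed)

    # World voxel-center coordinates shared by all wavelengths.
    centers = [
        ref.origin[a] + (np.arange(ref.p0.shape[a]) + 0.5) * ref.voxel_size[a]
        for a in range(3)
    ]

    if model_aperture:
        det_all = subelement_positions(array, n_aperture_samples)
    else:
        det_all = array.element_positions[:, None, :]
    n_ap = det_all.shape[1]

    data = np.zeros(
        (len(config.scan_positions), len(wavelengths),
         array.n_elements, config.n_samples)
    )
    any_in_fov = None
    for ip, zpos in enumerate(config.scan_positions):
        for iw, wl in enumerate(wavelengths):
            p0 = vols[float(wl)].p0
            idx = np.nonzero(p0)
            if idx[0].size == 0:
                continue
            src = np.column_stack([
                centers[0][idx[0]], centers[1][idx[1]], centers[2][idx[2]]
            ])
            src_rel = src - np.array([0.0, 0.0, zpos])
            if iw == 0:
                # Crude field-of-view heuristic: in view when below the
                # array's equatorial plane or close to the focus.
                rr = np.linalg.norm(src_rel, axis=1)
                in_fov = (src_rel[:, 1] <= 0) | (rr < array.radius * 0.5)
                if any_in_fov is None:
                    any_in_fov = in_fov
                else:
                    any_in_fov = any_in_fov | in_fov
            amp = p0[idx] * dvox / n_ap
            raw = np.zeros((array.n_elements, config.n_samples))
            for a in range(n_ap):
                det = det_all[:, a, :] + np.array([0.0, 0.0, zpos])
                raw += _splat_traces(
                    src_rel + np.array([0.0, 0.0, zpos]), amp, det,
                    config.n_samples, samples_per_mm,
                )
            data[ip, iw] = fftconvolve(raw, signature[None, :], mode="same")
    if any_in_fov is not None and not np.all(any_in_fov):
        warnings.warn(
            f"{int((~any_in_fov).sum())} source voxel(s) outside the array's "
            "field of view at every scan position", stacklevel=2
        )
    if config.noise_sigma > 0:
        data = data + rng.normal(
            0.0, config.noise_sigma / np.sqrt(config.n_averages), size=data.shape
        )
    return SinogramSet(data=data, config=config, array=array)
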