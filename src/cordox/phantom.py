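"""Synthetic spinal-cord chromophore phantoms and optical forward quantities.

The phantom is the ground-truth object of the whole pipeline: voxel grids of
oxy- and deoxyhemoglobin concentration (arbitrary molar units) describing a
cylindrical mouse spinal cord, partitioned along the rostro-caudal (z) axis
into thoracic, lumbar and sacral segments.  Each segment carries a known
oxygen saturation sO2 = C_HbO2 / (C_HbO2 + C_HbR), so every downstream
estimate can be compared against an exact truth.

From a phantom, this module derives the optical quantities that generate
optoacoustic signal:

* absorption  mu_a(lambda) = eps_HbO2(lambda) C_HbO2 + eps_HbR(lambda) C_HbR
* fluence     Phi(r, z) = exp(-4 ln2 r^2 / FWHM^2) exp(-mu_eff z)
              (Gaussian beam, default 10 mm FWHM, exponential depth decay)
* initial pressure p0 = Gamma mu_a Phi   (Gamma: Grueneisen efficiency)

World coordinates are right-handed with z along the scan (spine) axis and
illumination entering along -y from above; all lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import ExtinctionTable

__all__ = [
    "ChromophorePhantom",
    "FluenceVolume",
    "InitialPressureVolume",
    "SEGMENT_LABELS",
    "DEFAULT_SEGMENT_FRACTIONS",
    "DEFAULT_MU_EFF_MM",
    "make_cord_phantom",
    "absorption_map",
    "fluence_model",
    "initial_pressure",
    "save_phantom_nifti",
    "save_phantom_hdf5",
    "load_phantom_hdf5",
]

#: Integer labels of the named cord segments in ``segment_map``.
SEGMENT_LABELS = {"thoracic": 1, "lumbar": 2, "sacral": 3}

#: Fractions of cord length per segment; proportional to the vertebral
#: counts of the 23-segment scheme (T1-T13, L1-L6, S1-S4).
DEFAULT_SEGMENT_FRACTIONS = {"thoracic": 13 / 23, "lumbar": 6 / 23, "sacral": 4 / 23}

#: Default effective attenuation (mm^-1) per study wavelength; mildly
#: decreasing with wavelength as in soft tissue.
DEFAULT_MU_EFF_MM = {700.0: 0.10, 730.0: 0.095, 760.0: 0.09, 800.0: 0.085, 850.0: 0.08}


@dataclass
class ChromophorePhantom:
    """Voxelized HbO2/HbR concentrations with cord geometry annotations."""

    c_hbo2: np.ndarray
    c_hbr: np.ndarray
    voxel_size: tuple[float, float, float]
    cord_mask: np.ndarray
    segment_map: np.ndarray
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    grueneisen: float = 1.0
    segment_labels: dict[str, int] = field(default_factory=lambda: dict(SEGMENT_LABELS))

    def __post_init__(self) -> None:
        if self.c_hbo2.shape != self.c_hbr.shape:
            raise ValueError("chromophore grids must share a shape")
        if np.any(self.c_hbo2 < 0) or np.any(self.c_hbr < 0):
            raise ValueError("concentrations must be non-negative")
        hbt = self.c_hbo2 + self.c_hbr
        if np.any(self.cord_mask & (hbt <= 0) & (hbt.max() > 0)):
            raise ValueError("cord_mask must lie inside the non-zero HbT region")
        if np.any((self.segment_map != 0) & ~self.cord_mask):
            raise ValueError("segment_map must be zero outside cord_mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.c_hbo2.shape

    def hbt(self) -> np.ndarray:
        return self.c_hbo2 + self.c_hbr

    def so2(self) -> np.ndarray:
        """Ground-truth saturation; NaN where total hemoglobin is zero."""
        hbt = self.hbt()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(hbt > 0, self.c_hbo2 / hbt, np.nan)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of voxel centers along each axis."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.voxel_size[a]
            for a in range(3)
        )


@dataclass
class FluenceVolume:
    """Normalized optical fluence on a voxel grid (unit surface on-axis value)."""

    phi: np.ndarray
    wavelength: float
    beam_fwhm: float
    mu_eff: float


@dataclass
class InitialPressureVolume:
    """Initial acoustic pressure p0 = Gamma * mu_a * Phi on the phantom grid."""

    p0: np.ndarray
    wavelength: float
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


def make_cord_phantom(
    grid_shape=(48, 48, 120),
    voxel_size=(0.25, 0.25, 0.25),
    cord_radius_mm: float = 1.25,
    baseline_so2: float = 0.8,
    hbt_level: float = 1.0,
    regional_so2_multipliers: dict[str, float] | None = None,
    segment_fractions: dict[str, float] | None = None,
    n_vessels: int = 0,
    vessel_radius_mm: float = 0.15,
    vessel_hbt_multiplier: float = 2.0,
    grueneisen: float = 1.0,
    seed: int = 0,
) -> ChromophorePhantom:
    """Build a cylindrical cord phantom with per-segment oxygen saturation.

    The cord is a straight cylinder (default diameter 2.5 mm, typical for
    mouse) along z, laterally centered, spanning the full z extent, split
    into thoracic/lumbar/sacral segments by ``segment_fractions``.  Within
    segment ``s`` every cord voxel has exactly

        sO2(s) = baseline_so2 * regional_so2_multipliers[s]

    and total hemoglobin ``hbt_level`` (vessel voxels get
    ``vessel_hbt_multiplier`` times that, same saturation).  Identical seeds
    produce bitwise-identical phantoms.
    """
    if not 0.0 <= baseline_so2 <= 1.0:
        raise ValueError("baseline_so2 must lie in [0, 1]")
    multipliers = dict.fromkeys(SEGMENT_LABELS, 1.0)
    if regional_so2_multipliers:
        unknown = set(regional_so2_multipliers) - set(SEGMENT_LABELS)
        if unknown:
            raise ValueError(f"unknown segment name(s): {sorted(unknown)}")
        multipliers.update(regional_so2_multipliers)
    for name, mult in multipliers.items():
        so2 = baseline_so2 * mult
        if not 0.0 <= so2 <= 1.0:
            raise ValueError(
                f"multiplier {mult} pushes segment '{name}' sO2 to {so2:g}, "
                "outside [0, 1]"
            )
    fractions = dict(segment_fractions or DEFAULT_SEGMENT_FRACTIONS)
    if set(fractions) != set(SEGMENT_LABELS):
        raise ValueError("segment_fractions must cover thoracic/lumbar/sacral")

    nx, ny, nz = (int(n) for n in grid_shape)
    if min(nx, ny, nz) <= 0:
        raise ValueError("grid_shape entries must be positive")
    dx, dy, dz = (float(v) for v in voxel_size)
    rng = np.random.default_rng(seed)

    # Lateral center at x = y = 0; z runs from 0 to nz*dz.
    origin = (-nx * dx / 2.0, -ny * dy / 2.0, 0.0)
    x = origin[0] + (np.arange(nx) + 0.5) * dx
    y = origin[1] + (np.arange(ny) + 0.5) * dy
    z = origin[2] + (np.arange(nz) + 0.5) * dz
    xx, yy = np.meshgrid(x, y, indexing="ij")
    lateral = (xx**2 + yy**2 <= cord_radius_mm**2)
    cord_mask = np.repeat(lateral[:, :, None], nz, axis=2)

    length = nz * dz
    bounds = np.cumsum(
        [0.0] + [fractions[s] * length for s in ("thoracic", "lumbar", "sacral")]
    )
    segment_map = np.zeros((nx, ny, nz), dtype=np.int16)
    for name, (lo, hi) in zip(
        ("thoracic", "lumbar", "sacral"), zip(bounds[:-1], bounds[1:])
    ):
        in_z = (z >= lo) & (z < hi) if name != "sacral" else (z >= lo) & (z <= hi)
        segment_map[:, :, in_z] = SEGMENT_LABELS[name]
    segment_map[~cord_mask] = 0

    hbt = np.zeros((nx, ny, nz))
    hbt[cord_mask] = hbt_level
    for _ in range(n_vessels):
        # Thin high-HbT cylinders parallel to the cord axis.
        r = rng.uniform(0, cord_radius_mm - vessel_radius_mm)
        theta = rng.uniform(0, 2 * np.pi)
        cx, cy = r * np.cos(theta), r * np.sin(theta)
        vessel = ((xx - cx) ** 2 + (yy - cy) ** 2 <= vessel_radius_mm**2)
        hbt[np.repeat(vessel[:, :, None], nz, axis=2) & cord_mask] = (
            hbt_level * vessel_hbt_multiplier
        )

    so2_map = np.zeros((nx, ny, nz))
    for name, label in SEGMENT_LABELS.items():
        so2_map[segment_map == label] = baseline_so2 * multipliers[name]

    c_hbo2 = hbt * so2_map
    c_hbr = hbt * (1.0 - so2_map)
    c_hbr[hbt == 0] = 0.0
    if hbt_level == 0:
        cord_mask = np.zeros_like(cord_mask)
        segment_map = np.zeros_like(segment_map)
    return ChromophorePhantom(
        c_hbo2=c_hbo2,
        c_hbr=c_hbr,
        voxel_size=(dx, dy, dz),
        cord_mask=cord_mask,
        segment_map=segment_map,
        origin=origin,
        grueneisen=grueneisen,
    )


def absorption_map(
    phantom: ChromophorePhantom, wavelength: float, table: ExtinctionTable
) -> np.ndarray:
    """Voxel-wise optical absorption at one wavelength (arbitrary units)."""
    eps_o, eps_r = table.extinction(wavelength)
    return eps_o * phantom.c_hbo2 + eps_r * phantom.c_hbr


def fluence_model(
    grid_shape,
    voxel_size,
    wavelength: float,
    beam_fwhm: float = 10.0,
    mu_eff: float | None = None,
    entry_axis: int = 1,
    origin: tuple[float, float, float] | None = None,
) -> FluenceVolume:
    """Gaussian-beam / exponential-depth fluence on a voxel grid.

    The beam axis runs along ``entry_axis`` through the lateral center of
    the grid; depth is measured from the entry face (index 0 along that
    axis).  On-axis surface fluence is normalized to 1.
    """
    if beam_fwhm <= 0:
        raise ValueError("beam_fwhm must be positive")
    if mu_eff is None:
        mu_eff = float(np.interp(
            wavelength,
            sorted(DEFAULT_MU_EFF_MM),
            [DEFAULT_MU_EFF_MM[w] for w in sorted(DEFAULT_MU_EFF_MM)],
        ))
    if mu_eff < 0:
        raise ValueError("mu_eff must be non-negative")
    shape = tuple(int(n) for n in grid_shape)
    vox = tuple(float(v) for v in voxel_size)
    if origin is None:
        origin = tuple(-n * v / 2.0 for n, v in zip(shape, vox))
    axes = [origin[a] + (np.arange(shape[a]) + 0.5) * vox[a] for a in range(3)]

    # Depth 0 at the first voxel plane along the entry axis.
    depth = axes[entry_axis] - axes[entry_axis][0]
    lateral_axes = [a for a in range(3) if a != entry_axis]
    la, lb = lateral_axes
    ca = 0.5 * (axes[la][0] + axes[la][-1])
    cb = 0.5 * (axes[lb][0] + axes[lb][-1])
    r2 = (
        (axes[la] - ca)[:, None] ** 2 + ((axes[lb] - cb)[None, :]) ** 2
    )
    lateral = np.exp(-4.0 * np.log(2.0) * r2 / beam_fwhm**2)
    axial = np.exp(-mu_eff * depth)

    phi = np.ones(shape)
    # Broadcast lateral (la, lb) and axial (entry_axis) onto the 3D grid.
    shape_lat = [1, 1, 1]
    shape_lat[la] = shape[la]
    shape_lat[lb] = shape[lb]
    shape_ax = [1, 1, 1]
    shape_ax[entry_axis] = shape[entry_axis]
    phi = lateral.reshape(shape_lat) * axial.reshape(shape_ax)
    return FluenceVolume(phi=phi, wavelength=float(wavelength),
                         beam_fwhm=float(beam_fwhm), mu_eff=float(mu_eff))


def initial_pressure(
    mu_a: np.ndarray,
    phi: FluenceVolume | np.ndarray,
    grueneisen: float = 1.0,
    wavelength: float | None = None,
    voxel_size=(0.25, 0.25, 0.25),
    origin=(0.0, 0.0, 0.0),
) -> InitialPressureVolume:
    """Initial pressure p0 = Gamma * mu_a * Phi (elementwise)."""
    phi_arr = phi.phi if isinstance(phi, FluenceVolume) else np.asarray(phi)
    if phi_arr.shape != mu_a.shape:
        raise ValueError(
            f"shape mismatch: mu_a {mu_a.shape} vs fluence {phi_arr.shape}"
        )
    if wavelength is None and isinstance(phi, FluenceVolume):
        wavelength = phi.wavelength
    return InitialPressureVolume(
        p0=grueneisen * mu_a * phi_arr,
        wavelength=float(wavelength if wavelength is not None else np.nan),
        voxel_size=tuple(voxel_size),
        origin=tuple(origin),
    )


def phantom_initial_pressures(
    phantom: ChromophorePhantom,
    wavelengths,
    table: ExtinctionTable,
    fluences: dict[float, FluenceVolume] | None = None,
) -> dict[float, InitialPressureVolume]:
    """Per-wavelength p0 volumes for a phantom (uniform fluence if None)."""
    out = {}
    for wl in wavelengths:
        mu_a = absorption_map(phantom, wl, table)
        phi = fluences[wl] if fluences is not None else np.ones_like(mu_a)
        p0 = initial_pressure(
            mu_a, phi, phantom.grueneisen, wavelength=wl,
            voxel_size=phantom.voxel_size, origin=phantom.origin,
        )
        out[float(wl)] = p0
    return out


def save_phantom_nifti(phantom: ChromophorePhantom, out_dir) -> None:
    """Write one NIfTI per chromophore plus cord/segment label files."""
    import os

    import nibabel as nib

    affine = np.diag(list(phantom.voxel_size) + [1.0])
    affine[:3, 3] = phantom.origin
    os.makedirs(out_dir, exist_ok=True)
    for name, arr in (
        ("c_hbo2", phantom.c_hbo2),
        ("c_hbr", phantom.c_hbr),
        ("cord_mask", phantom.cord_mask.astype(np.uint8)),
        ("segment_map", phantom.segment_map.astype(np.int16)),
    ):
        nib.save(nib.Nifti1Image(np.asarray(arr), affine),
                 os.path.join(out_dir, f"{name}.nii"))


def save_phantom_hdf5(phantom: ChromophorePhantom, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("c_hbo2", data=phantom.c_hbo2)
        f.create_dataset("c_hbr", data=phantom.c_hbr)
        f.create_dataset("cord_mask", data=phantom.cord_mask)
        f.create_dataset("segment_map", data=phantom.segment_map)
        f.attrs["voxel_size_mm"] = phantom.voxel_size
        f.attrs["origin_mm"] = phantom.origin
        f.attrs["grueneisen"] = phantom.grueneisen


def load_phantom_hdf5(path) -> ChromophorePhantom:
    import h5py

    with h5py.File(path, "r") as f:
        return ChromophorePhantom(
            c_hbo2=f["c_hbo2"][()],
            c_hbr=f["c_hbr"][()],
            voxel_size=tuple(f.attrs["voxel_size_mm"]),
            cord_mask=f["cord_mask"][()].astype(bool),
            segment_map=f["segment_map"][()],
            origin=tuple(f.attrs["origin_mm"]),
            grueneisen=float(f.attrs["grueneisen"]),
        )
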