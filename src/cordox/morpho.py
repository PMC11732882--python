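"""Spinal-cord MRI morphometry on GM/WM label volumes.

Label convention: 0 background, 1 gray matter, 2 white matter, on an
isotropic grid (50 um in the study data).  Cross-sectional areas are plain
voxel counts times the in-plane voxel area, without cord-angle correction;
segment summaries average five consecutive slices centered on each of the
23 anchor slices (T1-T13, L1-L6, S1-S4).  Agreement between two
segmentations (e.g. automatic vs manual) is Spearman rank correlation over
their paired CSA values.

A synthetic generator produces elliptical-cord label volumes with analytic
per-slice areas, so every measurement here can be checked against a closed
form.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LabelVolume",
    "SEGMENT_SCHEME_23",
    "read_label_volume",
    "write_label_volume",
    "slice_csa",
    "segment_csa",
    "SpearmanResult",
    "segmentation_agreement",
    "synth_label_volume",
]

BACKGROUND, GM, WM = 0, 1, 2

#: The 23-segment labeling scheme: thoracic, lumbar, sacral.
SEGMENT_SCHEME_23 = tuple(
    [f"T{i}" for i in range(1, 14)]
    + [f"L{i}" for i in range(1, 7)]
    + [f"S{i}" for i in range(1, 5)]
)


@dataclass
class LabelVolume:
    """3D GM/WM segmentation with voxel dimensions (mm).

    ``rc_axis`` marks the rostro-caudal axis; axial slices are taken
    perpendicular to it.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    rc_axis: int = 2

    def __post_init__(self) -> None:
        bad = sorted(set(np.unique(self.labels)) - {BACKGROUND, GM, WM})
        if bad:
            raise ValueError(f"unexpected label value(s): {bad}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def n_slices(self) -> int:
        return self.labels.shape[self.rc_axis]

    def inplane_area_mm2(self) -> float:
        dims = [v for a, v in enumerate(self.voxel_size) if a != self.rc_axis]
        return float(dims[0] * dims[1])


def read_label_volume(path, rc_axis: int = 2) -> LabelVolume:
    """Load a NIfTI segmentation, validating the 0/1/2 label convention."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError("label volume must be integer-valued")
    return LabelVolume(
        labels=np.round(data).astype(np.int16),
        voxel_size=tuple(float(z) for z in img.header.get_zooms()[:3]),
        rc_axis=rc_axis,
    )


def write_label_volume(vol: LabelVolume, path) -> None:
    import nibabel as nib

    affine = np.diag(list(vol.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), affine), str(path))


def slice_csa(vol: LabelVolume) -> pd.DataFrame:
    """Per-axial-slice GM and WM cross-sectional areas (mm^2), no angle
    correction."""
    area = vol.inplane_area_mm2()
    moved = np.moveaxis(vol.labels, vol.rc_axis, 0)
    gm = (moved == GM).sum(axis=(1, 2)) * area
    wm = (moved == WM).sum(axis=(1, 2)) * area
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(wm > 0, gm / wm, np.nan)
    return pd.DataFrame({
        "slice_index": np.arange(vol.n_slices),
        "gm_csa": gm,
        "wm_csa": wm,
        "gm_wm_ratio": ratio,
    })


def segment_csa(
    table: pd.DataFrame,
    segment_anchor_slices: dict[str, int],
    window: int = 5,
) -> pd.DataFrame:
    """Mean of ``window`` consecutive slice CSAs centered on each anchor.

    Reports GM and WM means per segment plus both ratio conventions
    (GM/WM and WM/GM) of those means.
    """
    half = window // 2
    n = len(table)
    gm = table["gm_csa"].to_numpy()
    wm = table["wm_csa"].to_numpy()
    rows = []
    for seg, anchor in segment_anchor_slices.items():
        lo, hi = anchor - half, anchor + half + 1
        if lo < 0 or hi > n:
            raise ValueError(
                f"segment '{seg}': {window}-slice window [{lo}, {hi}) out of "
                f"range for {n} slices"
            )
        g, w = gm[lo:hi].mean(), wm[lo:hi].mean()
        rows.append({
            "segment": seg, "gm_csa": g, "wm_csa": w,
            "gm_wm_ratio": g / w if w > 0 else np.nan,
            "wm_gm_ratio": w / g if g > 0 else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass
class SpearmanResult:
    r: float
    p: float
    n: int
    defined: bool = True


def _spearman_rho(ra: np.ndarray, rb: np.ndarray) -> float:
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    return float((ra * rb).sum() / denom)


def segmentation_agreement(csa_a, csa_b) -> SpearmanResult:
    """Spearman rank correlation between two paired CSA series.

    Average ranks handle ties.  The two-sided p-value uses the
    t-approximation for n >= 10 and exact permutation enumeration below
    that; constant inputs give an undefined (flagged) result.
    """
    a = np.asarray(csa_a, dtype=float)
    b = np.asarray(csa_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1D and of equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return SpearmanResult(r=float("nan"), p=float("nan"), n=n,
                              defined=False)
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    rho = _spearman_rho(ra, rb)
    if n >= 10:
        # t approximation with n - 2 degrees of freedom
        t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    else:
        perms = np.array(list(permutations(rb)))
        rc = ra - ra.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt((rc**2).sum() * (pc**2).sum(axis=1))
        rhos = pc @ rc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return SpearmanResult(r=rho, p=float(p), n=n)


def synth_label_volume(
    cord_semiaxes_mm: tuple[float, float] = (1.3, 1.0),
    gm_semiaxes_mm: tuple[float, float] = (0.75, 0.55),
    n_slices: int = 120,
    inplane_shape: tuple[int, int] = (80, 80),
    voxel_size: float = 0.05,
    modulation: float = 0.1,
    seed: int = 0,
) -> tuple[LabelVolume, pd.DataFrame]:
    """Elliptical cord phantom with analytic per-slice ground-truth areas.

    The white matter is an outer ellipse, the gray matter a strictly
    interior inner ellipse (WM = cord minus GM); both sets of semi-axes are
    smoothly modulated along the rostro-caudal axis to emulate the natural
    taper of the cord.  Returns the label volume (rc axis last) and a table
    of exact pi*a*b areas per slice.
    """
    ac, bc = cord_semiaxes_mm
    ag, bg = gm_semiaxes_mm
    if not (ag < ac and bg < bc):
        raise ValueError("GM ellipse must lie strictly inside the cord ellipse")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    ny, nx = inplane_shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * voxel_size
    x = (np.arange(nx) - (nx - 1) / 2.0) * voxel_size
    yy, xx = np.meshgrid(y, x, indexing="ij")

    labels = np.zeros((ny, nx, n_slices), dtype=np.int16)
    recs = []
    for k in range(n_slices):
        scale = 1.0 + modulation * np.sin(2.0 * np.pi * k / n_slices + phase)
        a_c, b_c = ac * scale, bc * scale
        a_g, b_g = ag * scale, bg * scale
        cord = (xx / a_c) ** 2 + (yy / b_c) ** 2 <= 1.0
        gm = (xx / a_g) ** 2 + (yy / b_g) ** 2 <= 1.0
        sl = np.zeros((ny, nx), dtype=np.int16)
        sl[cord] = WM
        sl[gm] = GM
        labels[:, :, k] = sl
        gm_true = np.pi * a_g * b_g
        recs.append({
            "slice_index": k,
            "gm_area_true": gm_true,
            "wm_area_true": np.pi * a_c * b_c - gm_true,
        })
    vol = LabelVolume(labels=labels,
                      voxel_size=(voxel_size, voxel_size, voxel_size),
                      rc_axis=2)
    return vol, pd.DataFrame(recs)
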