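"""Formula-defined 2D histology metrics on binary fluorescence masks.

Implements the measurement formulas used on stained spinal-cord sections:

* CD31 vessel mask  -> area fraction, skeleton length (chamfer 1/sqrt(2)
  step weighting), branch-point count (skeleton pixels with >= 3 skeleton
  neighbors in 8-connectivity, merged within a 1-pixel radius);
* GLUT1 mask        -> area fraction;
* pS129 vs DAPI     -> relative nuclear signal area
  |pS129 ∩ DAPI| / |DAPI| and relative cytoplasmic signal area
  |pS129 \\ DAPI| / (|image| - |DAPI|);
* group comparison  -> two-sided Mann-Whitney U per metric with Holm-Sidak
  adjustment across metrics.

The synthetic generator draws random-walk vessel tubes, disk nuclei and
Bernoulli pS129 puncta with controlled nuclear/cytoplasmic densities, and
records the generating ground truth.  Thresholding of raw fluorescence
(Otsu or fixed) is provided for completeness, but the metrics operate on
binary masks, which is where the formulas live.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.morphology import skeletonize

__all__ = [
    "HistoMaskSet",
    "HistoMetrics",
    "area_fraction",
    "vessel_metrics",
    "ps129_colocalization",
    "synth_histo_masks",
    "histo_group_compare",
    "threshold_mask",
]


@dataclass
class HistoMaskSet:
    """Aligned binary channel masks on a common pixel grid."""

    masks: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share a shape")


@dataclass
class HistoMetrics:
    vascular_area_fraction: float
    vessel_length_um: float
    n_branches: int
    glut1_area_fraction: float
    nuclear_ps129_fraction: float
    cytoplasmic_ps129_fraction: float


def _check_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary (bool or 0/1)")
    return arr.astype(bool)


def area_fraction(mask: np.ndarray) -> float:
    """Foreground pixels over total pixels."""
    arr = _check_binary(mask)
    if arr.size == 0:
        raise ValueError("empty image")
    return float(arr.sum() / arr.size)


def _skeleton_length_px(skel: np.ndarray) -> float:
    """Chamfer length: 1 per orthogonal step, sqrt(2) per diagonal step.

    Counts unique 8-neighborhood edges; a diagonal edge is skipped when
    both of its adjacent orthogonal pixels are present (the path already
    runs through them).
    """
    s = skel.astype(bool)
    n_orth = np.sum(s[:, :-1] & s[:, 1:]) + np.sum(s[:-1, :] & s[1:, :])
    # Diagonals: down-right and down-left.
    dr = s[:-1, :-1] & s[1:, 1:]
    dr_skip = s[:-1, 1:] & s[1:, :-1]
    dl = s[:-1, 1:] & s[1:, :-1]
    dl_skip = s[:-1, :-1] & s[1:, 1:]
    n_diag = np.sum(dr & ~dr_skip) + np.sum(dl & ~dl_skip)
    return float(n_orth + np.sqrt(2.0) * n_diag)


def _branch_points(skel: np.ndarray) -> int:
    """Skeleton pixels with >= 3 skeleton neighbors, merged within 1 px."""
    s = skel.astype(np.uint8)
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    neigh = ndimage.convolve(s, kernel, mode="constant")
    cand = (s > 0) & (neigh >= 3)
    if not cand.any():
        return 0
    merged = ndimage.binary_dilation(cand, structure=np.ones((3, 3)))
    _, n = ndimage.label(merged, structure=np.ones((3, 3)))
    return int(n)


def vessel_metrics(
    vessel_mask: np.ndarray, pixel_size_um: float = 1.0
) -> tuple[float, float, int]:
    """(area_fraction, skeleton length in um, branch count) of a vessel mask."""
    mask = _check_binary(vessel_mask)
    frac = area_fraction(mask)
    if not mask.any():
        return 0.0, 0.0, 0
    skel = skeletonize(mask)
    length = _skeleton_length_px(skel) * pixel_size_um
    if skel.sum() == 1:          # single isolated pixel still has extent
        length = pixel_size_um
    return frac, float(length), _branch_points(skel)


def ps129_colocalization(
    ps129_mask: np.ndarray, dapi_mask: np.ndarray
) -> tuple[float, float]:
    """Relative nuclear and cytoplasmic pS129 signal areas.

    nuclear     = |pS129 ∩ DAPI| / |DAPI|
    cytoplasmic = |pS129 \\ DAPI| / (|image| - |DAPI|)

    An empty DAPI mask leaves the nuclear fraction undefined (NaN, with a
    warning); a full-image DAPI mask leaves the cytoplasmic fraction
    undefined.
    """
    ps = _check_binary(ps129_mask)
    dapi = _check_binary(dapi_mask)
    if ps.shape != dapi.shape:
        raise ValueError("masks must be aligned")
    n_dapi = int(dapi.sum())
    n_img = dapi.size
    if n_dapi == 0:
        warnings.warn("DAPI mask is empty; nuclear fraction undefined",
                      stacklevel=2)
        nuclear = float("nan")
    else:
        nuclear = float((ps & dapi).sum() / n_dapi)
    if n_dapi == n_img:
        warnings.warn("DAPI mask covers the image; cytoplasmic fraction "
                      "undefined", stacklevel=2)
        cyto = float("nan")
    else:
        cyto = float((ps & ~dapi).sum() / (n_img - n_dapi))
    return nuclear, cyto


def threshold_mask(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Binarize a fluorescence image (Otsu by default, fixed otherwise)."""
    img = np.asarray(image, dtype=float)
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = threshold_otsu(img)
    return img > threshold


def synth_histo_masks(
    shape: tuple[int, int] = (512, 512),
    n_vessels: int = 12,
    vessel_width_px: int = 3,
    n_nuclei: int = 150,
    nucleus_radius_px: int = 6,
    ps129_nuclear_fraction: float = 0.01227,
    ps129_cytoplasmic_fraction: float = 0.002,
    pixel_size_um: float = 1.0,
    seed: int = 0,
) -> tuple[HistoMaskSet, dict]:
    """Procedural CD31/GLUT1/pS129/DAPI mask set with recorded ground truth.

    Vessels are random-walk tubes of the given width, nuclei are disks,
    GLUT1 follows the vessel walls, and pS129 pixels are Bernoulli draws
    with probability ``ps129_nuclear_fraction`` inside DAPI and
    ``ps129_cytoplasmic_fraction`` outside (so the expected measured
    fractions equal the generating ones).  Identical seeds give identical
    masks.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    vessel = np.zeros(shape, dtype=bool)
    for _ in range(n_vessels):
        r = np.array([rng.uniform(0, h), rng.uniform(0, w)])
        ang = rng.uniform(0, 2 * np.pi)
        n_steps = int(0.6 * max(h, w))
        for _ in range(n_steps):
            ang += rng.normal(0.0, 0.15)
            r = r + np.array([np.sin(ang), np.cos(ang)])
            ri, ci = int(round(r[0])), int(round(r[1]))
            if not (0 <= ri < h and 0 <= ci < w):
                break
            vessel[ri, ci] = True
    if vessel.any() and vessel_width_px > 1:
        vessel = ndimage.binary_dilation(
            vessel, iterations=vessel_width_px // 2
        )

    dapi = np.zeros(shape, dtype=bool)
    yy, xx = np.ogrid[:h, :w]
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        dapi |= (yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius_px**2

    glut1 = ndimage.binary_dilation(vessel) if vessel.any() else vessel.copy()

    ps129 = np.zeros(shape, dtype=bool)
    u = rng.random(shape)
    ps129[dapi] = u[dapi] < ps129_nuclear_fraction
    ps129[~dapi] = u[~dapi] < ps129_cytoplasmic_fraction

    masks = HistoMaskSet(
        masks={"vessel": vessel, "glut1": glut1, "ps129": ps129, "dapi": dapi},
        pixel_size_um=pixel_size_um,
    )
    truth = {
        "ps129_nuclear_fraction": ps129_nuclear_fraction,
        "ps129_cytoplasmic_fraction": ps129_cytoplasmic_fraction,
        "n_vessels": n_vessels,
        "n_nuclei": n_nuclei,
        "dapi_area_fraction": float(dapi.mean()),
        "vessel_area_fraction": float(vessel.mean()),
    }
    return masks, truth


def compute_metrics(mask_set: HistoMaskSet) -> HistoMetrics:
    """All study metrics for one aligned mask set."""
    m = mask_set.masks
    vaf, vlen, nbr = vessel_metrics(m["vessel"], mask_set.pixel_size_um)
    nuc, cyt = ps129_colocalization(m["ps129"], m["dapi"])
    return HistoMetrics(
        vascular_area_fraction=vaf,
        vessel_length_um=vlen,
        n_branches=nbr,
        glut1_area_fraction=area_fraction(m["glut1"]),
        nuclear_ps129_fraction=nuc,
        cytoplasmic_ps129_fraction=cyt,
    )


def histo_group_compare(
    metrics: pd.DataFrame,
    group_col: str = "genotype",
    groups: tuple[str, str] = ("NTL", "M83"),
    metric_cols: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Mann-Whitney U per metric with Holm-Sidak adjustment across metrics.

    ``metrics`` holds one row per subject; returns a table with U, raw and
    adjusted two-sided p-values.  All-tied data yield p = 1 with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    ref, alt = groups
    a_rows = metrics[metrics[group_col] == ref]
    b_rows = metrics[metrics[group_col] == alt]
    if len(a_rows) < 3 or len(b_rows) < 3:
        raise ValueError("need at least 3 subjects per group")
    if metric_cols is None:
        metric_cols = tuple(
            c for c in metrics.columns
            if c != group_col and np.issubdtype(metrics[c].dtype, np.number)
        )
    recs = []
    for col in metric_cols:
        a = a_rows[col].to_numpy(float)
        b = b_rows[col].to_numpy(float)
        if np.all(a == b[0]) and np.all(b == b[0]):
            warnings.warn(f"metric '{col}': all values tied; p = 1",
                          stacklevel=2)
            u, p = a.size * b.size / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="auto")
            u, p = float(res.statistic), float(res.pvalue)
        recs.append({"metric": col, "U": u, "p_raw": p,
                     f"median_{ref}": float(np.median(a)),
                     f"median_{alt}": float(np.median(b))})
    out = pd.DataFrame(recs)
    raw = out["p_raw"].to_numpy()
    capped = np.minimum(raw, 1.0 - 1e-12)
    adj = np.minimum(multipletests(capped, method="holm-sidak")[1], 1.0)
    out["p_adj"] = np.where(raw >= 1.0, 1.0, adj)
    return out
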