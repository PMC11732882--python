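"""Sagittal projections, segment ROIs, per-subject means and group stats.

Quantification happens on the sagittal maximum-intensity projection of the
sO2 volume: the cord silhouette is divided along the spine axis into
thoracic, lumbar and sacral regions by landmark coordinates (supplied per
subject, mirroring atlas-guided manual placement), the mean sO2 is taken
per region plus a voxel-weighted "total", and groups are compared with a
two-way ANOVA (genotype x segment) followed by Holm-Sidak-adjusted
per-segment contrasts, reporting percent reductions
100 * (mean_NTL - mean_M83) / mean_NTL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupStatsResult",
    "sagittal_mip",
    "segment_rois",
    "segment_means",
    "group_compare",
    "SEGMENTS",
]

SEGMENTS = ("thoracic", "lumbar", "sacral")


def sagittal_mip(so2: np.ndarray, mask: np.ndarray, axis: int = 0):
    """Maximum over defined voxels along the left-right axis.

    Returns (projection, defined): pixels with no defined voxel along the
    ray are NaN in the projection and False in ``defined``.
    """
    if so2.shape != mask.shape:
        raise ValueError("so2 and mask must share a shape")
    defined = mask.any(axis=axis)
    work = np.where(mask, so2, -np.inf)
    proj = work.max(axis=axis)
    proj = np.where(defined, proj, np.nan)
    if not defined.any():
        warnings.warn("fully masked volume: projection is undefined "
                      "everywhere", stacklevel=2)
    return proj, defined


def segment_rois(
    defined: np.ndarray,
    boundaries_mm,
    z_origin: float = 0.0,
    z_spacing: float = 1.0,
) -> np.ndarray:
    """Assign each defined pixel to a segment by its axial (z) coordinate.

    ``boundaries_mm`` are the ordered landmark coordinates
    [thoracic_start, lumbar_start, sacral_start, sacral_end]; intervals are
    half-open [start, end).  The z axis is the last array axis.
    """
    b = np.asarray(boundaries_mm, dtype=float)
    if b.size < 4:
        raise ValueError("need at least 4 boundaries (3 segments)")
    if np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    nz = defined.shape[-1]
    z = z_origin + (np.arange(nz) + 0.5) * z_spacing
    if b[0] < z_origin - 1e-9 or b[-1] > z_origin + nz * z_spacing + 1e-9:
        raise ValueError(
            f"boundaries [{b[0]:g}, {b[-1]:g}] mm outside projection extent "
            f"[{z_origin:g}, {z_origin + nz * z_spacing:g}] mm"
        )
    labels_z = np.zeros(nz, dtype=np.int16)
    for k in range(3):
        labels_z[(z >= b[k]) & (z < b[k + 1])] = k + 1
    rois = np.broadcast_to(labels_z, defined.shape).copy()
    rois[~defined] = 0
    return rois


def segment_means(
    projection: np.ndarray,
    rois: np.ndarray,
    subject_id: str = "subject",
    genotype: str = "NA",
) -> pd.DataFrame:
    """Per-segment mean sO2 rows plus the pixel-weighted total.

    Empty segments are reported with n = 0 and an undefined (NaN) mean.
    """
    if projection.shape != rois.shape:
        raise ValueError("projection and ROI map must be aligned")
    rows = []
    total_sum, total_n = 0.0, 0
    for k, name in enumerate(SEGMENTS, start=1):
        sel = (rois == k) & np.isfinite(projection)
        n = int(sel.sum())
        mean = float(projection[sel].mean()) if n else float("nan")
        rows.append({"subject_id": subject_id, "genotype": genotype,
                     "segment": name, "mean_so2": mean, "n_pixels": n})
        if n:
            total_sum += projection[sel].sum()
            total_n += n
    rows.append({
        "subject_id": subject_id, "genotype": genotype, "segment": "total",
        "mean_so2": total_sum / total_n if total_n else float("nan"),
        "n_pixels": total_n,
    })
    return pd.DataFrame(rows)


@dataclass
class GroupStatsResult:
    anova: pd.DataFrame        # genotype, segment, interaction effects
    contrasts: pd.DataFrame    # per-segment means, % reduction, raw/adj p

    def significant(self, alpha: float = 0.05) -> pd.Series:
        return self.contrasts.set_index("segment")["p_adj"] < alpha


def _holm_sidak(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    # keep p strictly below 1 so the Sidak log1p transform stays finite
    capped = np.minimum(np.asarray(pvals, dtype=float), 1.0 - 1e-12)
    return multipletests(capped, method="holm-sidak")[1]


def group_compare(
    table: pd.DataFrame,
    group_col: str = "genotype",
    groups: tuple[str, str] = ("NTL", "M83"),
    value_col: str = "mean_so2",
) -> GroupStatsResult:
    """Two-way ANOVA plus Holm-Sidak per-segment genotype contrasts.

    ``table`` is tidy with one row per subject x segment (segments
    thoracic/lumbar/sacral plus the derived "total").  The ANOVA uses the
    three anatomical segments; contrasts (including "total") are pooled-
    variance t tests, adjusted as one Holm-Sidak family of four.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    ref, alt = groups
    seg_rows = table[table["segment"].isin(SEGMENTS)].copy()
    for g in groups:
        n = seg_rows.loc[seg_rows[group_col] == g, "subject_id"].nunique()
        if n < 2:
            raise ValueError(f"group '{g}' has {n} subject(s); need >= 2")
    seg_rows = seg_rows.rename(columns={value_col: "value"})
    model = smf.ols(f"value ~ C({group_col}) * C(segment)", data=seg_rows).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    mse, df_resid = model.mse_resid, model.df_resid

    recs = []
    for seg in list(SEGMENTS) + ["total"]:
        sub = table[table["segment"] == seg]
        a = sub.loc[sub[group_col] == ref, value_col].to_numpy(float)
        b = sub.loc[sub[group_col] == alt, value_col].to_numpy(float)
        ma, mb = a.mean(), b.mean()
        if seg in SEGMENTS:
            se = np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
            df = df_resid
        else:
            va = a.var(ddof=1) if a.size > 1 else 0.0
            vb = b.var(ddof=1) if b.size > 1 else 0.0
            sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2)
            se = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
            df = a.size + b.size - 2
        diff = ma - mb
        t = diff / se if se > 0 else (0.0 if diff == 0 else np.inf * np.sign(diff))
        p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
        recs.append({
            "segment": seg, f"mean_{ref}": ma, f"mean_{alt}": mb,
            "percent_reduction": 100.0 * diff / ma if ma != 0 else np.nan,
            "t": t, "df": df, "p_raw": p,
        })
    contrasts = pd.DataFrame(recs)
    contrasts["p_adj"] = _holm_sidak(contrasts["p_raw"].to_numpy())
    return GroupStatsResult(anova=anova, contrasts=contrasts)
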