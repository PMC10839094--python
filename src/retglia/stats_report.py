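"""Statistical comparisons and per-zone summary tables.

The study design compares pre- vs post-stimulation swelling within
zones (paired t-test), lesion size across the four charge-density
groups (Kruskal-Wallis with tie correction), and the microglia
alignment time course against the 0 h baseline.  ``zone_report``
assembles the per-charge-density summary tables from a merged zone
table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def paired_t(pre, post) -> tuple[float, float, int]:
    """Two-sided paired (dependent-samples) t-test.

    Returns ``(t, p, n)``.  Identical samples give ``t = 0, p = 1``;
    constant non-zero differences have zero variance, so the statistic
    diverges and the p-value is the minimal attainable value (0) under
    the t reference distribution.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = len(pre)
    if n < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = post - pre
    if np.all(d == d[0]):  # zero-variance differences
        if d[0] == 0:
            return 0.0, 1.0, n
        return float(np.sign(d[0]) * np.inf), 0.0, n
    t, p = stats.ttest_rel(post, pre)
    return float(t), float(p), n


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test across groups, with tie correction.

    Returns ``(H, p)`` with the chi-square reference p-value.  All
    observations identical across groups carry no rank information:
    ``H = 0, p = 1``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


#: Column pairs reported pre/post per zone, in the order they appear in
#: the summary table.
_PAIRED_METRICS = (
    ("ilm_ipl_pre_um", "ilm_ipl_post_um", "ilm_ipl"),
    ("ipl_thickness_pre_um", "ipl_thickness_post_um", "ipl_thickness"),
)


def zone_report(table: pd.DataFrame, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Summaries per charge density from a merged zone table.

    The zone table has one row per stimulation zone (``zone_id``), with
    ``charge_density_uC_cm2`` and any of: pre/post ILM-IPL distances
    and IPL thicknesses (um), ``lesion_area_um2``,
    ``lesion_diameter_um``, ``alignment_index``, ``timepoint_h``.
    Returns the swelling table (with paired t-tests per charge
    density), the lesion table (with a Kruskal-Wallis test across
    charge densities), and the cluster-plot coordinates.  The report
    is a pure, order-invariant function of the table.
    """
    if table.empty:
        raise ValueError("zone table is empty")
    if "zone_id" in table.columns and table["zone_id"].duplicated().any():
        raise ValueError("zone table must have one row per zone")
    df = table.sort_values("charge_density_uC_cm2", kind="mergesort").reset_index(drop=True)
    out: dict[str, pd.DataFrame] = {}

    swelling_rows = []
    for cd, grp in df.groupby("charge_density_uC_cm2"):
        row = {"charge_density_uC_cm2": cd, "n": len(grp)}
        for pre_col, post_col, label in _PAIRED_METRICS:
            if pre_col not in grp.columns or post_col not in grp.columns:
                continue
            row[f"{label}_pre_mean"] = grp[pre_col].mean()
            row[f"{label}_pre_sd"] = grp[pre_col].std(ddof=1)
            row[f"{label}_post_mean"] = grp[post_col].mean()
            row[f"{label}_post_sd"] = grp[post_col].std(ddof=1)
            if len(grp) >= 2:
                t, p, _ = paired_t(grp[pre_col].to_numpy(), grp[post_col].to_numpy())
                row[f"{label}_t"] = t
                row[f"{label}_p"] = p
                row[f"{label}_significant"] = bool(p < alpha)
            else:
                row[f"{label}_t"] = np.nan
                row[f"{label}_p"] = np.nan
                row[f"{label}_significant"] = False
        swelling_rows.append(row)
    if swelling_rows:
        out["swelling"] = pd.DataFrame(swelling_rows)

    if "lesion_area_um2" in df.columns:
        lesion = (
            df.groupby("charge_density_uC_cm2")
            .agg(
                n=("zone_id", "size"),
                area_mean=("lesion_area_um2", "mean"),
                area_sd=("lesion_area_um2", "std"),
                diameter_mean=("lesion_diameter_um", "mean"),
                diameter_sd=("lesion_diameter_um", "std"),
            )
            .reset_index()
        )
        groups = [g["lesion_area_um2"].to_numpy() for _, g in df.groupby("charge_density_uC_cm2")]
        if len(groups) >= 2 and all(len(g) for g in groups):
            h, p = kruskal_wallis(groups)
            lesion.attrs["kruskal_H"] = h
            lesion.attrs["kruskal_p"] = p
            lesion.attrs["kruskal_significant"] = bool(p < alpha)
        out["lesion"] = lesion

    if {"lesion_area_um2"}.issubset(df.columns) and any(
        c in df.columns for c in ("ilm_ipl_pre_um",)
    ):
        clusters = df.assign(
            distension_ratio=df["ilm_ipl_post_um"] / df["ilm_ipl_pre_um"]
        ).groupby("charge_density_uC_cm2").agg(
            area_mean=("lesion_area_um2", "mean"),
            area_sd=("lesion_area_um2", "std"),
            ratio_mean=("distension_ratio", "mean"),
            ratio_sd=("distension_ratio", "std"),
        ).reset_index()
        out["clusters"] = clusters

    if "alignment_index" in df.columns and "timepoint_h" in df.columns:
        out["timecourse"] = (
            df.groupby("timepoint_h")
            .agg(n=("alignment_index", "size"),
                 index_mean=("alignment_index", "mean"),
                 index_sd=("alignment_index", "std"))
            .reset_index()
        )
    return out
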