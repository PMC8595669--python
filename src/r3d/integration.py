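"""ChIP/Input domain marking, group statistics, and expression overlays."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def bin_signal(track: pd.DataFrame, resolution: int, n_bins: int) -> np.ndarray:
    """Length-weighted mean ratio per genomic bin.

    ``track`` has sorted, non-overlapping columns chrom, start, end, ratio
    (a bedGraph). Bins with no covered base are NaN; partially covered bins
    average over the covered bases only.
    """
    for col in ("start", "end", "ratio"):
        if col not in track.columns:
            raise ValueError(f"track missing column {col!r}")
    starts = track["start"].to_numpy()
    ends = track["end"].to_numpy()
    ratios = track["ratio"].to_numpy(dtype=float)
    if (np.diff(starts) < 0).any():
        raise ValueError("track intervals are not sorted")
    if (starts[1:] < ends[:-1]).any():
        raise ValueError("track intervals overlap")
    if (ratios < 0).any():
        raise ValueError("ratio values must be >= 0")

    weight = np.zeros(n_bins)
    total = np.zeros(n_bins)
    for s, e, r in zip(starts, ends, ratios):
        b0 = max(0, s // resolution)
        b1 = min(n_bins - 1, (e - 1) // resolution)
        for b in range(b0, b1 + 1):
            ov = min(e, (b + 1) * resolution) - max(s, b * resolution)
            if ov > 0:
                weight[b] += ov
                total[b] += ov * r
    with np.errstate(invalid="ignore"):
        out = np.where(weight > 0, total / np.maximum(weight, 1), np.nan)
    return out


def mark_regions(
    regions: pd.DataFrame,
    binned: np.ndarray,
    resolution: int,
    ratio_min: float = 2.0,
    frac_min: float = 0.5,
) -> pd.DataFrame:
    """Flag regions whose ChIP/Input signal clears the marking rule.

    A region is marked when at least ``frac_min`` of its defined bins carry
    a ratio >= ``ratio_min``. ``regions`` needs columns start, end (bp) and
    optionally ``group``. Regions with no defined bin are excluded with a
    warning. Adds mean_ratio, frac_high, marked columns.
    """
    rows = []
    dropped = 0
    for idx, reg in regions.iterrows():
        b0 = int(reg["start"]) // resolution
        b1 = max(b0 + 1, -(-int(reg["end"]) // resolution))
        vals = binned[b0 : min(b1, len(binned))]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            dropped += 1
            continue
        frac_high = float((vals >= ratio_min).mean())
        rows.append(
            {**reg.to_dict(), "mean_ratio": float(vals.mean()),
             "frac_high": frac_high, "marked": frac_high >= frac_min}
        )
    if dropped:
        warnings.warn(f"{dropped} regions excluded: no defined bins", stacklevel=2)
    return pd.DataFrame(rows)


def marked_fraction_by_group(report: pd.DataFrame, group_col: str = "group") -> pd.Series:
    """Fraction of marked regions per group."""
    return report.groupby(group_col)["marked"].mean()


STAR_BANDS = (
    (0.0005, "***"),
    (0.005, "**"),
    (0.05, "*"),
)


def significance_stars(p: float) -> str:
    """Star annotation: *** p <= 0.0005, ** to 0.005, * to 0.05, else ns."""
    for cutoff, stars in STAR_BANDS:
        if p <= cutoff:
            return stars
    return "ns"


def group_intensity_compare(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between groups.

    Uses the exact null distribution for small, tie-free samples and the
    normal approximation otherwise (Mann-Whitney U is the identical
    statistic). Pairs where either group has < 3 values get NA.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(values_by_group[names[i]], dtype=float)
            b = np.asarray(values_by_group[names[j]], dtype=float)
            if len(a) < 3 or len(b) < 3:
                rows.append({"group1": names[i], "group2": names[j],
                             "p_value": np.nan, "stars": "NA"})
                continue
            no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
            method = "exact" if no_ties and max(len(a), len(b)) <= 25 else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            rows.append({"group1": names[i], "group2": names[j],
                         "p_value": float(res.pvalue),
                         "stars": significance_stars(float(res.pvalue))})
    return pd.DataFrame(rows)


def expression_by_structure(
    expr: pd.DataFrame,
    regions: pd.DataFrame,
    condition_cols: dict[str, list[str]],
) -> pd.DataFrame:
    """Assign genes to labeled regions by TSS and summarize expression.

    ``expr`` needs columns gene, chrom, tss plus per-sample FPKM columns;
    ``regions`` needs chrom, start, end, group. Membership uses the
    half-open convention (tss == end is outside). Returns a long table
    gene / group / condition / fpkm where fpkm is the mean over that
    condition's samples; empty groups are reported with a single flagged
    row (gene NA).
    """
    rows = []
    seen_groups = set()
    for _, g in expr.iterrows():
        hits = regions[
            (regions["chrom"] == g["chrom"])
            & (regions["start"] <= g["tss"])
            & (g["tss"] < regions["end"])
        ]
        if hits.empty:
            continue
        group = hits.iloc[0]["group"]
        seen_groups.add(group)
        for cond, cols in condition_cols.items():
            rows.append({"gene": g["gene"], "group": group, "condition": cond,
                         "fpkm": float(np.mean([g[c] for c in cols]))})
    for group in regions["group"].unique():
        if group not in seen_groups:
            warnings.warn(f"no genes in group {group!r}", stacklevel=2)
            rows.append({"gene": None, "group": group, "condition": None,
                         "fpkm": np.nan})
    return pd.DataFrame(rows, columns=["gene", "group", "condition", "fpkm"])


def degs_in_abnormal(
    deg_list: pd.DataFrame,
    abnormal: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Intersect an externally computed DEG list with abnormal structures.

    ``deg_list`` needs gene, chrom, tss (rows with missing TSS are skipped
    with a warning); ``abnormal`` maps layer name (e.g. "compartment",
    "tad", "loop") to interval tables with chrom, start, end. Returns one
    row per (layer, gene) hit.
    """
    rows = []
    skipped = 0
    for _, g in deg_list.iterrows():
        if pd.isna(g.get("tss")) or pd.isna(g.get("chrom")):
            skipped += 1
            continue
        for layer, regions in abnormal.items():
            hit = regions[
                (regions["chrom"] == g["chrom"])
                & (regions["start"] <= g["tss"])
                & (g["tss"] < regions["end"])
            ]
            if not hit.empty:
                rows.append({"layer": layer, "gene": g["gene"],
                             "chrom": g["chrom"], "tss": int(g["tss"])})
    if skipped:
        warnings.warn(f"{skipped} DEGs skipped: missing TSS", stacklevel=2)
    return pd.DataFrame(rows, columns=["layer", "gene", "chrom", "tss"])
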