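"""ATAC peak-intensity normalization, K-means clustering, and annotation.

Peaks are partitioned into accessibility clusters C1 (open in all), C2
(donor-specific) and C3 (ESC-specific) by K-means on per-peak z-scores; the
C4/C5 subsets are the C3 peaks differentially accessible between the two
ESC derivation routes. Peaks are annotated by genomic context with
precedence promoter > exon > intron > intergenic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

DEFAULT_SAMPLE_GROUPS = {
    "cc": ["CC"],
    "nt": ["NT5", "NT6"],
    "f": ["F35", "F40"],
}


@dataclass
class PeakMatrix:
    """Peak intervals with a peak-by-sample intensity table.

    ``intensity`` holds raw values until :func:`normalize_peak_matrix` sets
    ``normalized``; the z-score view used for clustering lives in
    ``zscores``. ``cluster`` is NA until clustering has run.
    """

    peaks: pd.DataFrame  # chrom, start, end
    intensity: pd.DataFrame  # peaks x samples
    normalized: bool = False
    zscores: pd.DataFrame | None = None
    cluster: pd.Series | None = None
    scale_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.peaks) != len(self.intensity):
            raise ValueError("peak count and intensity rows differ")

    @property
    def samples(self) -> list[str]:
        return list(self.intensity.columns)


def normalize_peak_matrix(raw: PeakMatrix) -> PeakMatrix:
    """Depth-normalize to counts-per-million within peaks, then log2(x+1).

    Stores per-sample scale factors so the transform is invertible, plus a
    per-peak z-score view for clustering (constant rows z-score to 0).
    """
    x = raw.intensity.astype(float)
    depths = x.sum(axis=0)
    if (depths == 0).any():
        bad = list(depths.index[depths == 0])
        raise ValueError(f"all-zero sample column(s): {bad}")
    factors = depths / 1e6
    cpm = x / factors
    logv = np.log2(cpm + 1.0)
    mu = logv.mean(axis=1)
    centered = logv.sub(mu, axis=0)
    # standardize against the pooled std, not per row: per-row scaling blows
    # flat (open-in-all) peaks up to unit-norm noise vectors and makes their
    # cluster assignment arbitrary; the pooled scale keeps them near the
    # origin where K-means can isolate them
    pooled = float(np.sqrt((centered.to_numpy() ** 2).mean()))
    z = centered / pooled if pooled > 0 else centered
    return PeakMatrix(
        peaks=raw.peaks.copy(),
        intensity=logv,
        normalized=True,
        zscores=z,
        scale_factors=factors,
        cluster=raw.cluster,
    )


def denormalize(pm: PeakMatrix) -> pd.DataFrame:
    """Invert normalization using the stored factors (round-trip check)."""
    if not pm.normalized or pm.scale_factors is None:
        raise ValueError("matrix is not normalized")
    cpm = np.exp2(pm.intensity) - 1.0
    return cpm * pm.scale_factors


def kmeans_clusters(
    pm: PeakMatrix,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
    sample_groups: dict[str, list[str]] | None = None,
) -> PeakMatrix:
    """K-means on the z-score view, relabelled semantically as C1-C3.

    C1 is the cluster whose weakest per-sample mean (on normalized log
    intensities) is highest — open in every cell type. Of the rest, C2 is
    the cluster with the largest donor-minus-ESC mean difference
    (donor-specific), and C3 the remaining (ESC-specific) cluster. The
    relabelling keys on sample-group means, never on K-means indices, so a
    different seed cannot swap names.
    """
    groups = sample_groups or DEFAULT_SAMPLE_GROUPS
    if not pm.normalized or pm.zscores is None:
        raise ValueError("normalize the matrix before clustering")
    n = len(pm.zscores)
    if k > n:
        raise ValueError(f"k={k} exceeds peak count {n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(pm.zscores.to_numpy())
    if len(np.unique(raw_labels)) < k:
        warnings.warn("degenerate clustering: fewer than k distinct clusters",
                      stacklevel=2)

    cc_cols = groups["cc"]
    esc_cols = groups["nt"] + groups["f"]
    stats_rows = {}
    for lab in np.unique(raw_labels):
        sub = pm.intensity[raw_labels == lab]
        per_sample = sub.mean(axis=0)
        stats_rows[lab] = {
            "min_mean": per_sample.min(),
            "cc_minus_esc": per_sample[cc_cols].mean() - per_sample[esc_cols].mean(),
        }
    order = sorted(stats_rows)
    c1 = max(order, key=lambda l: stats_rows[l]["min_mean"])
    rest = [l for l in order if l != c1]
    c2 = max(rest, key=lambda l: stats_rows[l]["cc_minus_esc"]) if rest else None
    mapping = {c1: "C1"}
    if c2 is not None:
        mapping[c2] = "C2"
    for l in order:
        mapping.setdefault(l, "C3")
    out = PeakMatrix(
        peaks=pm.peaks.copy(), intensity=pm.intensity, normalized=True,
        zscores=pm.zscores, scale_factors=pm.scale_factors,
    )
    out.cluster = pd.Series([mapping[l] for l in raw_labels], index=pm.intensity.index)
    return out


def differential_esc_peaks(
    pm: PeakMatrix,
    fc: float = 2.0,
    alpha: float = 0.05,
    sample_groups: dict[str, list[str]] | None = None,
) -> PeakMatrix:
    """Split C3 into C4/C5 by fESC-vs-ntESC differential accessibility.

    Per C3 peak: Welch t-test on normalized log2 intensities between the
    fESC and ntESC sample pairs; C4 when the fESC-minus-ntESC mean log2
    fold change is >= log2(fc) with p < alpha, C5 for the reverse trend.
    C1/C2 assignments are never touched.
    """
    groups = sample_groups or DEFAULT_SAMPLE_GROUPS
    nt_cols, f_cols = groups["nt"], groups["f"]
    if len(nt_cols) < 2 or len(f_cols) < 2:
        raise ValueError("need >= 2 samples per ESC group")
    if pm.cluster is None:
        raise ValueError("run kmeans_clusters first")
    out = PeakMatrix(
        peaks=pm.peaks.copy(), intensity=pm.intensity, normalized=pm.normalized,
        zscores=pm.zscores, scale_factors=pm.scale_factors,
        cluster=pm.cluster.copy(),
    )
    c3_idx = out.cluster.index[out.cluster == "C3"]
    if len(c3_idx) == 0:
        return out
    f_vals = pm.intensity.loc[c3_idx, f_cols].to_numpy()
    nt_vals = pm.intensity.loc[c3_idx, nt_cols].to_numpy()
    lfc = f_vals.mean(axis=1) - nt_vals.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(f_vals, nt_vals, axis=1, equal_var=False)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    thresh = np.log2(fc)
    c4 = (lfc >= thresh) & (pvals < alpha)
    c5 = (lfc <= -thresh) & (pvals < alpha)
    out.cluster.loc[c3_idx[c4]] = "C4"
    out.cluster.loc[c3_idx[c5]] = "C5"
    return out


# ---------------------------------------------------------------------------
# genomic-context annotation

CATEGORIES = ("promoter", "exon", "intron", "intergenic")


def annotate_peaks(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    exons: pd.DataFrame,
    promoter_flank: int = 1000,
) -> pd.Series:
    """Single genomic-context category per peak, by peak center.

    ``genes`` needs columns chrom, start, end, strand (TSS = start on '+',
    end - 1 on '-'); ``exons`` needs chrom, start, end. The promoter window
    is [TSS - flank, TSS + flank) in 0-based half-open coordinates.
    Precedence: promoter > exon > intron > intergenic.
    """
    for df, cols in ((genes, ("chrom", "start", "end", "strand")),
                     (exons, ("chrom", "start", "end"))):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"malformed annotation: missing columns {missing}")
    if "summit" in peaks.columns:
        centers = peaks["summit"].to_numpy()
    else:
        centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    chroms = peaks["chrom"].to_numpy()

    tss = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])
    prom = pd.DataFrame(
        {"chrom": genes["chrom"],
         "start": tss - promoter_flank,
         "end": tss + promoter_flank}
    )

    def _in_any(intervals: pd.DataFrame, chrom: str, pos: int) -> bool:
        sub = intervals[intervals["chrom"] == chrom]
        return bool(((sub["start"] <= pos) & (pos < sub["end"])).any())

    out = []
    for chrom, c in zip(chroms, centers):
        if _in_any(prom, chrom, c):
            out.append("promoter")
        elif _in_any(exons, chrom, c):
            out.append("exon")
        elif _in_any(genes, chrom, c):
            out.append("intron")
        else:
            out.append("intergenic")
    return pd.Series(out, index=peaks.index, name="category")


def annotation_summary(
    categories: pd.Series, clusters: pd.Series | None = None
) -> pd.DataFrame:
    """Counts per category (optionally per cluster)."""
    if clusters is None:
        return categories.value_counts().reindex(CATEGORIES, fill_value=0).to_frame("count")
    df = pd.DataFrame({"category": categories, "cluster": clusters})
    return (
        df.groupby(["cluster", "category"]).size().unstack(fill_value=0)
        .reindex(columns=CATEGORIES, fill_value=0)
    )
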