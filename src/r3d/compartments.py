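"""A/B compartment calling and reprogramming-dynamics classification.

PC1 of the O/E correlation matrix defines compartments (A: pc1 > 0,
B: pc1 < 0 after orientation against an activity track). Donor-vs-ESC
switches are classified into Repro / Partial / Hyper / Resis dynamics, and
the NT and iPSC reprogramming processes are compared bin by bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from r3d.contact import ContactMatrix

CLASSES = ("Repro", "Partial", "Hyper", "Resis")


@dataclass
class CompartmentTrack:
    """Per-bin PC1 values and A/B states for one condition.

    ``pc1`` is NaN at masked bins; ``state`` is "A" where pc1 > 0, "B"
    where pc1 < 0, "NA" otherwise.
    """

    chrom: str
    resolution: int
    pc1: np.ndarray
    orientation_reference: str = "activity"

    def __post_init__(self) -> None:
        self.pc1 = np.asarray(self.pc1, dtype=float)

    @property
    def state(self) -> np.ndarray:
        out = np.full(len(self.pc1), "NA", dtype=object)
        out[self.pc1 > 0] = "A"
        out[self.pc1 < 0] = "B"
        return out

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(len(self.pc1)) * self.resolution
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": starts,
                "end": starts + self.resolution,
                "pc1": self.pc1,
                "state": self.state,
            }
        )


def pearson_oe_matrix(oe: ContactMatrix, min_bins: int = 10) -> np.ndarray:
    """Pearson correlation of O/E rows over unmasked columns.

    Returns an n_bins x n_bins matrix with NaN rows/columns at masked bins
    and unit diagonal on the unmasked block.
    """
    keep = oe.unmasked
    if keep.sum() < min_bins:
        raise ValueError(f"fewer than {min_bins} unmasked bins")
    sub = oe.counts[np.ix_(keep, keep)]
    with np.errstate(invalid="ignore"):
        corr_sub = np.corrcoef(sub)
    n = oe.n_bins
    corr = np.full((n, n), np.nan)
    corr[np.ix_(keep, keep)] = corr_sub
    return corr


def compute_pc1(corr: np.ndarray, n_components: int = 1) -> np.ndarray:
    """Leading principal-component scores of the correlation matrix.

    Columns of the unmasked submatrix are centered; the unit-norm leading
    left singular vector gives per-bin PC1 scores. Masked (all-NaN) rows
    come back as NaN. With ``n_components > 1`` returns a (n, k) array.
    """
    corr = np.asarray(corr, dtype=float)
    keep = ~np.all(np.isnan(corr), axis=1)
    sub = corr[np.ix_(keep, keep)]
    if np.isnan(sub).any():
        raise ValueError("correlation matrix has NaNs inside the unmasked block")
    centered = sub - sub.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("no principal axis: degenerate correlation matrix")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = n_components
    comps = u[:, :k] * np.sign(np.where(s[:k] > 0, 1.0, 1.0))
    out = np.full((corr.shape[0], k), np.nan)
    out[keep] = comps
    return out[:, 0] if k == 1 else out


def orient_and_call(
    pc1: np.ndarray,
    activity: np.ndarray,
    chrom: str = "chrS",
    resolution: int = 200_000,
    reference_name: str = "activity",
) -> CompartmentTrack:
    """Fix the PC1 sign against an activity reference and call A/B states.

    The global sign is flipped when the Pearson correlation between pc1 and
    the activity track (gene density or ATAC coverage per bin) is negative,
    so that A-compartment bins carry positive values.
    """
    pc1 = np.asarray(pc1, dtype=float)
    activity = np.asarray(activity, dtype=float)
    if pc1.shape != activity.shape:
        raise ValueError("pc1 and activity must have equal length")
    ok = np.isfinite(pc1) & np.isfinite(activity)
    if ok.sum() < 3 or np.std(activity[ok]) == 0:
        raise ValueError("orientation undefined: zero-variance activity track")
    r = np.corrcoef(pc1[ok], activity[ok])[0, 1]
    oriented = -pc1 if r < 0 else pc1.copy()
    return CompartmentTrack(
        chrom=chrom, resolution=resolution, pc1=oriented,
        orientation_reference=reference_name,
    )


def call_compartments(
    oe: ContactMatrix,
    activity: np.ndarray,
    min_abs_corr: float = 0.2,
) -> CompartmentTrack:
    """O/E matrix -> oriented compartment track.

    Falls back to PC2 when PC1 tracks the activity reference poorly
    (|r| < ``min_abs_corr``) and PC2 tracks it better — the usual guard
    against PC1 capturing chromosome arms instead of the plaid.
    """
    corr = pearson_oe_matrix(oe)
    comps = compute_pc1(corr, n_components=2)
    pc1, pc2 = comps[:, 0], comps[:, 1]
    ok = np.isfinite(pc1) & np.isfinite(activity)
    r1 = abs(np.corrcoef(pc1[ok], activity[ok])[0, 1])
    r2 = abs(np.corrcoef(pc2[ok], activity[ok])[0, 1])
    chosen = pc1
    if r1 < min_abs_corr and r2 > r1:
        warnings.warn("PC1 poorly tracks activity; substituting PC2", stacklevel=2)
        chosen = pc2
    return orient_and_call(chosen, activity, chrom=oe.chrom, resolution=oe.resolution)


def compartment_strength(
    oe: ContactMatrix, track: CompartmentTrack, n_quantiles: int = 5
) -> float:
    """Saddle-style compartmentalization strength.

    Bins are ranked by PC1 into ``n_quantiles``; strength is the mean O/E
    over (top x top) and (bottom x bottom) pixel pairs divided by the mean
    over (top x bottom) pairs. Structureless maps give 1.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    if len(track.pc1) != oe.n_bins:
        raise ValueError("track and matrix binning differ")
    keep = oe.unmasked & np.isfinite(track.pc1)
    idx = np.where(keep)[0]
    order = idx[np.argsort(track.pc1[idx])]
    q = len(order) // n_quantiles
    if q == 0:
        raise ValueError("too few bins for the requested quantiles")
    bottom, top = order[:q], order[-q:]
    within = np.concatenate(
        [
            oe.counts[np.ix_(top, top)][np.triu_indices(q, k=1)],
            oe.counts[np.ix_(bottom, bottom)][np.triu_indices(q, k=1)],
        ]
    )
    between = oe.counts[np.ix_(top, bottom)].ravel()
    within = within[within > 0]
    between = between[between > 0]
    if within.size == 0 or between.size == 0:
        raise ValueError("no informative pixels for strength")
    return float(within.mean() / between.mean())


# ---------------------------------------------------------------------------
# switches and dynamics


def _condition_mean(tracks: list[CompartmentTrack]) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins -> NaN
        return np.nanmean(np.vstack([t.pc1 for t in tracks]), axis=0)


def _consensus_state(tracks: list[CompartmentTrack]) -> np.ndarray:
    """State where all lines agree in sign, else 'NA'."""
    signs = np.vstack([np.sign(t.pc1) for t in tracks])
    out = np.full(signs.shape[1], "NA", dtype=object)
    out[(signs > 0).all(axis=0)] = "A"
    out[(signs < 0).all(axis=0)] = "B"
    return out


def call_switches(
    cc: CompartmentTrack,
    nt_lines: list[CompartmentTrack],
    f_lines: list[CompartmentTrack],
) -> pd.DataFrame:
    """Per-bin donor-vs-ESC compartment transitions.

    Donor state from the CC track; ESC state from the fESC lines where both
    agree in sign (else the bin is NA and excluded). Returns a bin-level
    table with columns chrom, start, end, bin, cc_pc1, nt_pc1, f_pc1,
    donor_state, esc_state, transition in {A-to-B, B-to-A, stable, NA}.
    """
    n = len(cc.pc1)
    for t in nt_lines + f_lines:
        if len(t.pc1) != n:
            raise ValueError("tracks must share binning")
    nt_pc1 = _condition_mean(nt_lines)
    f_pc1 = _condition_mean(f_lines)
    donor = cc.state
    esc = _consensus_state(f_lines)

    transition = np.full(n, "NA", dtype=object)
    classifiable = (donor != "NA") & (esc != "NA")
    stable = classifiable & (donor == esc)
    a2b = classifiable & (donor == "A") & (esc == "B")
    b2a = classifiable & (donor == "B") & (esc == "A")
    transition[stable] = "stable"
    transition[a2b] = "A-to-B"
    transition[b2a] = "B-to-A"

    starts = np.arange(n) * cc.resolution
    return pd.DataFrame(
        {
            "chrom": cc.chrom,
            "start": starts,
            "end": starts + cc.resolution,
            "bin": np.arange(n),
            "cc_pc1": cc.pc1,
            "nt_pc1": nt_pc1,
            "f_pc1": f_pc1,
            "donor_state": donor,
            "esc_state": esc,
            "transition": transition,
        }
    )


def switch_summary(switches: pd.DataFrame) -> dict[str, float]:
    """Percentages of each transition over classifiable bins."""
    classifiable = switches[switches["transition"] != "NA"]
    n = len(classifiable)
    if n == 0:
        raise ValueError("no classifiable bins")
    out = {}
    for t in ("A-to-B", "B-to-A", "stable"):
        out[t] = 100.0 * (classifiable["transition"] == t).sum() / n
    out["n_classifiable"] = n
    return out


def merge_switch_regions(switches: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent bins with the same non-stable transition into regions.

    Region-level PC1 values are means over the member bins.
    """
    sw = switches[switches["transition"].isin(["A-to-B", "B-to-A"])].copy()
    if sw.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "transition", "cc_pc1", "nt_pc1", "f_pc1"]
        )
    sw = sw.sort_values("bin")
    breaks = (sw["bin"].diff() != 1) | (sw["transition"] != sw["transition"].shift())
    sw["region_id"] = breaks.cumsum()
    agg = sw.groupby("region_id").agg(
        chrom=("chrom", "first"),
        start=("start", "min"),
        end=("end", "max"),
        transition=("transition", "first"),
        cc_pc1=("cc_pc1", "mean"),
        nt_pc1=("nt_pc1", "mean"),
        f_pc1=("f_pc1", "mean"),
        n_bins=("bin", "size"),
    )
    return agg.reset_index(drop=True)


def classify_record(
    cc_pc1: float, nt_pc1: float, f_pc1: float, delta: float = 0.15
) -> str | None:
    """Four-class reprogramming dynamics for one switched region.

    With the trajectory coordinate r = (nt - cc) / (f - cc):

    * ``Resis``   — r <= delta, or the ntESC value keeps the donor sign
    * ``Partial`` — delta < r <= 1 - delta (ntESC intermediate, ESC sign)
    * ``Repro``   — 1 - delta < r <= 1 + delta (ntESC at the fESC state)
    * ``Hyper``   — r > 1 + delta (ntESC beyond the fESC state)

    Returns None (record skipped) when f == cc so r is undefined.
    """
    if not 0 < delta < 0.5:
        raise ValueError("delta must be in (0, 0.5)")
    denom = f_pc1 - cc_pc1
    if denom == 0:
        return None
    r = (nt_pc1 - cc_pc1) / denom
    if r <= delta or np.sign(nt_pc1) == np.sign(cc_pc1):
        return "Resis"
    if r <= 1 - delta:
        return "Partial"
    if r <= 1 + delta:
        return "Repro"
    return "Hyper"


def classify_dynamics(records: pd.DataFrame, delta: float = 0.15) -> pd.DataFrame:
    """Classify switched records into Repro/Partial/Hyper/Resis.

    ``records`` needs columns cc_pc1, nt_pc1, f_pc1 (bin- or region-level,
    restricted to switched entries). Records with f == cc are dropped with
    a warning. Adds a ``class`` column.
    """
    out = records.copy()
    labels = []
    skipped = 0
    for cc_v, nt_v, f_v in zip(out["cc_pc1"], out["nt_pc1"], out["f_pc1"]):
        lab = classify_record(cc_v, nt_v, f_v, delta=delta)
        if lab is None:
            skipped += 1
        labels.append(lab)
    if skipped:
        warnings.warn(
            f"{skipped} records skipped: undefined trajectory (f_pc1 == cc_pc1)",
            stacklevel=2,
        )
    out["class"] = labels
    return out[out["class"].notna()].reset_index(drop=True)


def dynamics_counts(classified: pd.DataFrame) -> dict[str, int]:
    return {c: int((classified["class"] == c).sum()) for c in CLASSES}


# ---------------------------------------------------------------------------
# NT vs iPSC process comparison


def compare_processes(
    cc: CompartmentTrack,
    mef: CompartmentTrack,
    nt: CompartmentTrack,
    ipsc: CompartmentTrack,
    esc: CompartmentTrack,
) -> pd.DataFrame:
    """Per-bin switch taxonomy for the NT and iPSC reprogramming processes.

    ``esc`` is the consensus track (bins where the fESC lines and E14 agree;
    NA elsewhere). A bin switches in the NT process when CC differs from the
    ESC consensus and the ntESC reaches the ESC state; likewise for the iPSC
    process from MEF. Categories: common / NT-specific / iPSC-specific.
    Non-common switches are donor-specific when CC and MEF states differ,
    method-specific when they agree but ntESC and iPSC end up different.
    """
    tracks = {"cc": cc, "mef": mef, "nt": nt, "ipsc": ipsc, "esc": esc}
    n = len(cc.pc1)
    for name, t in tracks.items():
        if t is None:
            raise ValueError(f"missing condition: {name}")
        if len(t.pc1) != n:
            raise ValueError("tracks must share binning")
    states = {k: t.state for k, t in tracks.items()}
    rows = []
    for i in range(n):
        st = {k: states[k][i] for k in states}
        if any(v == "NA" for v in st.values()):
            continue
        nt_switch = st["cc"] != st["esc"] and st["nt"] == st["esc"]
        ipsc_switch = st["mef"] != st["esc"] and st["ipsc"] == st["esc"]
        if not (nt_switch or ipsc_switch):
            continue
        if nt_switch and ipsc_switch:
            category, specificity = "common", "NA"
        else:
            category = "NT-specific" if nt_switch else "iPSC-specific"
            if st["cc"] != st["mef"]:
                specificity = "donor-specific"
            elif st["nt"] != st["ipsc"]:
                specificity = "method-specific"
            else:
                specificity = "NA"
        donor_state = st["cc"] if nt_switch else st["mef"]
        rows.append(
            {
                "chrom": cc.chrom,
                "start": i * cc.resolution,
                "end": (i + 1) * cc.resolution,
                "bin": i,
                "cc_state": st["cc"],
                "mef_state": st["mef"],
                "nt_state": st["nt"],
                "ipsc_state": st["ipsc"],
                "esc_state": st["esc"],
                "transition": f"{donor_state}-to-{st['esc']}",
                "category": category,
                "specificity": specificity,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "bin", "cc_state", "mef_state", "nt_state",
            "ipsc_state", "esc_state", "transition", "category", "specificity",
        ],
    )


def process_summary(comparison: pd.DataFrame) -> dict[str, float]:
    """Per-category percentages over bins switching in at least one process."""
    n = len(comparison)
    if n == 0:
        return {"common": 0.0, "NT-specific": 0.0, "iPSC-specific": 0.0, "n": 0}
    out: dict[str, float] = {"n": n}
    for cat in ("common", "NT-specific", "iPSC-specific"):
        out[cat] = 100.0 * (comparison["category"] == cat).sum() / n
    return out
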