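"""Insulation scores, TAD boundaries, relative TAD intensity, and dynamics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from r3d.contact import ContactMatrix


@dataclass
class InsulationTrack:
    """Per-bin sliding-diamond insulation scores.

    ``score[i] = log2(diamond mean at i / chromosome mean of diamond
    means)``; NaN within ``window`` of chromosome ends and at bins whose
    diamond is fully masked.
    """

    chrom: str
    resolution: int
    window: int
    score: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(len(self.score)) * self.resolution
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": starts,
                "end": starts + self.resolution,
                "score": self.score,
            }
        )


@dataclass
class Boundary:
    position: int  # bin index
    strength: float  # contrast vs nearest flanking local maxima
    insulation_minimum: float


@dataclass
class Tad:
    chrom: str
    start: int  # bp
    end: int  # bp
    start_bin: int
    end_bin: int  # exclusive


def insulation_track(m: ContactMatrix, window: int = 480_000) -> InsulationTrack:
    """Sliding-diamond insulation score.

    For each bin i the diamond is the w x w block of contacts between the w
    upstream and w downstream bins (w = window / resolution); pairs touching
    masked bins are excluded from the mean. Scores are log2 ratios to the
    chromosome-wide mean diamond value, so they average ~0 and are invariant
    to global scaling of the matrix.
    """
    if window % m.resolution != 0:
        raise ValueError("window must be a multiple of the resolution")
    w = window // m.resolution
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    n = m.n_bins
    keep = m.unmasked
    diamond = np.full(n, np.nan)
    for i in range(w, n - w):
        rows = np.arange(i - w, i)
        cols = np.arange(i + 1, i + w + 1)
        ok_r = keep[rows]
        ok_c = keep[cols]
        if not (ok_r.any() and ok_c.any()) or not keep[i]:
            continue
        block = m.counts[np.ix_(rows[ok_r], cols[ok_c])]
        diamond[i] = block.mean()
    defined = np.isfinite(diamond)
    if not defined.any():
        raise ValueError("no bins with a defined diamond")
    mean_d = diamond[defined].mean()
    score = np.full(n, np.nan)
    positive = defined & (diamond > 0)
    score[positive] = np.log2(diamond[positive] / mean_d)
    return InsulationTrack(chrom=m.chrom, resolution=m.resolution, window=window, score=score)


def _local_extrema(score: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices of local minima and maxima over the defined stretch."""
    minima, maxima = [], []
    n = len(score)
    for i in range(1, n - 1):
        if not np.isfinite(score[i - 1 : i + 2]).all():
            continue
        if score[i] < score[i - 1] and score[i] <= score[i + 1]:
            minima.append(i)
        if score[i] > score[i - 1] and score[i] >= score[i + 1]:
            maxima.append(i)
    return minima, maxima


def call_boundaries(t: InsulationTrack, min_delta: float = 0.1) -> list[Boundary]:
    """Boundaries = local insulation minima with sufficient contrast.

    Contrast is the smaller of (nearest flanking local maximum - minimum)
    on each side; a chromosome end counts as the track extremum on that
    side. Minima closer than 2 bins are merged keeping the deeper one.
    """
    score = t.score
    if not np.isfinite(score).any():
        raise ValueError("insulation track is entirely undefined")
    minima, maxima = _local_extrema(score)
    cands: list[Boundary] = []
    for i in minima:
        left_max = [j for j in maxima if j < i]
        right_max = [j for j in maxima if j > i]
        finite = np.where(np.isfinite(score))[0]
        left_val = score[left_max[-1]] if left_max else np.nanmax(score[finite[0] : i + 1])
        right_val = score[right_max[0]] if right_max else np.nanmax(score[i : finite[-1] + 1])
        contrast = min(left_val, right_val) - score[i]
        if contrast >= min_delta:
            cands.append(Boundary(position=i, strength=float(contrast),
                                  insulation_minimum=float(score[i])))
    merged: list[Boundary] = []
    for b in sorted(cands, key=lambda b: b.position):
        if merged and b.position - merged[-1].position < 2:
            if b.insulation_minimum < merged[-1].insulation_minimum:
                merged[-1] = b
        else:
            merged.append(b)
    return merged


def boundaries_to_tads(
    bounds: list[Boundary], chrom: str = "chrS", resolution: int = 40_000,
    min_bins: int = 3,
) -> list[Tad]:
    """Consecutive boundaries delimit TADs; domains under ``min_bins`` drop."""
    pos = sorted(b.position for b in bounds)
    tads = []
    for a, b in zip(pos[:-1], pos[1:]):
        if b - a >= min_bins:
            tads.append(Tad(chrom=chrom, start=a * resolution, end=b * resolution,
                            start_bin=a, end_bin=b))
    return tads


def aggregate_boundary_profile(
    oe: ContactMatrix, bounds: list[Boundary], flank: int = 600_000
) -> np.ndarray:
    """Mean O/E submatrix over windows centered on each boundary.

    Boundaries within ``flank`` of a chromosome end are skipped; output is
    a (2*flank/res + 1)-square matrix.
    """
    f = flank // oe.resolution
    n = oe.n_bins
    eligible = [b for b in bounds if f <= b.position < n - f]
    if not eligible:
        raise ValueError("no boundaries far enough from chromosome ends")
    acc = np.zeros((2 * f + 1, 2 * f + 1))
    for b in eligible:
        i = b.position
        acc += oe.counts[i - f : i + f + 1, i - f : i + f + 1]
    return acc / len(eligible)


def relative_tad_intensity(oe: ContactMatrix, tad: Tad) -> float:
    """RTI: mean intra-TAD O/E over mean TAD-vs-flank O/E.

    Flanks are the adjacent regions of equal length on each side, truncated
    at chromosome ends; the denominator pools the two inter-domain
    rectangles. Returns NaN (flagged by the caller) when the flanks are
    fully masked.
    """
    a, b = tad.start_bin, tad.end_bin
    n = oe.n_bins
    keep = oe.unmasked
    length = b - a
    tad_bins = np.arange(a, b)
    tad_bins = tad_bins[keep[tad_bins]]
    if tad_bins.size == 0:
        return float("nan")
    intra = oe.counts[np.ix_(tad_bins, tad_bins)]
    iu = np.triu_indices(len(tad_bins), k=1)
    intra_vals = intra[iu]

    left = np.arange(max(0, a - length), a)
    right = np.arange(b, min(n, b + length))
    inter_vals = []
    for flank_bins in (left, right):
        fb = flank_bins[keep[flank_bins]] if flank_bins.size else flank_bins
        if fb.size:
            inter_vals.append(oe.counts[np.ix_(tad_bins, fb)].ravel())
    if not inter_vals or intra_vals.size == 0:
        warnings.warn("RTI undefined: flanks fully masked", stacklevel=2)
        return float("nan")
    inter = np.concatenate(inter_vals)
    inter_mean = inter.mean()
    if inter_mean == 0:
        return float("nan")
    return float(intra_vals.mean() / inter_mean)


def classify_tad_dynamics(
    rti_cc: float,
    rti_nt: float,
    rti_f: float,
    fold: float = 1.5,
    delta: float = 0.15,
    tol: float = 1e-9,
) -> str:
    """Static/Resis/Repro/Hyper label from per-condition RTIs.

    Static when the CC-vs-fESC change is under ``fold``; otherwise the
    trajectory coordinate r = (nt - cc) / (f - cc) is thresholded as in the
    compartment classifier, except that the intermediate band is folded
    into the nearest side (Repro when r > 0.5, else Resis) — there is no
    Partial group for TADs/loops.
    """
    for v in (rti_cc, rti_nt, rti_f):
        if not np.isfinite(v):
            raise ValueError("all three RTIs must be defined")
    if abs(np.log2(rti_cc / rti_f)) < np.log2(fold):
        return "Static"
    denom = rti_f - rti_cc
    if abs(denom) < tol:
        return "Static"
    r = (rti_nt - rti_cc) / denom
    if r <= delta:
        return "Resis"
    if r <= 1 - delta:
        return "Repro" if r > 0.5 else "Resis"
    if r <= 1 + delta:
        return "Repro"
    return "Hyper"


def specific_tads(rti_by_condition: pd.DataFrame, fold: float = 1.5) -> pd.Series:
    """Condition-specific TAD labels from an RTI table.

    ``rti_by_condition`` needs columns ``rti_cc`` and ``rti_f``. A TAD is
    CC-specific when rti_cc >= fold * rti_f, ESC-specific when
    rti_f >= fold * rti_cc, otherwise unspecific.
    """
    cc = rti_by_condition["rti_cc"].to_numpy(dtype=float)
    f = rti_by_condition["rti_f"].to_numpy(dtype=float)
    labels = np.full(len(cc), "unspecific", dtype=object)
    labels[cc >= fold * f] = "CC-specific"
    labels[f >= fold * cc] = "ESC-specific"
    return pd.Series(labels, index=rti_by_condition.index, name="specificity")


def consensus_boundaries(
    boundary_sets: list[list[Boundary]], min_support: int = 2, tol_bins: int = 1
) -> list[Boundary]:
    """Union of boundaries present in >= ``min_support`` conditions
    within +/- ``tol_bins``; position is that of the deepest supporting
    minimum. Used so cross-condition RTI triples share intervals."""
    all_b = sorted(
        (b for bs in boundary_sets for b in bs), key=lambda b: b.position
    )
    out: list[Boundary] = []
    used = [False] * len(all_b)
    for i, b in enumerate(all_b):
        if used[i]:
            continue
        group = [b]
        used[i] = True
        for j in range(i + 1, len(all_b)):
            if used[j]:
                continue
            if abs(all_b[j].position - b.position) <= tol_bins:
                group.append(all_b[j])
                used[j] = True
        support = 0
        for bs in boundary_sets:
            if any(abs(x.position - b.position) <= tol_bins for x in bs):
                support += 1
        if support >= min_support:
            deepest = min(group, key=lambda x: x.insulation_minimum)
            if not out or deepest.position - out[-1].position > tol_bins:
                out.append(deepest)
    return out
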