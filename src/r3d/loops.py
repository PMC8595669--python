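"""Focal chromatin-loop calling, APA scoring, and loop dynamics.

The caller is a desk-scale analogue of donut-style loop detection: each
in-band pixel is tested against Poisson expectations from four local
neighborhoods (donut, lower-left, horizontal, vertical), followed by
Benjamini-Hochberg control and 8-connectivity clustering of significant
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from r3d.contact import ContactMatrix, expected_profile, observed_over_expected


@dataclass
class Loop:
    chrom: str
    bin1: int
    bin2: int  # bin1 < bin2
    resolution: int
    enrichment: float  # pixel over max local-background expectation
    q_value: float
    n_pixels: int = 1  # pixels in the significant cluster

    @property
    def anchor1(self) -> tuple[int, int]:
        return (self.bin1 * self.resolution, (self.bin1 + 1) * self.resolution)

    @property
    def anchor2(self) -> tuple[int, int]:
        return (self.bin2 * self.resolution, (self.bin2 + 1) * self.resolution)


@dataclass
class ApaResult:
    window: np.ndarray  # (2k+1) x (2k+1) aggregate O/E
    apa_score: float
    n_loops: int


def _neighborhood_offsets(outer: int = 7, inner: int = 3):
    """Relative (di, dj) index sets for the four local backgrounds."""
    donut, lower_left, horizontal, vertical = [], [], [], []
    for di in range(-outer, outer + 1):
        for dj in range(-outer, outer + 1):
            if max(abs(di), abs(dj)) <= inner:
                continue  # exclude the inner square around the center
            donut.append((di, dj))
            if 1 <= di <= outer and -outer <= dj <= -1:
                lower_left.append((di, dj))
            if abs(di) <= 1:
                horizontal.append((di, dj))
            if abs(dj) <= 1:
                vertical.append((di, dj))
    return donut, lower_left, horizontal, vertical


def _neighborhood_kernels(outer: int = 7, inner: int = 3) -> list[np.ndarray]:
    """Convolution kernels (one per neighborhood) over a (2*outer+1)-square."""
    size = 2 * outer + 1
    kernels = [np.zeros((size, size)) for _ in range(4)]
    for idx, offs in enumerate(_neighborhood_offsets(outer, inner)):
        for di, dj in offs:
            kernels[idx][di + outer, dj + outer] = 1.0
    return kernels


def call_loops(
    m: ContactMatrix,
    min_dist: int = 100_000,
    max_dist: int = 2_000_000,
    fdr: float = 0.1,
    outer: int = 7,
    inner: int = 3,
    min_enrichment: float = 1.0,
) -> list[Loop]:
    """Call focal loops in the distance band [min_dist, max_dist].

    For every unmasked in-band pixel the expected count is estimated from
    each of the four neighborhoods as (neighborhood count sum / neighborhood
    decay-expected sum) * decay-expected at the pixel; the Poisson
    upper-tail p-value is taken against the maximum of the four. BH control
    at ``fdr`` runs across the whole band; significant pixels are clustered
    with 8-connectivity and each cluster reports its maximum-count pixel.
    """
    res = m.resolution
    lo = max(1, int(np.ceil(min_dist / res)))
    hi = int(max_dist // res)
    n = m.n_bins
    if lo > hi or lo >= n:
        raise ValueError("empty distance band at this resolution")
    prof = expected_profile(m)
    dmat = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    ev = prof.values[np.clip(dmat, 0, n - 1)]
    ev = np.where(np.isfinite(ev), ev, 0.0)
    keep = m.unmasked
    counts = m.counts

    # valid neighbor pixels: strict upper triangle with both bins unmasked
    valid = np.triu(np.ones((n, n), dtype=bool), k=1)
    valid &= keep[:, None] & keep[None, :]
    band_mask = valid & (dmat >= lo) & (dmat <= hi)
    if not band_mask.any():
        raise ValueError("no testable pixels in band")

    cw = np.where(valid, counts, 0.0)
    ew = np.where(valid, ev, 0.0)
    lam = np.zeros((n, n))
    for kernel in _neighborhood_kernels(outer, inner):
        # correlate (no kernel flip): sum over neighbors at the listed offsets
        csum = ndimage.correlate(cw, kernel, mode="constant", cval=0.0)
        esum = ndimage.correlate(ew, kernel, mode="constant", cval=0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lam_k = np.where(esum > 0, csum / esum * ev, 0.0)
        lam = np.maximum(lam, lam_k)

    test = band_mask & (lam > 0)
    ii, jj = np.nonzero(test)
    pvals = stats.poisson.sf(counts[ii, jj] - 1, lam[ii, jj])
    enr = counts[ii, jj] / lam[ii, jj]

    reject = _bh_reject(pvals, fdr)
    qvals = _bh_qvalues(pvals)

    sig = np.zeros((n, n), dtype=bool)
    qmap = np.ones((n, n))
    emap = np.zeros((n, n))
    hit = reject & (enr >= min_enrichment)
    sig[ii[hit], jj[hit]] = True
    qmap[ii[hit], jj[hit]] = qvals[hit]
    emap[ii[hit], jj[hit]] = enr[hit]

    labels, n_clusters = ndimage.label(sig, structure=np.ones((3, 3), dtype=int))
    loops: list[Loop] = []
    for c in range(1, n_clusters + 1):
        members = np.argwhere(labels == c)
        best = members[np.argmax([counts[i, j] for i, j in members])]
        i, j = int(best[0]), int(best[1])
        loops.append(
            Loop(
                chrom=m.chrom, bin1=i, bin2=j, resolution=res,
                enrichment=float(emap[i, j]), q_value=float(qmap[i, j]),
                n_pixels=len(members),
            )
        )
    return sorted(loops, key=lambda l: (l.bin1, l.bin2))


def _bh_reject(pvals: np.ndarray, fdr: float) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    thresh = fdr * (np.arange(1, m + 1)) / m
    passed = pvals[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.where(passed)[0])
        reject[order[: k + 1]] = True
    return reject


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def apa_score(m: ContactMatrix, loops: list[Loop], k: int = 5) -> ApaResult:
    """Aggregate peak analysis over a loop list.

    Averages (2k+1)-square O/E windows centered on each loop pixel;
    the APA score is the center value over the mean of the 3x3 block in
    the lower-left corner of the window (the short-distance corner).
    Loops too close to the diagonal or to matrix edges are skipped.
    """
    if not loops:
        raise ValueError("empty loop list")
    prof = expected_profile(m)
    oe = observed_over_expected(m, prof)
    n = m.n_bins
    acc = np.zeros((2 * k + 1, 2 * k + 1))
    used = 0
    min_sep = 2 * (2 * k + 1)
    for lp in loops:
        i, j = lp.bin1, lp.bin2
        if j - i < min_sep:
            continue
        if i - k < 0 or j + k >= n or i + k >= n or j - k < 0:
            continue
        acc += oe.counts[i - k : i + k + 1, j - k : j + k + 1]
        used += 1
    if used == 0:
        raise ValueError("no loops usable for APA at this k")
    window = acc / used
    corner = window[2 * k - 2 :, :3]
    corner_mean = corner.mean()
    score = float(window[k, k] / corner_mean) if corner_mean > 0 else float("nan")
    return ApaResult(window=window, apa_score=score, n_loops=used)


def apa_score_from_window(window: np.ndarray) -> float:
    """APA score of a pre-aggregated (2k+1)-square window: center pixel over
    the mean of the 3x3 lower-left corner block."""
    window = np.asarray(window, dtype=float)
    size = window.shape[0]
    if window.ndim != 2 or window.shape[1] != size or size % 2 == 0 or size < 5:
        raise ValueError("window must be square with odd size >= 5")
    k = size // 2
    corner_mean = window[size - 3 :, :3].mean()
    return float(window[k, k] / corner_mean)


def focal_enrichments(
    m: ContactMatrix,
    pairs: list[tuple[int, int]],
    outer: int = 7,
    inner: int = 3,
) -> np.ndarray:
    """Pixel over max-of-four local-background expectation for each pair.

    Same background model as :func:`call_loops`; NaN for pairs touching
    masked bins or with no informative neighborhood.
    """
    n = m.n_bins
    prof = expected_profile(m)
    dmat = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    ev = prof.values[np.clip(dmat, 0, n - 1)]
    ev = np.where(np.isfinite(ev), ev, 0.0)
    keep = m.unmasked
    valid = np.triu(np.ones((n, n), dtype=bool), k=1)
    valid &= keep[:, None] & keep[None, :]
    cw = np.where(valid, m.counts, 0.0)
    ew = np.where(valid, ev, 0.0)
    lam = np.zeros((n, n))
    for kernel in _neighborhood_kernels(outer, inner):
        csum = ndimage.correlate(cw, kernel, mode="constant", cval=0.0)
        esum = ndimage.correlate(ew, kernel, mode="constant", cval=0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.maximum(lam, np.where(esum > 0, csum / esum * ev, 0.0))
    out = np.full(len(pairs), np.nan)
    for idx, (a, b) in enumerate(pairs):
        i, j = min(a, b), max(a, b)
        if keep[i] and keep[j] and lam[i, j] > 0:
            out[idx] = m.counts[i, j] / lam[i, j]
    return out


def focal_enrichment(m: ContactMatrix, bin1: int, bin2: int, **kw) -> float:
    """Single-pair convenience wrapper around :func:`focal_enrichments`."""
    return float(focal_enrichments(m, [(bin1, bin2)], **kw)[0])


def union_loop_list(
    loop_sets: dict[str, list[Loop]], tol_bins: int = 1
) -> pd.DataFrame:
    """Merge per-condition loop calls into a union list.

    Loops from different conditions whose anchors agree within
    +/- ``tol_bins`` are the same loop; ``called_in`` records the calling
    conditions.
    """
    rows: list[dict] = []
    for cond, loops in loop_sets.items():
        for lp in loops:
            matched = False
            for row in rows:
                if (
                    abs(row["bin1"] - lp.bin1) <= tol_bins
                    and abs(row["bin2"] - lp.bin2) <= tol_bins
                ):
                    row["called_in"].add(cond)
                    matched = True
                    break
            if not matched:
                rows.append(
                    {"chrom": lp.chrom, "bin1": lp.bin1, "bin2": lp.bin2,
                     "resolution": lp.resolution, "called_in": {cond}}
                )
    return pd.DataFrame(rows)


def classify_loop_dynamics(
    union: pd.DataFrame,
    e_cc: np.ndarray,
    e_nt: np.ndarray,
    e_f: np.ndarray,
    fold: float = 1.5,
    delta: float = 0.15,
) -> pd.DataFrame:
    """Per-loop Static/Resis/Repro/Hyper labels plus specificity sets.

    Enrichment triples follow the same rule as TAD dynamics. Also flags
    CC-specific disappeared loops (called in CC only) and ESC-like gained
    loops (called in both ESC conditions but not CC) from ``called_in``.
    Loops with an undefined enrichment are skipped.
    """
    from r3d.domains import classify_tad_dynamics

    out = union.copy()
    labels, status = [], []
    for i, (cc_v, nt_v, f_v) in enumerate(zip(e_cc, e_nt, e_f)):
        called = out["called_in"].iloc[i]
        if not all(np.isfinite([cc_v, nt_v, f_v])):
            labels.append(None)
            status.append(None)
            continue
        labels.append(classify_tad_dynamics(cc_v, nt_v, f_v, fold=fold, delta=delta))
        if "cc" in called and not ({"nt", "f"} & called):
            status.append("CC-specific-disappeared")
        elif {"nt", "f"} <= called and "cc" not in called:
            status.append("ESC-like-gained")
        else:
            status.append("shared")
    out["e_cc"], out["e_nt"], out["e_f"] = e_cc, e_nt, e_f
    out["dynamics"] = labels
    out["status"] = status
    return out[out["dynamics"].notna()].reset_index(drop=True)


def write_bedpe(loops: list[Loop], path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a1, a2 = lp.anchor1, lp.anchor2
            fh.write(
                f"{lp.chrom}\t{a1[0]}\t{a1[1]}\t{lp.chrom}\t{a2[0]}\t{a2[1]}"
                f"\t.\t{lp.q_value:.4g}\n"
            )


def read_bedpe(path, resolution: int) -> list[Loop]:
    loops = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            f = ln.split()
            loops.append(
                Loop(
                    chrom=f[0], bin1=int(f[1]) // resolution,
                    bin2=int(f[4]) // resolution, resolution=resolution,
                    enrichment=float("nan"),
                    q_value=float(f[7]) if len(f) > 7 and f[7] != "." else float("nan"),
                )
            )
    return loops
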