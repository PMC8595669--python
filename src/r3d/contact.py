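"""Binned per-chromosome Hi-C contact matrices.

Loading, iterative-correction balancing, distance-decay expected profiles,
observed/expected maps, and contact-decay curves. All matrices are dense,
symmetric, cis-only, with 0-based half-open bin coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

DEFAULT_RESOLUTIONS = (5_000, 20_000, 40_000, 200_000)


class MatrixFormatError(ValueError):
    """Raised when a matrix file cannot be parsed."""


class MatrixValidationError(ValueError):
    """Raised when parsed records violate matrix invariants."""


@dataclass
class ContactMatrix:
    """Symmetric binned contact map for one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    resolution : int
        Bin width in bp.
    counts : ndarray of shape (n_bins, n_bins)
        Symmetric, non-negative contact counts (or balanced frequencies).
    balanced : bool
        Whether iterative correction has been applied.
    mask : ndarray of bool, shape (n_bins,)
        True for excluded bins; masked rows/columns are all zero.
    bias : ndarray or None
        Multiplicative per-bin bias from balancing (NaN at masked bins),
        such that ``balanced[i, j] = raw[i, j] / (bias[i] * bias[j])``.
    """

    chrom: str
    resolution: int
    counts: np.ndarray
    balanced: bool = False
    mask: np.ndarray = None  # type: ignore[assignment]
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise MatrixValidationError("counts must be a square matrix")
        if not np.allclose(self.counts, self.counts.T, equal_nan=True):
            raise MatrixValidationError("counts must be symmetric")
        if np.nanmin(self.counts) < 0:
            raise MatrixValidationError("counts must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_bins,):
                raise MatrixValidationError("mask length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean vector of retained bins."""
        return ~self.mask

    def copy(self) -> "ContactMatrix":
        return replace(
            self,
            counts=self.counts.copy(),
            mask=self.mask.copy(),
            bias=None if self.bias is None else self.bias.copy(),
        )


@dataclass
class ExpectedProfile:
    """Mean contact per genomic separation (in bins), over unmasked pairs."""

    resolution: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class DecayCurve:
    """Normalized contact probability over log-spaced genomic separations."""

    separations: np.ndarray  # bp, strictly increasing (bin midpoints)
    probability: np.ndarray  # sums to 1

    def value_at(self, separation_bp: float) -> float:
        """Curve value at the log-spaced bin containing ``separation_bp``."""
        idx = int(np.argmin(np.abs(np.log(self.separations) - np.log(separation_bp))))
        return float(self.probability[idx])


def default_mask(counts: np.ndarray, percentile: float = 1.0) -> np.ndarray:
    """Mask bins whose marginal is zero or below the given percentile of
    nonzero marginals."""
    marginals = counts.sum(axis=0)
    mask = marginals == 0
    nonzero = marginals[marginals > 0]
    if nonzero.size:
        cutoff = np.percentile(nonzero, percentile)
        mask |= marginals < cutoff
    return mask


def load_matrix(
    path: str | Path,
    chrom: str = "chrS",
    resolution: int = 200_000,
    n_bins: int | None = None,
) -> ContactMatrix:
    """Load a contact matrix from triplet text or dense TSV.

    Triplet files have three whitespace-separated columns
    ``bin_i  bin_j  count`` (0-based bins); dense files are square
    whitespace-separated numeric tables. The format is sniffed from the
    first data line. Bins with zero marginal are masked.

    Raises
    ------
    MatrixFormatError
        Empty file or unparseable content.
    MatrixValidationError
        Conflicting (i, j) vs (j, i) records in a triplet file.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise MatrixFormatError(f"no records in {path}")
    first = lines[0].split()
    try:
        [float(x) for x in first]
    except ValueError as exc:
        raise MatrixFormatError(f"unknown format in {path}: non-numeric fields") from exc

    if len(first) == 3 and all(len(ln.split()) == 3 for ln in lines[:20]):
        counts = _parse_triplets(lines, n_bins, path)
    else:
        counts = np.loadtxt(lines)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise MatrixFormatError(f"dense matrix in {path} is not square")
    m = ContactMatrix(chrom=chrom, resolution=resolution, counts=counts)
    m.mask = counts.sum(axis=0) == 0
    return m


def _parse_triplets(lines: list[str], n_bins: int | None, path: Path) -> np.ndarray:
    ii, jj, vv = [], [], []
    for ln in lines:
        fields = ln.split()
        if len(fields) != 3:
            raise MatrixFormatError(f"bad triplet line in {path}: {ln!r}")
        ii.append(int(fields[0]))
        jj.append(int(fields[1]))
        vv.append(float(fields[2]))
    i = np.array(ii)
    j = np.array(jj)
    v = np.array(vv)
    n = n_bins if n_bins is not None else int(max(i.max(), j.max())) + 1
    counts = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for a, b, val in zip(i, j, v):
        key = (min(a, b), max(a, b))
        if key in seen and seen[key] != val:
            raise MatrixValidationError(
                f"asymmetric records for bins {key} in {path}: {seen[key]} vs {val}"
            )
        seen[key] = val
        counts[a, b] = val
        counts[b, a] = val
    return counts


def write_matrix(m: ContactMatrix, path: str | Path, fmt: str = "triplet") -> None:
    """Write a matrix as upper-triangle triplet text or a dense TSV."""
    path = Path(path)
    if fmt == "triplet":
        with path.open("w") as fh:
            iu, ju = np.nonzero(np.triu(m.counts))
            for a, b in zip(iu, ju):
                fh.write(f"{a}\t{b}\t{m.counts[a, b]:.10g}\n")
    elif fmt == "dense":
        np.savetxt(path, m.counts, delimiter="\t", fmt="%.10g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def balance_matrix(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mask_percentile: float = 1.0,
) -> ContactMatrix:
    """Iterative-correction balancing (sequential row/column scaling).

    Equalizes unmasked row sums (to 1) within ``tol`` on the coefficient of
    variation of row sums. The bias vector is retained so the raw matrix can
    be recovered. Low-coverage bins are masked first (zero marginal or below
    the ``mask_percentile`` percentile of nonzero marginals).

    Non-convergence yields a warning and a best-effort result (still flagged
    balanced, with the achieved biases).
    """
    out = m.copy()
    out.mask = out.mask | default_mask(out.counts, mask_percentile)
    keep = out.unmasked
    if not keep.any():
        raise MatrixValidationError("all bins masked; cannot balance")
    w = out.counts.copy()
    w[out.mask, :] = 0.0
    w[:, out.mask] = 0.0

    bias = np.ones(out.n_bins)
    converged = False
    for _ in range(max_iter):
        s = w.sum(axis=1)
        s_keep = s[keep]
        cv = s_keep.std() / s_keep.mean() if s_keep.mean() > 0 else np.inf
        if cv < tol:
            converged = True
            break
        adj = np.ones_like(s)
        adj[keep] = s_keep / s_keep.mean()
        adj[adj == 0] = 1.0
        w = w / np.outer(adj, adj)
        bias *= adj
    if not converged:
        warnings.warn(
            f"balancing did not converge in {max_iter} iterations (cv={cv:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    # scale so unmasked row sums are exactly ~1
    s_keep = w[keep].sum(axis=1)
    scale = s_keep.mean()
    if scale > 0:
        w /= scale
        bias *= np.sqrt(scale)
    out.counts = w
    out.balanced = True
    full_bias = np.where(keep, bias, np.nan)
    out.bias = full_bias
    return out


def expected_profile(m: ContactMatrix) -> ExpectedProfile:
    """Mean contact per separation d over unmasked bin pairs.

    ``values[d]`` is the mean of ``m[i, i+d]`` over all i with both bins
    unmasked; NaN where no unmasked pair exists at that separation.
    """
    keep = m.unmasked
    if not keep.any():
        raise MatrixValidationError("all bins masked")
    n = m.n_bins
    values = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(m.counts, offset=d)
        ok = keep[: n - d] & keep[d:]
        if ok.any():
            values[d] = diag[ok].mean()
    return ExpectedProfile(resolution=m.resolution, values=values)


def observed_over_expected(m: ContactMatrix, e: ExpectedProfile) -> ContactMatrix:
    """Divide each entry by the expected value at its separation.

    Entries where the expected value is zero or undefined become 0; masked
    bins stay masked (all-zero rows).
    """
    if e.resolution != m.resolution:
        raise MatrixValidationError(
            f"resolution mismatch: matrix {m.resolution}, profile {e.resolution}"
        )
    if len(e.values) != m.n_bins:
        raise MatrixValidationError("profile length does not match n_bins")
    n = m.n_bins
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    ev = e.values[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((ev > 0) & np.isfinite(ev), m.counts / ev, 0.0)
    oe[m.mask, :] = 0.0
    oe[:, m.mask] = 0.0
    out = m.copy()
    out.counts = oe
    return out


def contact_decay_curve(m: ContactMatrix, bins_per_decade: int = 8) -> DecayCurve:
    """Log-binned contact probability versus genomic separation.

    Mean contact per log-spaced separation bin, corrected for the number of
    pixel pairs available at each separation, normalized to sum to 1.
    """
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    prof = expected_profile(m)
    n = m.n_bins
    if n < 3:
        raise MatrixValidationError("matrix too small for a decay curve")
    seps_bp = np.arange(1, n) * m.resolution
    means = prof.values[1:]
    lo, hi = np.log10(seps_bp[0]), np.log10(seps_bp[-1])
    n_curve = max(2, int(np.ceil((hi - lo) * bins_per_decade)))
    edges = np.logspace(lo, hi + 1e-9, n_curve + 1)
    idx = np.clip(np.digitize(seps_bp, edges) - 1, 0, n_curve - 1)
    sep_mid, prob = [], []
    for k in range(n_curve):
        sel = (idx == k) & np.isfinite(means)
        if sel.any():
            sep_mid.append(np.sqrt(edges[k] * edges[k + 1]))
            prob.append(means[sel].mean())
    probability = np.array(prob)
    total = probability.sum()
    if total <= 0:
        raise MatrixValidationError("empty decay curve")
    return DecayCurve(separations=np.array(sep_mid), probability=probability / total)
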