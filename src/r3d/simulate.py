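"""Synthetic Hi-C / ATAC / ChIP / expression data with planted ground truth.

Truth is generated first (compartment scores, TAD boundaries, loop pixels,
peak-cluster labels, marked regions); matrices and tracks are then derived
from it, so every truth record is realizable in the emitted data. All
randomness flows through a single seed for bit-reproducibility.

The contact-map generative model is

    mu(i, j) = depth * (|i - j| + 1)^(-alpha) * plaid(i, j) * tad(i, j) * loop(i, j)

with ``plaid(i, j) = w ** (s_i * s_j)`` for per-bin compartment scores s
(so same-sign pairs are enriched w-fold and opposite-sign pairs depleted
w-fold at |s| = 1), and counts Poisson-sampled around mu, optionally times
a per-bin multiplicative lognormal bias to exercise balancing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from r3d.atac import PeakMatrix
from r3d.contact import ContactMatrix

CONDITION_LINES = {"cc": ["CC"], "nt": ["NT5", "NT6"], "f": ["F35", "F40"]}

# trajectory coordinate r = (nt - cc) / (f - cc) planted per dynamics class
CLASS_R = {"Resis": 0.05, "Partial": 0.5, "Repro": 1.0, "Hyper": 1.4}

# log2-intensity archetypes per peak cluster across (CC, NT5, NT6, F35, F40);
# the C3 family (C3/C4/C5) shares a strong CC-low axis so it stays one
# K-means cluster, with the C4/C5 fESC-vs-ntESC tilt at 2 log2 units
PEAK_ARCHETYPES = {
    "C1": (7.0, 7.0, 7.0, 7.0, 7.0),
    "C2": (8.0, 1.0, 1.0, 1.0, 1.0),
    "C3": (1.0, 8.0, 8.0, 8.0, 8.0),
    "C4": (1.0, 6.0, 6.0, 8.0, 8.0),
    "C5": (1.0, 8.0, 8.0, 6.0, 6.0),
}


@dataclass
class SimulationConfig:
    """Knobs for every synthetic generator; identical config => identical output."""

    seed: int = 0
    # contact maps
    n_bins: int = 600
    resolution: int = 200_000
    decay_exponent: float = 1.0
    depth: float = 1000.0
    bias_sigma: float = 0.0  # lognormal per-bin bias; 0 disables
    # compartments
    block_bins: tuple[int, int] = (8, 20)
    within_enrichment: float = 2.0
    switch_fraction: float = 0.3
    class_proportions: dict = field(
        default_factory=lambda: {"Repro": 0.4, "Partial": 0.2, "Hyper": 0.2, "Resis": 0.2}
    )
    donor_magnitude: float = 0.4  # |score| in the donor state (B side weaker)
    esc_magnitude: float = 1.0
    # TADs
    tad_bins: tuple[int, int] = (10, 30)
    tad_enrichment: float = 3.0
    nested_enrichment: float = 1.0  # >1 adds a nested sub-domain per TAD
    # loops
    n_loops: int = 20
    loop_sep_bins: tuple[int, int] = (25, 80)
    loop_enrichment: float = 2.5
    # tracks / tables
    pc1_noise: float = 0.05
    peak_noise: float = 0.1
    n_peaks_per_cluster: int = 100
    chip_marked_mean: float = 3.0
    chip_unmarked_mean: float = 1.0
    chip_noise: float = 0.2


@dataclass
class TruthSet:
    """Planted ground truth backing the emitted matrices and tracks."""

    scores: dict | None = None  # condition -> per-bin compartment score
    regions: pd.DataFrame | None = None  # block-level truth (start/end bins, class)
    boundaries: list | None = None  # planted boundary bin positions
    tads: pd.DataFrame | None = None
    loops: list | None = None  # (bin1, bin2) planted loop pixels
    peak_labels: pd.Series | None = None
    marked: np.ndarray | None = None  # per-region marked flag


def _check_proportions(cfg: SimulationConfig) -> None:
    total = sum(cfg.class_proportions.values())
    if total > 1 + 1e-9 or any(v < 0 for v in cfg.class_proportions.values()):
        raise ValueError("class proportions must be non-negative and sum to <= 1")


# ---------------------------------------------------------------------------
# compartment truth and matrices


def plant_compartment_truth(cfg: SimulationConfig) -> TruthSet:
    """Alternate A/B blocks along the chromosome and plant switch classes.

    Donor (cc) blocks alternate sign at magnitude ``donor_magnitude``; in
    the fESC state a ``switch_fraction`` of blocks flip sign to magnitude
    ``esc_magnitude``, each switched block drawing a dynamics class; the
    ntESC score interpolates along the planted trajectory coordinate.
    """
    _check_proportions(cfg)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_bins
    blocks = []
    pos = 0
    sign = 1.0
    while pos < n:
        size = int(rng.integers(cfg.block_bins[0], cfg.block_bins[1] + 1))
        blocks.append((pos, min(n, pos + size), sign))
        pos += size
        sign = -sign

    classes = list(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[c] for c in classes], dtype=float)
    probs = probs / probs.sum() if probs.sum() > 0 else probs

    s_cc = np.zeros(n)
    s_nt = np.zeros(n)
    s_f = np.zeros(n)
    rows = []
    for start, end, sgn in blocks:
        cc_val = sgn * cfg.donor_magnitude
        switched = rng.random() < cfg.switch_fraction
        if switched and probs.sum() > 0:
            cls = str(rng.choice(classes, p=probs))
            f_val = -sgn * cfg.esc_magnitude
            nt_val = cc_val + CLASS_R[cls] * (f_val - cc_val)
        else:
            cls = "stable"
            f_val = sgn * cfg.esc_magnitude
            nt_val = f_val
        s_cc[start:end] = cc_val
        s_nt[start:end] = nt_val
        s_f[start:end] = f_val
        rows.append(
            {"start_bin": start, "end_bin": end, "cc_score": cc_val,
             "nt_score": nt_val, "f_score": f_val, "class": cls,
             "transition": "stable" if cls == "stable"
             else ("B-to-A" if cc_val < 0 else "A-to-B")}
        )
    return TruthSet(
        scores={"cc": s_cc, "nt": s_nt, "f": s_f},
        regions=pd.DataFrame(rows),
    )


def plant_tad_truth(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> TruthSet:
    """Tile the chromosome with TADs of random size; boundaries at joints."""
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_bins
    bounds = [0]
    while bounds[-1] < n:
        bounds.append(bounds[-1] + int(rng.integers(cfg.tad_bins[0], cfg.tad_bins[1] + 1)))
    bounds[-1] = n
    tads = pd.DataFrame(
        {"start_bin": bounds[:-1], "end_bin": bounds[1:]}
    )
    return TruthSet(boundaries=bounds[1:-1], tads=tads)


def plant_loop_truth(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[tuple[int, int]]:
    """Random well-separated loop pixels inside the separation band."""
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_bins
    loops: list[tuple[int, int]] = []
    attempts = 0
    while len(loops) < cfg.n_loops and attempts < 100 * cfg.n_loops:
        attempts += 1
        sep = int(rng.integers(cfg.loop_sep_bins[0], cfg.loop_sep_bins[1] + 1))
        i = int(rng.integers(0, n - sep))
        j = i + sep
        if all(abs(i - a) > 3 or abs(j - b) > 3 for a, b in loops):
            loops.append((i, j))
    return sorted(loops)


def expected_matrix(
    cfg: SimulationConfig,
    scores: np.ndarray | None = None,
    tads: pd.DataFrame | None = None,
    loops: list[tuple[int, int]] | None = None,
    tad_enrichments: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free expected contact map mu(i, j) under the generative model."""
    n = cfg.n_bins
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    mu = cfg.depth * (d + 1.0) ** (-cfg.decay_exponent)
    if scores is not None:
        mu *= cfg.within_enrichment ** np.outer(scores, scores)
    if tads is not None:
        enr = tad_enrichments
        for t_idx, (_, tad) in enumerate(tads.iterrows()):
            a, b = int(tad["start_bin"]), int(tad["end_bin"])
            e = cfg.tad_enrichment if enr is None else float(enr[t_idx])
            mu[a:b, a:b] *= e
            if cfg.nested_enrichment > 1.0 and b - a >= 6:
                mid0 = a + (b - a) // 4
                mid1 = b - (b - a) // 4
                mu[mid0:mid1, mid0:mid1] *= cfg.nested_enrichment
        np.fill_diagonal(mu, np.diagonal(mu))
    if loops is not None:
        for i, j in loops:
            mu[i, j] *= cfg.loop_enrichment
            mu[j, i] *= cfg.loop_enrichment
    return mu


def noiseless_oe_matrix(
    cfg: SimulationConfig,
    scores: np.ndarray | None = None,
    tads: pd.DataFrame | None = None,
    loops: list[tuple[int, int]] | None = None,
    tad_enrichments: np.ndarray | None = None,
    chrom: str = "chrS",
) -> ContactMatrix:
    """Exact O/E matrix of the generative model (structure factors only).

    Dividing mu by the decay law leaves the plaid/TAD/loop factor product —
    the noise-free observed-over-expected map, useful for calibration
    (e.g. a single planted TAD at intra/inter ratio q has RTI exactly q).
    """
    from dataclasses import replace

    flat = replace(cfg, depth=1.0, decay_exponent=0.0)
    oe = expected_matrix(flat, scores=scores, tads=tads, loops=loops,
                         tad_enrichments=tad_enrichments)
    cm = ContactMatrix(chrom=chrom, resolution=cfg.resolution, counts=oe, balanced=True)
    return cm


def sample_matrix(
    mu: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    chrom: str = "chrS",
) -> ContactMatrix:
    """Poisson-sample a symmetric count matrix around mu (upper triangle)."""
    n = mu.shape[0]
    m = mu.copy()
    if cfg.bias_sigma > 0:
        bias = rng.lognormal(mean=0.0, sigma=cfg.bias_sigma, size=n)
        m = m * np.outer(bias, bias)
    iu = np.triu_indices(n)
    counts = np.zeros((n, n))
    draws = rng.poisson(m[iu])
    counts[iu] = draws
    counts = counts + np.triu(counts, k=1).T
    cm = ContactMatrix(chrom=chrom, resolution=cfg.resolution, counts=counts)
    cm.mask = counts.sum(axis=0) == 0
    return cm


def simulate_contact_matrix(
    cfg: SimulationConfig, condition: str = "cc"
) -> tuple[ContactMatrix, TruthSet]:
    """One planted-compartment matrix for a condition in {cc, nt, f}."""
    truth = plant_compartment_truth(cfg)
    if condition not in truth.scores:
        raise ValueError(f"unknown condition {condition!r}")
    mu = expected_matrix(cfg, scores=truth.scores[condition])
    rng = np.random.default_rng([cfg.seed, *condition.encode()])
    return sample_matrix(mu, cfg, rng), truth


def simulate_condition_series(
    cfg: SimulationConfig,
) -> tuple[dict[str, ContactMatrix], TruthSet]:
    """Matrices for CC, NT5, NT6, F35, F40 from one compartment truth.

    Line pairs are independent Poisson draws from identical expected maps.
    """
    truth = plant_compartment_truth(cfg)
    out: dict[str, ContactMatrix] = {}
    for cond, lines in CONDITION_LINES.items():
        mu = expected_matrix(cfg, scores=truth.scores[cond])
        for k, line in enumerate(lines):
            rng = np.random.default_rng([cfg.seed, k, *line.encode()])
            out[line] = sample_matrix(mu, cfg, rng)
    return out, truth


def activity_from_scores(scores: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Reference activity track: high where the planted state is A."""
    base = np.where(scores > 0, 2.0, 1.0)
    if rng is not None:
        base = base + rng.normal(0, 0.05, size=base.shape)
    return base


def simulate_tad_matrix(
    cfg: SimulationConfig, tad_enrichments: np.ndarray | None = None, noiseless: bool = False
) -> tuple[ContactMatrix, TruthSet]:
    """Planted-TAD matrix (no plaid), optionally noise-free."""
    rng = np.random.default_rng(cfg.seed)
    truth = plant_tad_truth(cfg, rng)
    mu = expected_matrix(cfg, tads=truth.tads, tad_enrichments=tad_enrichments)
    if noiseless:
        cm = ContactMatrix(chrom="chrS", resolution=cfg.resolution, counts=mu)
        return cm, truth
    return sample_matrix(mu, cfg, rng), truth


def simulate_loop_matrix(
    cfg: SimulationConfig, with_loops: bool = True
) -> tuple[ContactMatrix, TruthSet]:
    """Decay-only matrix with (or without) planted focal loop pixels."""
    rng = np.random.default_rng(cfg.seed)
    loops = plant_loop_truth(cfg, rng) if with_loops else []
    mu = expected_matrix(cfg, loops=loops if with_loops else None)
    cm = sample_matrix(mu, cfg, rng)
    return cm, TruthSet(loops=loops)


# ---------------------------------------------------------------------------
# track-level trajectories


def simulate_pc1_trajectories(
    cfg: SimulationConfig, n_regions: int = 200
) -> pd.DataFrame:
    """Planted (cc, nt, f) PC1 triples for switched regions with noise.

    Magnitudes are asymmetric (donor side weaker) so mid-trajectory values
    sit clear of zero. Returns cc_pc1 / nt_pc1 / f_pc1 / true_class.
    """
    _check_proportions(cfg)
    rng = np.random.default_rng(cfg.seed)
    classes = list(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[c] for c in classes], dtype=float)
    probs /= probs.sum()
    rows = []
    for _ in range(n_regions):
        cls = str(rng.choice(classes, p=probs))
        sgn = 1.0 if rng.random() < 0.5 else -1.0  # donor A or donor B
        cc = sgn * cfg.donor_magnitude
        f = -sgn * cfg.esc_magnitude
        nt = cc + CLASS_R[cls] * (f - cc)
        noise = rng.normal(0, cfg.pc1_noise, size=3)
        rows.append(
            {"cc_pc1": cc + noise[0], "nt_pc1": nt + noise[1],
             "f_pc1": f + noise[2], "true_class": cls}
        )
    return pd.DataFrame(rows)


def simulate_rti_triples(
    cfg: SimulationConfig, n_tads: int = 200, noise: float = 0.05
) -> pd.DataFrame:
    """Planted per-TAD RTI triples for the four TAD-dynamics groups.

    Static TADs keep rti ~2 in every condition; for the dynamic groups the
    CC RTI is 3 and the fESC RTI 1.2, with the ntESC value set by the class
    trajectory coordinate. Multiplicative noise is lognormal.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = ["Static", "Repro", "Resis", "Hyper"]
    rows = []
    for _ in range(n_tads):
        cls = groups[int(rng.integers(0, len(groups)))]
        if cls == "Static":
            cc = f = 2.0
            nt = 2.0
        else:
            cc, f = 3.0, 1.2
            r = {"Resis": 0.05, "Repro": 1.0, "Hyper": 1.5}[cls]
            nt = cc + r * (f - cc)
        eps = rng.lognormal(0, noise, size=3)
        rows.append({"rti_cc": cc * eps[0], "rti_nt": nt * eps[1],
                     "rti_f": f * eps[2], "true_class": cls})
    return pd.DataFrame(rows)


def simulate_process_states(
    cfg: SimulationConfig,
    n_common: int = 30,
    n_nt_specific: int = 20,
    n_ipsc_specific: int = 10,
    n_stable: int = 40,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Five-condition PC1 tracks with known switch-category counts.

    Returns pc1 vectors for cc / mef / nt / ipsc / esc plus a truth table
    of the planted category per bin. NT-specific bins alternate donor- and
    method-specific sub-types.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    pc1 = {k: [] for k in ("cc", "mef", "nt", "ipsc", "esc")}

    def push(cc_s, mef_s, nt_s, ipsc_s, esc_s, category):
        for key, s in zip(("cc", "mef", "nt", "ipsc", "esc"),
                          (cc_s, mef_s, nt_s, ipsc_s, esc_s)):
            pc1[key].append(s * (0.5 + 0.1 * rng.random()))
        rows.append({"category": category})

    for _ in range(n_common):
        push(-1, -1, 1, 1, 1, "common")
    for i in range(n_nt_specific):
        if i % 2 == 0:
            push(-1, 1, 1, 1, 1, "NT-specific")  # donor-specific
        else:
            push(-1, -1, 1, -1, 1, "NT-specific")  # method-specific
    for i in range(n_ipsc_specific):
        if i % 2 == 0:
            push(1, -1, 1, 1, 1, "iPSC-specific")  # donor-specific
        else:
            push(-1, -1, -1, 1, 1, "iPSC-specific")  # method-specific
    for _ in range(n_stable):
        push(1, 1, 1, 1, 1, "none")
    order = rng.permutation(len(rows))
    truth = pd.DataFrame(rows).iloc[order].reset_index(drop=True)
    tracks = {k: np.array(v)[order] for k, v in pc1.items()}
    return tracks, truth


# ---------------------------------------------------------------------------
# peaks, signal, expression


def simulate_peak_matrix(cfg: SimulationConfig) -> tuple[PeakMatrix, TruthSet]:
    """Peak-by-sample intensities around the five cluster archetypes.

    Noise is lognormal: Gaussian sigma = ``peak_noise`` on the log2
    archetype, exponentiated to raw intensity space.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = ["CC", "NT5", "NT6", "F35", "F40"]
    rows, labels, peaks = [], [], []
    pos = 1000
    for cls, arch in PEAK_ARCHETYPES.items():
        for _ in range(cfg.n_peaks_per_cluster):
            logv = np.array(arch) + rng.normal(0, cfg.peak_noise, size=len(arch))
            rows.append(np.exp2(logv))
            labels.append(cls)
            peaks.append({"chrom": "chrS", "start": pos, "end": pos + 500})
            pos += 1500
    intensity = pd.DataFrame(rows, columns=samples)
    pm = PeakMatrix(peaks=pd.DataFrame(peaks), intensity=intensity)
    return pm, TruthSet(peak_labels=pd.Series(labels))


def simulate_signal_track(
    cfg: SimulationConfig, regions: pd.DataFrame, marked: np.ndarray
) -> pd.DataFrame:
    """ChIP/Input bedGraph with elevated ratios over marked regions.

    ``regions`` needs start/end in bp; emits one interval per resolution
    bin with lognormal ratios around the marked/unmarked means.
    """
    if regions is None or marked is None:
        raise ValueError("truth regions and marked flags are required")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for (_, reg), is_marked in zip(regions.iterrows(), marked):
        mean = cfg.chip_marked_mean if is_marked else cfg.chip_unmarked_mean
        for s in range(int(reg["start"]), int(reg["end"]), cfg.resolution):
            ratio = mean * rng.lognormal(0, cfg.chip_noise)
            rows.append({"chrom": "chrS", "start": s,
                         "end": min(int(reg["end"]), s + cfg.resolution),
                         "ratio": ratio})
    return pd.DataFrame(rows)


def simulate_expression(
    cfg: SimulationConfig, truth: TruthSet, n_genes_per_region: int = 4
) -> pd.DataFrame:
    """FPKM table planted so Resis A-to-B genes drop in the ESC conditions.

    Genes are laid down at region midpoint TSSs; baseline FPKM is lognormal
    around 10 in every condition, and genes inside A-to-B regions (donor A,
    ESC B) are attenuated in the ntESC/fESC columns.
    """
    if truth.regions is None:
        raise ValueError("truth with planted regions is required")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    gid = 0
    for _, reg in truth.regions.iterrows():
        start_bp = int(reg["start_bin"]) * cfg.resolution
        end_bp = int(reg["end_bin"]) * cfg.resolution
        lost = reg["transition"] == "A-to-B"
        for g in range(n_genes_per_region):
            tss = start_bp + (g + 1) * (end_bp - start_bp) // (n_genes_per_region + 1)
            base = 10.0 * rng.lognormal(0, 0.3)
            esc_factor = 0.25 if lost else 1.0
            rows.append(
                {"gene": f"g{gid}", "chrom": "chrS", "tss": tss,
                 "CC": base * rng.lognormal(0, 0.1),
                 "NT5": base * esc_factor * rng.lognormal(0, 0.1),
                 "NT6": base * esc_factor * rng.lognormal(0, 0.1),
                 "F35": base * esc_factor * rng.lognormal(0, 0.1),
                 "F40": base * esc_factor * rng.lognormal(0, 0.1)}
            )
            gid += 1
    return pd.DataFrame(rows)
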