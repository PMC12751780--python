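"""Local ancestry by haplotype copying, and the excess-ancestry test.

Each admixed haplotype is modelled as a mosaic of copies of reference
haplotypes from two source panels (indicine-like "B", taurine-like "A").  A
dynamic program over template haplotypes minimizes allele mismatches plus a
per-switch penalty; the ancestry label at a site is the source panel of the
optimal path's template.  Robustness comes from bagging: the DP is re-run
over a bag of switch penalties × resampled reference subsets and the
per-site labels are decided by majority vote.

Downstream: label runs are assembled into segments (midpoint-to-midpoint
spans), per-window ancestry frequencies feed a one-sided Z-test for excess
ancestry (retained iff frequency ≥ 0.7 and P < 0.01), and global ancestry
fractions summarize the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import norm

from .panel import MISSING, HaplotypePanel
from .stats import WindowGrid


@dataclass
class CopyingParams:
    """Bagging design for the copying DP.

    ``penalty_bag`` × ``n_bag_runs`` paths are computed per haplotype, each
    run on a random ``subsample_frac`` subset of every reference panel.
    Sites whose winning vote fraction falls below ``low_conf_threshold`` are
    flagged and excluded from segment building (never from frequency tables).
    """

    penalty_bag: tuple = (1.5, 2.0, 3.0, 5.0)
    n_bag_runs: int = 5
    subsample_frac: float = 0.8
    low_conf_threshold: float = 0.6

    def __post_init__(self):
        if any(p <= 0 for p in self.penalty_bag):
            raise ValueError("switch penalties must be positive")


@njit(cache=True)
def _viterbi_path(emit, penalty):
    """Min-cost template path; ties resolved toward no-switch, then lowest index.

    emit: (n_sites, n_templates) float mismatch costs.
    """
    m, r = emit.shape
    back = np.empty((m, r), dtype=np.int32)
    prev = emit[0].copy()
    for j in range(r):
        back[0, j] = j
    for t in range(1, m):
        best = prev[0]
        bi = 0
        for j in range(1, r):
            if prev[j] < best:
                best = prev[j]
                bi = j
        sw = best + penalty
        for j in range(r):
            if prev[j] <= sw:
                back[t, j] = j
                prev[j] = prev[j] + emit[t, j]
            else:
                back[t, j] = bi
                prev[j] = sw + emit[t, j]
    j = 0
    best = prev[0]
    for k in range(1, r):
        if prev[k] < best:
            best = prev[k]
            j = k
    path = np.empty(m, dtype=np.int32)
    path[m - 1] = j
    for t in range(m - 1, 0, -1):
        j = back[t, j]
        path[t - 1] = j
    return path, best


def copy_path(query, ref_a: np.ndarray, ref_b: np.ndarray, switch_penalty=2.0):
    """Optimal copying path of one query haplotype over two reference panels.

    Returns (labels, templates, total_cost): labels per site (0 = panel A,
    1 = panel B), the winning template index (A haplotypes first, then B),
    and the path cost.  Missing query alleles cost nothing against any
    template.
    """
    if ref_a.shape[0] == 0 or ref_b.shape[0] == 0:
        raise ValueError("reference panels must be non-empty")
    query = np.asarray(query)
    refs = np.vstack([ref_a, ref_b])
    emit = (refs != query[None, :]).T.astype(np.float64)
    emit[query == MISSING, :] = 0.0
    path, cost = _viterbi_path(emit, float(switch_penalty))
    labels = (path >= ref_a.shape[0]).astype(np.int8)
    return labels, path, float(cost)


def bagged_ancestry(query, ref_a, ref_b, params: CopyingParams | None = None,
                    rng=None):
    """Majority-vote ancestry labels for one query haplotype.

    Returns (labels, vote_fraction): labels in {0 = A, 1 = B} and the winning
    fraction per site (ties go to A).  Deterministic given the rng state.
    """
    params = params or CopyingParams()
    rng = np.random.default_rng(rng)
    m = np.asarray(query).size
    votes_b = np.zeros(m, dtype=np.int64)
    n_runs = 0
    for penalty in params.penalty_bag:
        for _ in range(params.n_bag_runs):
            sub_a = _subsample(ref_a, params.subsample_frac, rng)
            sub_b = _subsample(ref_b, params.subsample_frac, rng)
            labels, _, _ = copy_path(query, sub_a, sub_b, penalty)
            votes_b += labels
            n_runs += 1
    frac_b = votes_b / n_runs
    labels = (frac_b > 0.5).astype(np.int8)
    vote_fraction = np.where(labels == 1, frac_b, 1.0 - frac_b)
    return labels, vote_fraction


def _subsample(ref, frac, rng):
    n = ref.shape[0]
    k = max(2, int(round(frac * n)))
    if k >= n:
        return ref
    return ref[np.sort(rng.choice(n, size=k, replace=False))]


def infer_ancestry(admixed: HaplotypePanel, panel_a: HaplotypePanel,
                   panel_b: HaplotypePanel, params=None, seed=0):
    """Bagged labels and vote fractions for every haplotype of an admixed panel.

    Returns (labels, votes), each of shape (n_haplotypes, n_sites).
    """
    for p in (admixed, panel_a, panel_b):
        p.require_phased("ancestry copying")
    if not (np.array_equal(admixed.positions, panel_a.positions)
            and np.array_equal(admixed.positions, panel_b.positions)):
        raise ValueError("all panels must share the site list")
    params = params or CopyingParams()
    rng = np.random.default_rng(seed)
    labels = np.empty(admixed.alleles.shape, dtype=np.int8)
    votes = np.empty(admixed.alleles.shape, dtype=float)
    for h in range(admixed.n_haplotypes):
        labels[h], votes[h] = bagged_ancestry(
            admixed.alleles[h], panel_a.alleles, panel_b.alleles, params, rng)
    return labels, votes


# ---------------------------------------------------------------------------
# Segments, window frequencies, excess test, global fractions
# ---------------------------------------------------------------------------

def segment_bounds(positions, chrom_len_bp):
    """Per-site span boundaries: midpoints between flanking SNPs.

    Site i owns [bounds[i], bounds[i+1]); the first span starts at 0 and the
    last ends at chrom_len_bp, so spans tile the chromosome.
    """
    pos0 = np.asarray(positions, dtype=float) - 1.0
    mids = (pos0[:-1] + pos0[1:]) / 2.0
    return np.concatenate([[0.0], mids, [float(chrom_len_bp)]])


def labels_to_segments(labels, positions, chrom_len_bp, min_len_bp=1_000,
                       mask=None) -> pd.DataFrame:
    """Maximal same-label runs as (start_bp, end_bp, label) segments.

    Segment spans use the midpoint convention of :func:`segment_bounds`, so a
    minimum length is well defined between sparse SNPs.  Runs shorter than
    ``min_len_bp`` are discarded.  ``mask`` marks sites to exclude (e.g.
    low-confidence votes); excluded sites break runs.
    """
    labels = np.asarray(labels)
    bounds = segment_bounds(positions, chrom_len_bp)
    keep = np.ones(labels.size, dtype=bool) if mask is None else ~np.asarray(mask)
    rows = []
    i = 0
    m = labels.size
    while i < m:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and keep[j + 1] and labels[j + 1] == labels[i]:
            j += 1
        start, end = bounds[i], bounds[j + 1]
        if end - start >= min_len_bp:
            rows.append((int(start), int(end), int(labels[i])))
        i = j + 1
    return pd.DataFrame(rows, columns=["start_bp", "end_bp", "label"])


def ancestry_window_freq(labels, positions, grid: WindowGrid, ancestry=1) -> np.ndarray:
    """Per-window frequency of an ancestry across haplotypes and sites."""
    labels = np.atleast_2d(labels)
    lo, hi = grid.site_window_matrix(positions)
    ind = (labels == ancestry).mean(axis=0)
    c = np.concatenate([[0.0], np.cumsum(ind)])
    counts = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, (c[hi] - c[lo]) / np.maximum(counts, 1), np.nan)


def excess_ancestry_test(window_freqs, freq_min=0.7, p_max=0.01) -> pd.DataFrame:
    """One-sided Z-test for windows with excess ancestry.

    Z uses the genome-wide mean and SD of the per-window frequencies as the
    empirical null; a window is retained iff its frequency ≥ ``freq_min`` AND
    its upper-tail normal P < ``p_max``.
    """
    f = np.asarray(window_freqs, dtype=float)
    ok = np.isfinite(f)
    mu = np.nanmean(f[ok]) if ok.any() else np.nan
    sd = np.nanstd(f[ok], ddof=0) if ok.any() else np.nan
    if not np.isfinite(sd) or sd <= 1e-12:
        z = np.full(f.size, np.nan)
        p = np.full(f.size, np.nan)
        retained = np.zeros(f.size, dtype=bool)
    else:
        z = (f - mu) / sd
        p = norm.sf(z)
        retained = ok & (f >= freq_min) & (p < p_max)
    return pd.DataFrame({"freq": f, "Z": z, "P": p, "retained": retained})


def global_ancestry(labels_by_chrom: dict, positions_by_chrom: dict,
                    chrom_len_bp) -> tuple[np.ndarray, float]:
    """Span-weighted ancestry-B fraction per haplotype and its population mean.

    ``chrom_len_bp`` may be an int (all chromosomes equal) or a dict.
    The A fraction is 1 minus the returned B fraction.
    """
    num = None
    tot = 0.0
    for chrom, labels in labels_by_chrom.items():
        L = chrom_len_bp[chrom] if isinstance(chrom_len_bp, dict) else chrom_len_bp
        bounds = segment_bounds(positions_by_chrom[chrom], L)
        spans = np.diff(bounds)
        contrib = (np.atleast_2d(labels) == 1) @ spans
        num = contrib if num is None else num + contrib
        tot += float(L)
    frac = num / tot
    return frac, float(frac.mean())


def truth_labels_at_sites(truth: pd.DataFrame, chrom, positions,
                          haplotype_ids) -> np.ndarray:
    """Ground-truth ancestry label (0=A, 1=B) at each site, from tract tables."""
    pos0 = np.asarray(positions) - 1
    out = np.empty((len(haplotype_ids), pos0.size), dtype=np.int8)
    sub = truth[truth["chrom"].astype(str) == str(chrom)]
    for i, hid in enumerate(haplotype_ids):
        tr = sub[sub["haplotype_id"] == hid].sort_values("start_bp")
        idx = np.searchsorted(tr["start_bp"].to_numpy(), pos0, side="right") - 1
        lab = (tr["ancestry"].to_numpy() == "B").astype(np.int8)
        out[i] = lab[idx]
    return out
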