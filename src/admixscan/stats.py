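"""Windowed diversity and differentiation statistics.

Nucleotide diversity (π), Tajima's D, Weir–Cockerham and Hudson F_ST, the
heterozygosity-based inbreeding coefficient F = 1 − Ho/He, pairwise LD
(D, D′, r²), LD-decay curves, and greedy LD pruning.

Two window presets recur in this pipeline: 50 kb windows with 50 kb steps for
diversity profiles, and 50 kb windows with 20 kb steps for selection scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, HaplotypePanel

DIVERSITY_WINDOW = (50_000, 50_000)
SCAN_WINDOW = (50_000, 20_000)


# ---------------------------------------------------------------------------
# Window grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowGrid:
    """Sliding windows (0-based half-open) over one chromosome."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    window_size: int
    step: int

    @classmethod
    def make(cls, chrom, chrom_len_bp, window_size=50_000, step=None) -> "WindowGrid":
        step = step or window_size
        if step > window_size:
            raise ValueError("step must not exceed window size")
        starts = np.arange(0, max(chrom_len_bp - 1, 1), step, dtype=np.int64)
        ends = np.minimum(starts + window_size, chrom_len_bp)
        keep = starts < chrom_len_bp
        return cls(str(chrom), starts[keep], ends[keep], window_size, step)

    @property
    def n_windows(self) -> int:
        return self.starts.size

    def site_window_matrix(self, positions_bp):
        """For each window, the [lo, hi) slice of site indices it contains.

        Positions are 1-based; a site at position p falls in windows with
        start <= p-1 < end.
        """
        pos0 = np.asarray(positions_bp, dtype=np.int64) - 1
        lo = np.searchsorted(pos0, self.starts, side="left")
        hi = np.searchsorted(pos0, self.ends, side="left")
        return lo, hi

    def to_frame(self, values=None, n_sites=None, name="value") -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "start": self.starts, "end": self.ends})
        if n_sites is not None:
            df["n_sites"] = n_sites
        if values is not None:
            df[name] = values
        return df


@dataclass
class WindowedStat:
    """Per-window statistic values; NaN where a window had < min_sites sites."""

    grid: WindowGrid
    values: np.ndarray
    n_sites: np.ndarray
    name: str

    def to_frame(self) -> pd.DataFrame:
        return self.grid.to_frame(self.values, self.n_sites, self.name)


def _windowed_ratio(grid, positions, per_site_num, per_site_den=None,
                    min_sites=10, name="stat", denom_is_span=False):
    lo, hi = grid.site_window_matrix(positions)
    cnum = np.concatenate([[0.0], np.cumsum(per_site_num)])
    counts = hi - lo
    num = cnum[hi] - cnum[lo]
    if denom_is_span:
        den = (grid.ends - grid.starts).astype(float)
    else:
        cden = np.concatenate([[0.0], np.cumsum(per_site_den)])
        den = cden[hi] - cden[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where((counts >= min_sites) & (den != 0), num / np.where(den == 0, 1, den), np.nan)
    return WindowedStat(grid, vals, counts, name)


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def pi_per_site(panel: HaplotypePanel) -> np.ndarray:
    """Per-site mean pairwise difference 2 j (n−j) / (n (n−1)), missing-aware."""
    j, n = panel.derived_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.0 * j * (n - j) / (n * (n - 1.0))
    out[n < 2] = 0.0
    return out


def pi_windowed(panel: HaplotypePanel, grid: WindowGrid, min_sites=10) -> WindowedStat:
    """Nucleotide diversity per bp in each window (sum of per-site π / window span)."""
    stat = _windowed_ratio(grid, panel.positions, pi_per_site(panel),
                           min_sites=min_sites, name="pi", denom_is_span=True)
    # a window with enough span but no sites is monomorphic, π = 0, unless it
    # fails the site-count floor, in which case it stays missing
    return stat


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalizing constants for sample size n (haplotypes)."""
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(panel: HaplotypePanel, grid: WindowGrid, min_sites=1) -> WindowedStat:
    """Tajima's D per window from S and mean pairwise differences.

    Constants use the panel's haplotype count; windows with S = 0 are missing.
    """
    n = panel.n_haplotypes
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    k = tajima_constants(n)
    j, nn = panel.derived_counts()
    seg = ((j > 0) & (j < nn)).astype(float)
    pi_site = pi_per_site(panel)
    lo, hi = grid.site_window_matrix(panel.positions)
    cseg = np.concatenate([[0.0], np.cumsum(seg)])
    cpi = np.concatenate([[0.0], np.cumsum(pi_site)])
    S = cseg[hi] - cseg[lo]
    pi_hat = cpi[hi] - cpi[lo]
    counts = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        var = k["e1"] * S + k["e2"] * S * (S - 1.0)
        d = (pi_hat - S / k["a1"]) / np.sqrt(var)
    d[(S == 0) | (counts < min_sites) | (var <= 0)] = np.nan
    return WindowedStat(grid, d, counts, "tajimas_d")


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _pop_site_summaries(panel: HaplotypePanel):
    """Per-site diploid count, allele freq and observed het freq from genotypes."""
    g = panel.genotypes()
    ok = g != MISSING
    n_dip = ok.sum(axis=0).astype(float)
    dos = np.where(ok, g, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dos.sum(axis=0) / (2.0 * n_dip)
        h = np.where(ok, g == 1, 0).sum(axis=0) / n_dip
    return n_dip, p, h


def fst_site_components(panel1: HaplotypePanel, panel2: HaplotypePanel,
                        estimator="weir_cockerham"):
    """Per-site (numerator, denominator) of the chosen F_ST estimator."""
    if estimator == "weir_cockerham":
        n1, p1, h1 = _pop_site_summaries(panel1)
        n2, p2, h2 = _pop_site_summaries(panel2)
        r = 2.0
        nbar = (n1 + n2) / r
        with np.errstate(invalid="ignore", divide="ignore"):
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
                               / (nbar - 1.0))
            b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r
                                         - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
            c = hbar / 2.0
        num, den = a, a + b + c
    elif estimator == "hudson":
        j1, m1 = panel1.derived_counts()
        j2, m2 = panel2.derived_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = j1 / m1
            p2 = j2 / m2
            num = ((p1 - p2) ** 2
                   - p1 * (1 - p1) / (m1 - 1.0)
                   - p2 * (1 - p2) / (m2 - 1.0))
            den = p1 * (1 - p2) + p2 * (1 - p1)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    bad = ~np.isfinite(num) | ~np.isfinite(den)
    num = np.where(bad, 0.0, num)
    den = np.where(bad, 0.0, den)
    return num, den


def fst_windowed(panel1, panel2, grid, estimator="weir_cockerham",
                 min_sites=10) -> WindowedStat:
    """Windowed F_ST as a ratio of sums of per-site components.

    Weir & Cockerham (1984) two-population components by default (the
    convention of VCFtools); Hudson's within/between form as a cross-check.
    Values are not clamped: slightly negative W&C values are reported raw.
    """
    if not np.array_equal(panel1.positions, panel2.positions):
        raise ValueError("panels must share the site list")
    num, den = fst_site_components(panel1, panel2, estimator)
    return _windowed_ratio(grid, panel1.positions, num, den,
                           min_sites=min_sites, name=f"fst_{estimator}")


def fst_global(panel1, panel2, estimator="hudson") -> float:
    """Genome-wide ratio-of-sums F_ST over the full site list."""
    num, den = fst_site_components(panel1, panel2, estimator)
    return float(num.sum() / den.sum())


# ---------------------------------------------------------------------------
# Inbreeding F = 1 - Ho/He
# ---------------------------------------------------------------------------

def heterozygosity_F(panel: HaplotypePanel):
    """Per-individual and mean inbreeding coefficient F = 1 − Ho/He.

    He is the expected heterozygosity 2p(1−p) from the population's allele
    frequencies, averaged over polymorphic-capable sites; Ho_i is individual
    i's fraction of heterozygous genotypes over its non-missing sites.
    Negative values indicate excess heterozygosity (typical of admixed and
    outbred indicine populations).
    """
    g = panel.genotypes()
    ok = g != MISSING
    p = panel.allele_freq()
    he_site = 2.0 * p * (1.0 - p)
    he = float(np.nanmean(he_site))
    if not np.isfinite(he) or he == 0:
        return pd.DataFrame({"sample": panel.sample_ids, "Ho": np.nan, "F": np.nan}), np.nan
    ho = np.where(ok, g == 1, 0).sum(axis=1) / np.maximum(ok.sum(axis=1), 1)
    F = 1.0 - ho / he
    df = pd.DataFrame({"sample": panel.sample_ids, "Ho": ho, "F": F})
    return df, float(F.mean())


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_pair(hap_a: np.ndarray, hap_b: np.ndarray):
    """(D, D′, r²) between two phased haplotype columns (0/1, no missing).

    D = p_AB − p_A p_B; D′ = |D| / D_max with the sign-dependent D_max;
    r² = D² / (p_A(1−p_A) p_B(1−p_B)).  D′ = 1 marks complete disequilibrium.
    """
    hap_a = np.asarray(hap_a, dtype=float)
    hap_b = np.asarray(hap_b, dtype=float)
    pa = hap_a.mean()
    pb = hap_b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("both sites must be polymorphic")
    pab = np.mean(hap_a * hap_b)
    D = pab - pa * pb
    if D >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pa * (1 - pa) * pb * (1 - pb))
    return D, dprime, r2


def _r2_block(z, i_slice, j_slice, n):
    """r² between standardized haplotype columns (blocks)."""
    r = z[:, i_slice].T @ z[:, j_slice] / n
    return r * r


def ld_decay_curve(panel: HaplotypePanel, max_dist_bp=500_000,
                   bin_width_bp=10_000) -> pd.DataFrame:
    """Mean haplotype r² binned by pairwise bp distance.

    All polymorphic site pairs within ``max_dist_bp`` contribute; bins with
    no pairs are omitted.
    """
    panel.require_phased("LD decay")
    p = panel.allele_freq()
    poly = (p > 0) & (p < 1)
    pos = panel.positions[poly]
    a = panel.alleles[:, poly].astype(float)
    n = a.shape[0]
    z = (a - a.mean(axis=0)) / a.std(axis=0)
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    m = pos.size
    block = 512
    for i0 in range(0, m, block):
        i1 = min(i0 + block, m)
        jmax = np.searchsorted(pos, pos[i1 - 1] + max_dist_bp, side="right")
        r2 = _r2_block(z, slice(i0, i1), slice(i0, jmax), n)
        d = pos[i0:jmax][None, :] - pos[i0:i1][:, None]
        mask = (d > 0) & (d <= max_dist_bp)
        bins = (d[mask] - 1) // bin_width_bp
        np.add.at(sums, bins, r2[mask])
        np.add.at(counts, bins, 1)
    centers = (np.arange(n_bins) + 0.5) * bin_width_bp
    keep = counts > 0
    return pd.DataFrame({"dist_bp": centers[keep], "mean_r2": sums[keep] / counts[keep],
                         "n_pairs": counts[keep]})


def genotype_r2_matrix(g: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between genotype-dosage columns."""
    g = g.astype(float)
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = np.nan
    z = g / sd
    r = z.T @ z / g.shape[0]
    return np.nan_to_num(r * r)


def ld_prune(panel: HaplotypePanel, window=50, step=5, r2_max=0.2) -> np.ndarray:
    """Greedy LD pruning on genotype dosages (the `--indep-pairwise 50 5 0.2` rule).

    Slide a ``window``-SNP window by ``step`` SNPs; within each window, while
    any retained pair has r² > ``r2_max``, drop the later site of the
    worst (highest-r²) pair.  Returns the retained site indices.
    """
    g = panel.genotypes()
    m = panel.n_sites
    keep = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        idx = np.flatnonzero(keep[start:start + window]) + start
        if idx.size > 1:
            r2 = genotype_r2_matrix(g[:, idx])
            np.fill_diagonal(r2, 0.0)
            active = np.ones(idx.size, dtype=bool)
            while True:
                sub = np.where(np.outer(active, active), r2, 0.0)
                worst = np.unravel_index(np.argmax(sub), sub.shape)
                if sub[worst] <= r2_max:
                    break
                later = max(worst)
                active[later] = False
                keep[idx[later]] = False
        if start + window >= m:
            break
        start += step
    return np.flatnonzero(keep)
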