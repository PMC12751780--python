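"""Synthetic admixed genomes with known ancestry truth.

The generator emulates the target system: two ancestral cattle lineages
(taurine-like "A" and indicine-like "B") diverged to a target F_ST under a
Balding–Nichols model, and an admixed population formed by a single pulse
``admix_generations`` before sampling with indicine mixing fraction
``mix_fraction_B``.  Each admixed haplotype is a tract mosaic: ancestry
switch points form a Poisson process of rate λ per Morgan, each inter-switch
segment is labelled B with probability m, and alleles are copied from a
randomly chosen haplotype of the segment's source panel.  Optional hard
sweeps can be planted at chosen positions.

Allele 0 is ancestral by construction, which removes iHS polarity ambiguity
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import write_vcf
from .panel import HaplotypePanel


@dataclass
class SweepSpec:
    """A planted hard sweep: where, in which population, how far it got.

    ``escape_scale_bp`` is the mean distance at which a carrier haplotype
    recombines off the core haplotype; ``None`` disables escape (carriers are
    full copies of the core).
    """

    chrom: str
    position_bp: int
    source_population: str  # "A", "B" or "admixed"
    final_frequency: float
    escape_scale_bp: float | None = 200_000.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic admixed-population generator.

    Defaults define the reference study conditions: panels of 30 haplotypes, 20
    admixed diploids, 10 chromosomes of 1 Morgan (100 Mb at the cattle-average
    1 cM/Mb), 5,000 SNPs per chromosome, panel divergence F_ST 0.3, a single
    admixture pulse ~39 generations before sampling with near-equal mixing.
    """

    n_anc_A: int = 30              # haplotypes
    n_anc_B: int = 30              # haplotypes
    n_admixed: int = 20            # diploid samples
    n_chrom: int = 10
    chrom_len_bp: int = 100_000_000
    chrom_len_morgans: float = 1.0
    n_snps_per_chrom: int = 5_000
    divergence_fst_target: float = 0.3
    mix_fraction_B: float = 0.5
    admix_generations: float = 38.68
    sweep_specs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.mix_fraction_B < 1.0:
            if self.mix_fraction_B not in (0.0, 1.0):
                raise ValueError("mix_fraction_B must lie in (0,1) (0/1 allowed for edge tests)")
        if self.chrom_len_morgans <= 0:
            raise ValueError("chrom_len_morgans must be positive")
        if self.n_snps_per_chrom < 2:
            raise ValueError("need at least 2 SNPs per chromosome")
        if self.admix_generations <= 0:
            raise ValueError("admix_generations must be positive")

    def chrom_names(self):
        return [str(i + 1) for i in range(self.n_chrom)]


TRUTH_COLUMNS = ["haplotype_id", "chrom", "start_bp", "end_bp", "ancestry"]


def _draw_positions(rng, chrom_len_bp, m):
    """m distinct sorted positions in [1, chrom_len_bp] without materializing the range."""
    if m > chrom_len_bp:
        raise ValueError("more SNPs requested than base pairs")
    pos = np.unique(rng.integers(1, chrom_len_bp + 1, size=int(m * 1.1) + 64))
    while pos.size < m:
        extra = rng.integers(1, chrom_len_bp + 1, size=m)
        pos = np.unique(np.concatenate([pos, extra]))
    if pos.size > m:
        pos = np.sort(rng.choice(pos, size=m, replace=False))
    return pos


# ---------------------------------------------------------------------------
# Ancestral panels
# ---------------------------------------------------------------------------

def simulate_ancestral_panels(config: SimConfig, chrom="1", rng=None):
    """Two ancestral panels over a shared site list at the target divergence.

    Sites are unlinked.  Per site the ancestral derived-allele frequency is
    uniform on (0.05, 0.95); each population's frequency is a Balding–Nichols
    draw Beta(p(1−F)/F, (1−p)(1−F)/F) with F = divergence_fst_target, under
    which the expected Hudson ratio-of-sums F_ST equals F.  Sites monomorphic
    across both panels are redrawn so every retained site is informative.
    """
    F = config.divergence_fst_target
    if not 0.0 <= F <= 0.9:
        raise ValueError("divergence_fst_target must lie in [0, 0.9] "
                         "(higher targets are not achievable under this model)")
    if F > 0 and config.n_snps_per_chrom < 50:
        raise ValueError("need >= 50 SNPs per chromosome to realize a nonzero "
                         "F_ST target within tolerance; achievable range with "
                         f"{config.n_snps_per_chrom} SNPs is only F_ST = 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = config.n_snps_per_chrom
    positions = _draw_positions(rng, config.chrom_len_bp, m)

    nA, nB = config.n_anc_A, config.n_anc_B
    allelesA = np.empty((nA, m), dtype=np.int8)
    allelesB = np.empty((nB, m), dtype=np.int8)
    todo = np.arange(m)
    for _ in range(200):
        k = todo.size
        p_anc = rng.uniform(0.05, 0.95, size=k)
        if F == 0:
            pA = pB = p_anc
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            pA = rng.beta(a, b)
            pB = rng.beta(a, b)
        colA = (rng.random((nA, k)) < pA).astype(np.int8)
        colB = (rng.random((nB, k)) < pB).astype(np.int8)
        allelesA[:, todo] = colA
        allelesB[:, todo] = colB
        tot = colA.sum(axis=0) + colB.sum(axis=0)
        mono = (tot == 0) | (tot == nA + nB)
        todo = todo[mono]
        if todo.size == 0:
            break
    anc = np.zeros(m, dtype=np.int8)
    pa = HaplotypePanel(str(chrom), positions, allelesA,
                        [f"A{i}" for i in range(nA // 2)] if nA % 2 == 0 else [],
                        phased=True, ancestral=anc)
    pb = HaplotypePanel(str(chrom), positions, allelesB,
                        [f"B{i}" for i in range(nB // 2)] if nB % 2 == 0 else [],
                        phased=True, ancestral=anc.copy())
    return pa, pb


# ---------------------------------------------------------------------------
# Single-pulse admixture as a tract mosaic
# ---------------------------------------------------------------------------

def _mosaic_haplotype(panel_a, panel_b, config, rng):
    """One admixed haplotype plus its merged truth tracts (bp, half-open)."""
    L = config.chrom_len_morgans
    lam = config.admix_generations
    m = config.mix_fraction_B
    n_switch = rng.poisson(lam * L)
    cuts = np.sort(rng.uniform(0.0, L, size=n_switch))
    bounds = np.concatenate([[0.0], cuts, [L]])
    labels = (rng.random(bounds.size - 1) < m).astype(np.int8)  # 1 = B

    bp_bounds = np.round(bounds / L * config.chrom_len_bp).astype(np.int64)
    hap = np.empty(panel_a.n_sites, dtype=np.int8)
    pos0 = panel_a.positions - 1
    for k in range(labels.size):
        lo = np.searchsorted(pos0, bp_bounds[k], side="left")
        hi = np.searchsorted(pos0, bp_bounds[k + 1], side="left")
        src = panel_b if labels[k] == 1 else panel_a
        tpl = rng.integers(src.n_haplotypes)
        hap[lo:hi] = src.alleles[tpl, lo:hi]

    # merge consecutive same-label segments into truth tracts
    tracts = []
    run_start = bp_bounds[0]
    for k in range(labels.size):
        if k + 1 < labels.size and labels[k + 1] == labels[k]:
            continue
        end = bp_bounds[k + 1]
        if end > run_start:
            tracts.append((int(run_start), int(end), "B" if labels[k] else "A"))
        run_start = end
    return hap, tracts


def simulate_admixed(panel_a, panel_b, config: SimConfig, rng=None):
    """Admixed diploid panel and its ancestry truth for one chromosome.

    Returns (HaplotypePanel, truth DataFrame with columns
    haplotype_id/chrom/start_bp/end_bp/ancestry; coordinates 0-based
    half-open, tracts tiling [0, chrom_len_bp) per haplotype).
    """
    if not np.array_equal(panel_a.positions, panel_b.positions):
        raise ValueError("ancestral panels must share the site list")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_hap = 2 * config.n_admixed
    alleles = np.empty((n_hap, panel_a.n_sites), dtype=np.int8)
    rows = []
    for h in range(n_hap):
        hap_id = f"AD{h // 2}_{h % 2}"
        hap, tracts = _mosaic_haplotype(panel_a, panel_b, config, rng)
        alleles[h] = hap
        for s, e, lab in tracts:
            rows.append((hap_id, panel_a.chrom, s, e, lab))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    panel = HaplotypePanel(panel_a.chrom, panel_a.positions.copy(), alleles,
                           [f"AD{i}" for i in range(config.n_admixed)],
                           phased=True, ancestral=np.zeros(panel_a.n_sites, dtype=np.int8))
    return panel, truth


# ---------------------------------------------------------------------------
# Planted hard sweeps
# ---------------------------------------------------------------------------

def inject_sweep(panel: HaplotypePanel, sweep: SweepSpec, seed=0) -> HaplotypePanel:
    """Plant a hard sweep: carriers copy one core haplotype around the site.

    The favored (derived) allele is set to frequency ``final_frequency`` at
    the site nearest ``position_bp``.  Each carrier copies the core haplotype
    over an interval whose one-sided extent is exponential with mean
    ``escape_scale_bp``, so haplotype homozygosity is elevated and π reduced
    around the site, decaying with distance.
    """
    if not 0.0 < sweep.final_frequency <= 1.0:
        raise ValueError("final_frequency must lie in (0, 1]")
    if not panel.positions[0] <= sweep.position_bp <= panel.positions[-1]:
        raise ValueError("sweep position outside the chromosome's site range")
    rng = np.random.default_rng(seed)
    alleles = panel.alleles.copy()
    site = int(np.argmin(np.abs(panel.positions - sweep.position_bp)))
    n = panel.n_haplotypes
    n_car = max(1, int(round(sweep.final_frequency * n)))
    carriers = rng.choice(n, size=n_car, replace=False)
    core = carriers[0]
    alleles[:, site] = 0
    alleles[carriers, site] = 1
    pos = panel.positions.astype(float)
    for h in carriers:
        if h == core:
            continue
        if sweep.escape_scale_bp is None:
            lo_bp, hi_bp = -np.inf, np.inf
        else:
            lo_bp = pos[site] - rng.exponential(sweep.escape_scale_bp)
            hi_bp = pos[site] + rng.exponential(sweep.escape_scale_bp)
        mask = (pos >= lo_bp) & (pos <= hi_bp)
        alleles[h, mask] = alleles[core, mask]
    anc = None if panel.ancestral is None else panel.ancestral.copy()
    return HaplotypePanel(panel.chrom, panel.positions.copy(), alleles,
                          list(panel.sample_ids), panel.phased, anc)


# ---------------------------------------------------------------------------
# Whole-study orchestration and truth I/O
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    panels_a: dict       # chrom -> HaplotypePanel
    panels_b: dict
    admixed: dict
    truth: pd.DataFrame  # all chromosomes
    config: SimConfig


def simulate_study(config: SimConfig) -> SimResult:
    """Generate the full multi-chromosome study: panels, admixed genomes, truth."""
    master = np.random.SeedSequence(config.seed)
    panels_a, panels_b, admixed, truths = {}, {}, {}, []
    for chrom, ss in zip(config.chrom_names(), master.spawn(config.n_chrom)):
        rng = np.random.default_rng(ss)
        pa, pb = simulate_ancestral_panels(config, chrom=chrom, rng=rng)
        for i, sw in enumerate(config.sweep_specs):
            if str(sw.chrom) != chrom or sw.source_population == "admixed":
                continue
            tgt = pa if sw.source_population == "A" else pb
            swept = inject_sweep(tgt, sw, seed=int(rng.integers(2**31)))
            if sw.source_population == "A":
                pa = swept
            else:
                pb = swept
        adm, truth = simulate_admixed(pa, pb, config, rng=rng)
        for sw in config.sweep_specs:
            if str(sw.chrom) == chrom and sw.source_population == "admixed":
                adm = inject_sweep(adm, sw, seed=int(rng.integers(2**31)))
        panels_a[chrom], panels_b[chrom], admixed[chrom] = pa, pb, adm
        truths.append(truth)
    return SimResult(panels_a, panels_b, admixed,
                     pd.concat(truths, ignore_index=True), config)


def write_truth(truth: pd.DataFrame, path):
    truth.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def panel_to_vcf(panel, path):
    """Write a panel (or dict of panels) as phased VCF 4.2."""
    write_vcf(panel, path)
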