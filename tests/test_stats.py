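import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixscan.panel import HaplotypePanel
from admixscan.sim import SimConfig, simulate_ancestral_panels, simulate_admixed
from admixscan.stats import (WindowGrid, fst_global, fst_windowed,
                             genotype_r2_matrix, heterozygosity_F, ld_decay_curve,
                             ld_pair, ld_prune, pi_windowed, tajima_constants,
                             tajimas_d)
from tests.conftest import random_panel


# ---------------------------------------------------------------------------
# Independent oracles (direct transcriptions of the textbook formulas)
# ---------------------------------------------------------------------------

def pi_bruteforce(alleles, window_bp):
    """Mean pairwise differences over all haplotype pairs, per bp."""
    n = alleles.shape[0]
    diffs = sum((alleles[i] != alleles[j]).sum()
                for i, j in itertools.combinations(range(n), 2))
    return diffs / (n * (n - 1) / 2) / window_bp


def wc_fst_1984(p1, p2, n1, n2, h1, h2):
    """Weir & Cockerham (1984) a, b, c for one site, two populations."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def tajimas_d_1989(alleles):
    """Tajima (1989) D from first principles on a complete allele matrix."""
    n, m = alleles.shape
    counts = alleles.sum(axis=0)
    S = int(((counts > 0) & (counts < n)).sum())
    if S == 0:
        return np.nan
    k = sum((alleles[i] != alleles[j]).sum()
            for i, j in itertools.combinations(range(n), 2)) / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def ld_prune_oracle(g, window, step, r2_max):
    """Literal application of the greedy windowed removal rule."""
    m = g.shape[1]
    removed = set()
    start = 0
    while True:
        idx = [i for i in range(start, min(start + window, m)) if i not in removed]
        while True:
            worst, worst_pair = r2_max, None
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    x, y = g[:, idx[a]].astype(float), g[:, idx[b]].astype(float)
                    if x.std() == 0 or y.std() == 0:
                        continue
                    r2 = np.corrcoef(x, y)[0, 1] ** 2
                    if r2 > worst:
                        worst, worst_pair = r2, (a, b)
            if worst_pair is None:
                break
            removed.add(idx[worst_pair[1]])
            idx.pop(worst_pair[1])
        if start + window >= m:
            break
        start += step
    return [i for i in range(m) if i not in removed]


# ---------------------------------------------------------------------------
# π
# ---------------------------------------------------------------------------

class TestPi:
    def test_single_site_matches_pairwise_count(self):
        # 4 haplotypes, j=2 in a 10-kb window: 4 of 6 pairs differ
        alleles = np.array([[0], [0], [1], [1]], dtype=np.int8)
        panel = HaplotypePanel("1", np.array([5_000]), alleles)
        grid = WindowGrid.make("1", 10_000, 10_000)
        pi = pi_windowed(panel, grid, min_sites=1)
        assert pi.values[0] == pytest.approx(2 * 2 * 2 / (4 * 3) / 10_000)
        assert pi.values[0] == pytest.approx(pi_bruteforce(alleles, 10_000))

    def test_matches_bruteforce_on_random_panel(self):
        panel = random_panel(1, n_hap=10, n_sites=50, span=40_000)
        grid = WindowGrid.make("1", 40_000, 40_000)
        pi = pi_windowed(panel, grid, min_sites=1)
        assert pi.values[0] == pytest.approx(
            pi_bruteforce(panel.alleles, 40_000), rel=1e-12)

    def test_monomorphic_and_fixed_derived_contribute_zero(self):
        alleles = np.array([[0, 1], [0, 1], [0, 1], [0, 1]], dtype=np.int8)
        panel = HaplotypePanel("1", np.array([10, 20]), alleles)
        grid = WindowGrid.make("1", 100, 100)
        assert pi_windowed(panel, grid, min_sites=1).values[0] == 0.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonnegative_and_permutation_invariant(self, seed):
        panel = random_panel(seed, n_hap=8, n_sites=30, span=20_000)
        grid = WindowGrid.make("1", 20_000, 20_000)
        v1 = pi_windowed(panel, grid, min_sites=1).values
        perm = np.random.default_rng(seed).permutation(8)
        shuffled = HaplotypePanel("1", panel.positions, panel.alleles[perm])
        v2 = pi_windowed(shuffled, grid, min_sites=1).values
        assert np.all(v1 >= 0)
        np.testing.assert_allclose(v1, v2)


class TestTajimasD:
    def test_matches_independent_1989_transcription(self):
        panel = random_panel(2, n_hap=10, n_sites=16, span=50_000)
        grid = WindowGrid.make("1", 50_000, 50_000)
        d = tajimas_d(panel, grid).values[0]
        assert d == pytest.approx(tajimas_d_1989(panel.alleles), abs=1e-9)

    def test_no_segregating_sites_is_missing(self):
        alleles = np.zeros((6, 5), dtype=np.int8)
        panel = HaplotypePanel("1", np.arange(1, 6) * 100, alleles)
        grid = WindowGrid.make("1", 1_000, 1_000)
        assert np.isnan(tajimas_d(panel, grid).values[0])

    def test_all_singletons_negative(self):
        # each variant on its own haplotype: excess of rare alleles
        n, m = 10, 20
        alleles = np.zeros((n, m), dtype=np.int8)
        for s in range(m):
            alleles[s % n, s] = 1
        panel = HaplotypePanel("1", np.arange(1, m + 1) * 100, alleles)
        grid = WindowGrid.make("1", 3_000, 3_000)
        assert tajimas_d(panel, grid).values[0] < 0

    def test_neutral_simulation_mean_near_zero(self):
        from tests.conftest import msprime_panel
        means = []
        for seed in range(1, 6):
            p = msprime_panel(seed, n_hap=20, length=1_000_000)
            grid = WindowGrid.make("1", 1_000_000, 50_000)
            means.append(np.nanmean(tajimas_d(p, grid).values))
        assert -0.5 < np.mean(means) < 0.5


class TestFst:
    def test_wc_matches_independent_oracle(self):
        # p1=0.2, p2=0.8, 10 diploids each, one site
        rng = np.random.default_rng(3)
        def make(p, n=10):
            hap = np.zeros((2 * n, 1), dtype=np.int8)
            hap[:int(round(p * 2 * n)), 0] = 1
            return HaplotypePanel("1", np.array([100]), hap[rng.permutation(2 * n)])
        p1_panel, p2_panel = make(0.2), make(0.8)
        got = fst_windowed(p1_panel, p2_panel,
                           WindowGrid.make("1", 200, 200), "weir_cockerham",
                           min_sites=1).values[0]
        g1, g2 = p1_panel.genotypes()[:, 0], p2_panel.genotypes()[:, 0]
        a, b, c = wc_fst_1984(0.2, 0.8, 10, 10,
                              float((g1 == 1).mean()), float((g2 == 1).mean()))
        assert got == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_fixed_difference_gives_one(self):
        a = HaplotypePanel("1", np.array([10, 20]), np.zeros((8, 2), dtype=np.int8))
        b = HaplotypePanel("1", np.array([10, 20]), np.ones((8, 2), dtype=np.int8))
        grid = WindowGrid.make("1", 100, 100)
        for est in ("weir_cockerham", "hudson"):
            assert fst_windowed(a, b, grid, est, min_sites=1).values[0] == pytest.approx(1.0)

    def test_identical_panels_near_zero_not_clamped(self):
        p = random_panel(4, n_hap=20, n_sites=100, span=50_000)
        grid = WindowGrid.make("1", 50_000, 50_000)
        v = fst_windowed(p, p, grid, "weir_cockerham", min_sites=1).values[0]
        assert v <= 0.0  # identical samples: W&C estimate is (slightly) negative

    def test_hudson_at_most_one_and_permutation_invariant(self):
        a = random_panel(5, n_hap=12, n_sites=80)
        b = random_panel(6, n_hap=12, n_sites=80)
        b = HaplotypePanel("1", a.positions, b.alleles)
        v = fst_global(a, b, "hudson")
        assert v <= 1.0
        perm = np.random.default_rng(0).permutation(12)
        a2 = HaplotypePanel("1", a.positions, a.alleles[perm])
        assert fst_global(a2, b, "hudson") == pytest.approx(v)


class TestInbreedingF:
    def test_reference_points(self):
        # Ho == He -> 0; Ho == 0 -> 1; Ho=0.31, He=0.25 -> -0.24
        assert 1 - 0.25 / 0.25 == 0
        panel = random_panel(7, n_hap=20, n_sites=300)
        df, mean_f = heterozygosity_F(panel)
        he = np.nanmean(2 * panel.allele_freq() * (1 - panel.allele_freq()))
        np.testing.assert_allclose(df["F"], 1 - df["Ho"] / he)
        assert mean_f == pytest.approx(df["F"].mean())

    def test_excess_heterozygosity_is_negative(self):
        # all individuals heterozygous at every site: Ho=1 > He
        alleles = np.tile(np.array([[0], [1]], dtype=np.int8), (5, 20))
        panel = HaplotypePanel("1", np.arange(1, 21) * 10, alleles)
        df, mean_f = heterozygosity_F(panel)
        assert (df["F"] < 0).all() and mean_f < 0
        assert df["F"].iloc[0] == pytest.approx(1 - 1.0 / 0.5)

    def test_fully_homozygous_individual_is_one(self):
        alleles = np.array([[0, 0], [0, 0], [0, 1], [1, 0]], dtype=np.int8)
        panel = HaplotypePanel("1", np.array([5, 9]), alleles)
        df, _ = heterozygosity_F(panel)
        assert df["F"].iloc[0] == pytest.approx(1.0)


class TestLD:
    def test_complete_coupling(self):
        a = np.array([1] * 5 + [0] * 5)
        d, dprime, r2 = ld_pair(a, a)
        assert dprime == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_independence(self):
        a = np.repeat([1, 1, 0, 0], 25)
        b = np.tile([1, 0], 50)
        d, dprime, r2 = ld_pair(a, b)
        assert d == pytest.approx(0.0) and r2 == pytest.approx(0.0)

    def test_intermediate_counts(self):
        # AB=40, Ab=10, aB=10, ab=40
        a = np.array([1] * 50 + [0] * 50)
        b = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        d, dprime, r2 = ld_pair(a, b)
        assert d == pytest.approx(0.15)
        assert r2 == pytest.approx(0.36)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            ld_pair(np.ones(10), np.array([1, 0] * 5))

    def test_decay_curve_identical_haplotypes(self):
        base = random_panel(8, n_hap=2, n_sites=100, span=100_000)
        dup = HaplotypePanel("1", base.positions,
                             np.repeat(base.alleles[:1], 10, axis=0)
                             ^ np.arange(10)[:, None].astype(np.int8) % 2)
        curve = ld_decay_curve(dup, max_dist_bp=100_000, bin_width_bp=10_000)
        np.testing.assert_allclose(curve["mean_r2"], 1.0)

    def test_unlinked_sites_mean_r2_near_finite_sample_floor(self):
        # i.i.d. sites: E[r^2] ~ 1/n_haplotypes
        panel = random_panel(9, n_hap=50, n_sites=400, span=400_000)
        curve = ld_decay_curve(panel, max_dist_bp=200_000, bin_width_bp=50_000)
        assert np.all(np.abs(curve["mean_r2"] - 1 / 50) < 0.01)

    def test_admixture_ld_exceeds_ancestral_ld_at_long_range(self):
        wins = 0
        for seed in range(5):
            cfg = SimConfig(n_chrom=1, n_snps_per_chrom=2_000, seed=seed)
            pa, pb = simulate_ancestral_panels(cfg)
            adm, _ = simulate_admixed(pa, pb, cfg)
            kw = dict(max_dist_bp=1_000_000, bin_width_bp=250_000)
            adm_r2 = ld_decay_curve(adm, **kw)["mean_r2"].iloc[-1]
            anc_r2 = ld_decay_curve(pa, **kw)["mean_r2"].iloc[-1]
            wins += adm_r2 > anc_r2
        assert wins >= 4


class TestLDPrune:
    def test_duplicate_columns_keep_one_per_run(self):
        col = np.array([0, 0, 1, 1, 0, 1, 1, 0, 1, 0], dtype=np.int8)
        alleles = np.tile(col[:, None], (1, 6))
        panel = HaplotypePanel("1", np.arange(1, 7) * 100, alleles)
        kept = ld_prune(panel)
        assert list(kept) == [0]

    def test_low_ld_all_retained(self):
        panel = random_panel(10, n_hap=100, n_sites=30)
        r2 = genotype_r2_matrix(panel.genotypes())
        np.fill_diagonal(r2, 0)
        if r2.max() < 0.2:
            assert len(ld_prune(panel)) == 30

    def test_matches_exhaustive_rule_on_toys(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            base = rng.integers(0, 2, size=(12, 3)).astype(np.int8)
            # duplicate and lightly mutate columns to create LD structure
            cols = [base[:, i % 3].copy() for i in range(8)]
            for i, c in enumerate(cols):
                flip = rng.random(12) < 0.1
                c[flip] = 1 - c[flip]
            alleles = np.column_stack(cols)
            seg = [(alleles[:, i].min() != alleles[:, i].max()) for i in range(8)]
            alleles = alleles[:, np.flatnonzero(seg)]
            panel = HaplotypePanel("1", np.arange(1, alleles.shape[1] + 1) * 50,
                                   alleles)
            got = list(ld_prune(panel, window=4, step=2, r2_max=0.2))
            want = ld_prune_oracle(panel.genotypes(), 4, 2, 0.2)
            assert got == want, f"seed {seed}"


def test_partitioning_grid_covers_every_site():
    panel = random_panel(11, n_hap=8, n_sites=123, span=100_000)
    grid = WindowGrid.make("1", 100_000, 10_000, 10_000)
    pi = pi_windowed(panel, grid, min_sites=1)
    assert pi.n_sites.sum() == panel.n_sites
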