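import numpy as np
import pytest

from admixscan.panel import HaplotypePanel


@pytest.fixture
def tiny_panel():
    """4 haplotypes (2 samples), 3 sites, fully phased, ancestral = 0."""
    alleles = np.array([
        [0, 1, 0],
        [1, 1, 0],
        [0, 0, 0],
        [1, 0, 1],
    ], dtype=np.int8)
    return HaplotypePanel("1", np.array([100, 5_000, 9_000]), alleles,
                          ["s1", "s2"], ancestral=np.zeros(3, dtype=np.int8))


def random_panel(seed, n_hap=20, n_sites=200, chrom="1", span=1_000_000):
    """Unstructured random panel with segregating sites."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, span), size=n_sites, replace=False))
    p = rng.uniform(0.1, 0.9, size=n_sites)
    alleles = (rng.random((n_hap, n_sites)) < p).astype(np.int8)
    # ensure every site segregates
    mono = (alleles.sum(axis=0) == 0) | (alleles.sum(axis=0) == n_hap)
    alleles[0, mono] = 1 - alleles[0, mono]
    return HaplotypePanel(chrom, pos, alleles,
                          ancestral=np.zeros(n_sites, dtype=np.int8))


def msprime_panel(seed, n_hap=40, length=2_000_000, ne=10_000,
                  mu=1e-8, rho=1e-8):
    """Neutral constant-size coalescent panel (independent simulation oracle)."""
    import msprime

    ts = msprime.sim_ancestry(samples=n_hap // 2, population_size=ne,
                              sequence_length=length, recombination_rate=rho,
                              random_seed=seed)
    ts = msprime.sim_mutations(ts, rate=mu, random_seed=seed + 10_000,
                               model=msprime.BinaryMutationModel())
    gm = ts.genotype_matrix()
    pos = ts.sites_position.astype(np.int64) + 1
    keep = gm.max(axis=1) <= 1
    gm, pos = gm[keep], pos[keep]
    _, idx = np.unique(pos, return_index=True)
    gm, pos = gm[idx], pos[idx]
    return HaplotypePanel("1", pos, gm.T.astype(np.int8),
                          ancestral=np.zeros(pos.size, dtype=np.int8))
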