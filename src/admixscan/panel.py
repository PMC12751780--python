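"""Phased haplotype panels: the substrate for every statistic in the package.

A :class:`HaplotypePanel` holds the alleles of ``N`` haplotypes at ``M``
ordered biallelic SNPs on a single chromosome.  Allele values are ``0``
(reference / ancestral in simulation), ``1`` (alternate / derived) and ``-1``
(missing).  Haplotypes ``2*i`` and ``2*i + 1`` belong to sample ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class HaplotypePanel:
    """Phased biallelic alleles for N haplotypes at M sites on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    positions : ndarray of int
        1-based physical positions, strictly increasing, one per site.
    alleles : ndarray of shape (n_haplotypes, n_sites)
        Values in {0, 1, -1}; -1 marks a missing allele.
    sample_ids : list of str
        One id per diploid sample; ``len(sample_ids) * 2 == n_haplotypes``.
    phased : bool
        False when built from unphased genotypes; haplotype-based scans
        (EHH, iHS, XP-EHH, ancestry copying) refuse unphased panels.
    ancestral : ndarray or None
        Per-site ancestral allele in {0, 1}, -1 unknown.  The simulator
        always sets this to 0.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    sample_ids: list = field(default_factory=list)
    phased: bool = True
    ancestral: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (haplotypes x sites) array")
        if self.positions.shape[0] != self.alleles.shape[1]:
            raise ValueError("positions and alleles disagree on site count")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.sample_ids and 2 * len(self.sample_ids) != self.alleles.shape[0]:
            raise ValueError("need exactly two haplotypes per sample")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.alleles.shape[0] // 2)]
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele values must be 0, 1 or -1")
        if self.ancestral is not None:
            self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
            if self.ancestral.shape[0] != self.n_sites:
                raise ValueError("ancestral allele vector length mismatch")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def require_phased(self, what: str = "this operation"):
        if not self.phased:
            raise ValueError(f"{what} requires a phased panel")

    def genotypes(self) -> np.ndarray:
        """Diploid dosage matrix (n_samples, n_sites); -1 where any allele missing."""
        a = self.alleles[0::2]
        b = self.alleles[1::2]
        g = (a + b).astype(np.int8)
        g[(a == MISSING) | (b == MISSING)] = MISSING
        return g

    def derived_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (count of allele 1, count of non-missing alleles)."""
        ok = self.alleles != MISSING
        j = np.where(ok, self.alleles, 0).sum(axis=0)
        n = ok.sum(axis=0)
        return j.astype(np.int64), n.astype(np.int64)

    def allele_freq(self) -> np.ndarray:
        """Per-site alternate-allele frequency over non-missing alleles (NaN if all missing)."""
        j, n = self.derived_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, j / np.maximum(n, 1), np.nan)

    def take_sites(self, idx) -> "HaplotypePanel":
        anc = None if self.ancestral is None else self.ancestral[idx]
        return HaplotypePanel(self.chrom, self.positions[idx], self.alleles[:, idx],
                              list(self.sample_ids), self.phased, anc)

    def take_samples(self, sample_idx) -> "HaplotypePanel":
        sample_idx = np.asarray(sample_idx)
        hap_idx = np.empty(2 * sample_idx.size, dtype=np.int64)
        hap_idx[0::2] = 2 * sample_idx
        hap_idx[1::2] = 2 * sample_idx + 1
        ids = [self.sample_ids[i] for i in sample_idx]
        anc = None if self.ancestral is None else self.ancestral.copy()
        return HaplotypePanel(self.chrom, self.positions.copy(),
                              self.alleles[hap_idx], ids, self.phased, anc)

    def select_samples(self, names) -> "HaplotypePanel":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in panel: {missing}")
        return self.take_samples([lookup[n] for n in names])


def concat_panels(panels) -> dict:
    """Group a list of single-chromosome panels by chromosome name."""
    out = {}
    for p in panels:
        if p.chrom in out:
            raise ValueError(f"duplicate chromosome {p.chrom}")
        out[p.chrom] = p
    return out
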