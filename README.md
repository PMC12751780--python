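# admixscan

Population-genomic analysis of admixed genomes: selection scans, local
ancestry, and admixture dating, with a synthetic-data generator that provides
ground truth for every stage.

The package targets the analysis design used for admixed livestock such as
hybrid taurine × indicine cattle: a population formed by a recent single
admixture pulse between two diverged lineages, in which one wants to

- quantify diversity and inbreeding (windowed π, Tajima's D, LD decay,
  PLINK-style runs of homozygosity and F_ROH, F = 1 − Ho/He),
- date the admixture pulse from the exponential decay of weighted ancestry
  disequilibrium, A·e^(−λd) + c over genetic distance d, with a
  leave-one-chromosome-out jackknife SE on λ,
- assign local ancestry along each haplotype by a bagged haplotype-copying
  dynamic program over two reference panels, and flag windows with excess
  ancestry (frequency ≥ 0.7 and one-sided Z-test P < 0.01),
- scan for sweeps with the composite likelihood ratio (CLR) against the
  genome-wide background SFS, windowed θπ, iHS, XP-EHH and windowed F_ST,
  and call candidate regions where at least two of {CLR, θπ, iHS} fall in
  the genome-wide top 1%,
- intersect candidate windows with gene annotation (BED/GFF3), validate with
  Akey's di statistic, and assign each candidate gene's ancestral origin
  from the retained excess-ancestry segments.

All statistics operate on phased biallelic-SNP VCFs plus a sample→population
map; coordinates are handled as 0-based half-open internally and 1-based in
all standard formats.

## Worked example

Simulate the default study — reference panels of 30 haplotypes at
F_ST ≈ 0.3, 20 admixed diploids formed by a single pulse 38.68 generations
ago with equal mixing, 10 chromosomes of 1 Morgan (100 Mb at 1 cM/Mb) with
5,000 SNPs each — then re-date the pulse and re-infer genome-wide ancestry:

```python
from admixscan import (SimConfig, simulate_study, weighted_ld_curve,
                       fit_single_pulse, generations_to_years,
                       infer_ancestry, global_ancestry)

cfg = SimConfig(seed=1)
res = simulate_study(cfg)

ref_a = {c: p.allele_freq() for c, p in res.panels_a.items()}
ref_b = {c: p.allele_freq() for c, p in res.panels_b.items()}
fit = fit_single_pulse(weighted_ld_curve(res.admixed, ref_a, ref_b))
years, years_se = generations_to_years(fit.lam, fit.se_lam, 5)
print(f"admixture time: {fit.lam:.2f} +/- {fit.se_lam:.2f} generations")
print(f"             = {years:.1f} +/- {years_se:.1f} years (5-year generations)")

labels_by, pos_by = {}, {}
for c, adm in res.admixed.items():
    labels, _ = infer_ancestry(adm, res.panels_a[c], res.panels_b[c], seed=1)
    labels_by[c], pos_by[c] = labels, adm.positions
_, mean_b = global_ancestry(labels_by, pos_by, cfg.chrom_len_bp)
print(f"indicine-like ancestry: {100 * mean_b:.2f}%  (simulated truth: 50%)")
```

prints

```
admixture time: 37.43 +/- 2.49 generations
             = 187.2 +/- 12.4 years (5-year generations)
indicine-like ancestry: 50.68%  (simulated truth: 50%)
```

The fitted λ is the pulse age in generations (truth here: 38.68); the
jackknife SE reflects between-chromosome variation of the decay curve; the
ancestry percentage is the span-weighted fraction of haplotype length
assigned to the indicine-like panel.

A command-line interface mirrors the library: `admixscan simulate`, `filter`,
`stats`, `roh`, `scan-haplo`, `scan-clr`, `ancestry`, `date`, `integrate`
(see `admixscan --help`).

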