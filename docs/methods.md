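# Methods

This note documents the models implemented in admixscan, the defaults and
the reasoning behind them, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Synthetic data generator (`admixscan.sim`)

**Ancestral panels.** Two panels over a shared site list are drawn under a
Balding–Nichols model: per site an ancestral derived-allele frequency
p ~ Uniform(0.05, 0.95), then each population's frequency is an independent
Beta(p(1−F)/F, (1−p)(1−F)/F) draw with F equal to the divergence target.
Under this model the expected Hudson ratio-of-sums F_ST equals F, so the
realized genome-wide value lands within ±0.05 of the target for a few
thousand SNPs. Targets above 0.9 are rejected (the Beta variance cannot
realize them under uniform ancestral frequencies), as are nonzero targets
with fewer than 50 SNPs. Sites monomorphic across both panels are redrawn.
Allele 0 is ancestral by construction and written to INFO/AA, which removes
iHS polarity ambiguity in tests. Default divergence target 0.3 — a
calibration choice in the taurine/indicine range, not an estimate.

**Admixture.** Each admixed haplotype is a tract mosaic: switch points form
a Poisson process of rate λ per Morgan (λ = admixture generations, default
38.68), each inter-switch segment is labelled "B" with probability m
(default 0.5), and each segment copies a uniformly chosen haplotype of its
source panel (templates are redrawn per Poisson segment, so within-ancestry
haplotype diversity is preserved; truth tracts are the merged same-label
runs). This gives ancestry covariance m(1−m)e^(−λd) exactly — the
single-pulse decay the dating module fits — and exponential merged-tract
lengths with mean 1/(λ(1−m)) Morgans for ancestry B. The genetic map is
uniform 1 cM/Mb (cattle genome-wide average; chromosome default 100 Mb = 1
Morgan); any map supplied through `GeneticMap` overrides it.

**Planted sweeps.** A hard sweep at a chosen site sets the derived allele to
`final_frequency` (default study value for recovery tests: 0.8 so both
allele classes exist; 1.0 for a fixed sweep) and replaces each carrier's
flanking sequence with a copy of one core haplotype out to an exponential
one-sided distance with mean `escape_scale_bp` (default 200 kb; None
disables escape). This produces the elevated EHH and reduced π of a recent
sweep with a footprint of roughly the escape scale.

**What the generator does not emulate:** within-panel linkage
disequilibrium (ancestral sites are unlinked), post-admixture mutation,
genotyping error, missing data and phasing error. Consequences: background
LD in the admixed population is purely admixture LD (the affine constant c
of the dating fit is ≈ 0, easier than real data); and because admixed
haplotypes are literal copies of panel haplotypes, local-ancestry accuracy
against the same panels is template-level (≈ 99%) — the held-out-reference
setting in the tests shows the harder population-level regime. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not their field performance on noisy data.

## Diversity and differentiation (`admixscan.stats`)

Windows are 0-based half-open, clipped at the chromosome end; two presets
recur: 50 kb/50 kb (diversity profiles) and 50 kb/20 kb (selection scans).
Windows with fewer than `min_sites` SNPs (default 10) are reported missing —
sparse windows are dominated by sampling noise. π uses per-site
2j(n−j)/(n(n−1)) with site-wise non-missing allele counts, divided by the
window span. Tajima's D follows the 1989 constants computed from the panel's
haplotype count; windows with S = 0 are missing. F_ST is a ratio of sums of
per-site components: Weir & Cockerham (1984) two-population components from
genotypes (the convention of the standard VCF tools; values are not clamped,
so slightly negative estimates are reported raw), with Hudson's
within/between form as a cross-check. F = 1 − Ho/He uses the population's
mean expected heterozygosity 2p(1−p) as He and each individual's
heterozygous fraction as Ho; negative values indicate excess heterozygosity,
the signature of recent admixture. LD pruning is the greedy
`--indep-pairwise 50 5 0.2` rule on genotype-dosage r²: within each 50-SNP
window, while any retained pair exceeds r² = 0.2, the later site of the
worst pair is dropped; the window advances by 5 SNPs.

## Runs of homozygosity (`admixscan.roh`)

The PLINK `--homozyg` scheme: 50-SNP windows are eligible with ≤ 3
heterozygous and ≤ 5 missing calls; a SNP joins a candidate run when ≥ 5% of
the windows covering it are eligible; runs split at heterozygous calls and at
gaps > 1 Mb; segments are kept at ≥ 500 kb, ≥ 50 SNPs and ≤ 50 kb/SNP. The
window criteria (50 SNPs, 3 heterozygotes, 5 missing, density 50) are the
classic reporting convention for admixed cattle; the remaining thresholds
are the PLINK defaults and are echoed in output headers.
Length bins are left-closed: [0.5,1), [1,2), [2,4), [4,∞) Mb. F_ROH is the
summed segment length over the autosome length.

## Haplotype scans (`admixscan.haplo`)

EHH from a core site is the probability that two haplotypes of an allele
class are identical out to an offset; it is computed by refining haplotype
groups outward. iHH integrates EHH over genetic distance (trapezoid) on both
sides, stopping when EHH < 0.05; if an inter-SNP gap exceeds 200 kb the core
site is skipped. When the chromosome ends before EHH reaches the cutoff the
partial integral is used (truncation-tolerant, which keeps desk-scale
chromosomes usable; the convention is uniform across sites and both allele
classes, so the log-ratio is not systematically biased). iHS is
ln(iHH_ancestral/iHH_derived) standardized to mean 0, SD 1 within 50
equal-occupancy derived-frequency bins (fewer when few sites are scored);
sites with DAF outside [0.05, 0.95] are excluded. These are the selscan /
Voight conventions. XP-EHH
pools all haplotypes per population, uses the same truncation and gap rules,
and is standardized genome-wide rather than per chromosome (a design choice:
one null distribution for one genome-wide ranking; logged in outputs). Window
summaries: fraction of sites with |iHS| > 2 (iHS) or the window maximum
(XP-EHH). Site→window aggregation has no single field convention, so the
rules are declared here and in output metadata.

## CLR scan (`admixscan.clr`)

The background SFS is the genome-wide empirical spectrum with 0.5
pseudo-counts, folded when ancestral alleles are unknown. At a grid point
(one per 50-kb non-overlapping window) and sweep strength α, each of the n
lineages at a site at distance d escapes independently with
p_e = 1 − exp(−αd); the k escapees retain a hypergeometric draw of the
original derived count, and the n−k swept lineages share one Bernoulli(j/n)
allele; the count distribution is renormalized over polymorphic classes.
At p_e = 1 this recovers the background exactly, so the null is nested and
CLR = 2·max(0, max_α Σ log-ratio) ≥ 0 by construction. α runs over 20
log-spaced values spanning escape half-distances of 1 kb–1 Mb. The scan
evaluates p_e on a 1/1000-step quantized grid (log-likelihood error
negligible against empirical top-1% thresholds); exact evaluation is
available for spot checks. Scores are converted to candidate calls by
genome-wide empirical rank quantiles, recorded in output metadata.

## Local ancestry (`admixscan.ancestry`)

The copying DP minimizes per-site allele mismatches plus a constant penalty
per template switch, over all reference haplotypes of both panels; ties
break toward no-switch, then the lowest template index. Bagging re-runs the
DP for penalties {1.5, 2, 3, 5} × 5 random 80% subsets of each panel and
takes a per-site majority vote (ties to ancestry A); sites with winning vote
fraction < 0.6 are flagged low-confidence and excluded from segment building
but kept in frequency tables. Label runs become segments with
midpoint-to-midpoint spans (so a ≥ 1,000 bp rule is well defined between
sparse SNPs; the first/last spans extend to the chromosome ends); runs
shorter than 1 kb are discarded from segment lists only. The excess-ancestry
test uses the genome-wide empirical mean and SD of per-window ancestry
frequencies as the empirical null — conservative relative to a binomial
null when windows are correlated, and flagged in outputs: a window is retained
iff frequency ≥ 0.7 and one-sided P < 0.01. Global ancestry is the
span-weighted fraction of haplotype length per label; the two fractions sum
to 1. No genetic-map-calibrated HMM is attempted — the copying DP with a
constant switch penalty is the model.

## Admixture dating (`admixscan.ald`)

For SNP pairs (x, y) in the admixed population the statistic is the
genotype-dosage covariance D̂_xy multiplied by the weight
(p_A,x − p_B,x)(p_A,y − p_B,y) from the reference panels, averaged in 0.1-cM
distance bins out to 30 cM (bins with < 100 pairs dropped). Dosage
covariance (not haplotype D) keeps unphased admixed data usable and matches
the weighted-LD construction of admixture-dating practice. The single-pulse
model A·e^(−λd) + c is fit by bounded nonlinear least squares (λ ∈ (0,
1000]), initialized from a log-linear regression of the tail-detrended
curve; bins below 0.5 cM are excluded so short-range background LD cannot
contaminate the fit. The fit is flagged non-significant when the amplitude
is under twice the residual SD (the no-admixture case). The SE of λ is the
standard delete-one-chromosome jackknife over per-chromosome bin sums.
Years = λ × generation interval (default 5 years for cattle), and the SE
scales identically. Fit range and bin width are declared defaults and are
carried in the fit metadata.

## Candidate integration (`admixscan.integrate`)

Empirical tails are genome-wide (not per chromosome), ties at the threshold
included, missing windows excluded from numerator and denominator. Consensus
sweep windows require ≥ 2 of {CLR upper 1%, θπ lower 1%, iHS summary upper
1%} on the shared 50/20 grid; CLR grid points are attributed to every
sliding window containing them (window value = max over contained points).
Cross-population candidates are the intersection of the F_ST and XP-EHH
upper 1% sets. di is the sum over comparison populations of the per-site
z-scored pairwise F_ST (genome-wide mean/SD per pair; zero-variance pairs
dropped with a warning) — Akey's definition, labelled as such in outputs.
Gene overlap is
positional (strand ignored, ≥ 1 bp counts); a gene's origin is the label of
the retained excess-ancestry segments it overlaps ("mixed" when both,
"none" when none) — origin requires the retained flag, not mere majority
ancestry, mirroring the use of high-frequency segments.

## Problem sizes and numerical conventions

The default study configuration (and the scale used throughout the test
suite and the reproduction script) is 10 chromosomes × 1 Morgan × 5,000
SNPs, panels of 30 haplotypes, 20 admixed diploids, five seeds per
stochastic claim — large enough that dating recovers λ within a few percent
and ancestry within half a percentage point, small enough to run on a
laptop core in minutes. Degenerate inputs are handled explicitly: windows
with no data are missing (NaN), never zero; zero-variance standardizations
(excess test, di, XP-EHH) return no calls with a warning rather than ±∞;
monomorphic chromosomes make the CLR background undefined and raise.
Determinism: every stochastic routine takes a seed or Generator; fixed
seeds give byte-identical outputs.

## Known limitations

Single-pulse dating only (no multi-pulse or continuous migration, no
pre-test for LD shared between the reference panels); no
background-selection correction in the CLR; no phasing-error model anywhere
(haplotype scans refuse unphased panels rather than repair them); the
excess-ancestry Z-test treats windows as exchangeable, which overstates
significance when ancestry frequencies are strongly autocorrelated along
the genome.
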