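# Methods

## Scope and model

The package implements a three-group selection scan on biallelic SNP
genotypes. All statistics operate on allele counts `(a, n)` per SNP per
group of samples, where `a` counts copies of the counted allele among `n`
successfully genotyped chromosomes (`n = 2 ×` non-missing diploids). The
counted allele per SNP is the lexicographically smaller observed allele;
every downstream statistic (F_ST, LSBL, H_E, A_R) is invariant to this
orientation, and frequency reports state which allele is counted.

### F_ST

Differentiation is estimated with the Hudson-type unbiased estimator
computed from allele counts:

    h_i = a_i(n_i − a_i) / (n_i(n_i − 1))
    N   = (a_1/n_1 − a_2/n_2)² − h_1/n_1 − h_2/n_2
    D   = N + h_1 + h_2,     F_ST = N/D

`h_i` estimates within-group heterozygosity without bias and the
`h_i/n_i` subtraction removes the sampling variance of the frequency
difference, so `N` and `D` are separately unbiased. Conventions: the
estimator is undefined when either group has fewer than 2 chromosomes
(the SNP is dropped from that scan's denominator, not imputed); `D = 0`
(both groups fixed for the same allele) is reported as 0; negative
per-SNP values, which have no biological interpretation, are clipped to 0
for reporting, while the raw value is kept available. Genome-wide F_ST
averages `N` and `D` separately (ratio of sums): under a two-population
Balding–Nichols model with drift F in each population its expectation is
F, which is what the calibration suite verifies at 20% relative
tolerance. The per-SNP mean of clipped ratios is biased slightly below F
(Jensen plus clipping), which is why calibration uses the ratio-of-sums
form.

### LSBL

For a focal group f and contrasts 1, 2 with clipped pairwise values
`d_f1, d_f2, d_12`:

    LSBL(f) = (d_f1 + d_f2 − d_12) / 2

LSBL is not clipped: negative values occur and simply never reach the
upper tail. Two exact identities hold per SNP and are asserted in tests:
branch additivity (`LSBL(f) + LSBL(c1)` with a shared third group equals
`d_f1`) and invariance under swapping the two contrast groups.

### Outlier calling

Outliers are the top `top_fraction` (default 0.005) of the empirical
LSBL distribution among valid SNPs: records sorted by descending LSBL
with ties broken by (chrom, pos) ascending, and exactly
`floor(top_fraction × N_valid)` calls returned together with the cutoff.
Floor semantics reproduce the printed behaviour of array-scale scans
(41,495 valid SNPs → 207 calls at 0.5%). The threshold is recomputed per
scan, including after panel merging.

### Candidate regions and enrichment

Each outlier SNP is extended by ±`flank` bp (default 50,000), clamped at
position 1. Genes intersecting a window by ≥1 bp are candidates (the lax
rule; configurable by supplying different annotations rather than a
containment switch). Coordinates are normalized internally to 0-based
half-open (BED native; GFF3 converted). Enrichment per term uses the
hypergeometric upper tail `P(X ≥ k)` with the term intersected with the
universe first; the universe defaults to all genes in the supplied
annotation. Terms with `k = 0` report `p = 1` and stay in the output so
the Bonferroni factor (number of tested terms) is transparent.

## Supporting statistics

- **H_E**: `2p̂(1−p̂)·n/(n−1)` (unbiased small-sample correction, the form
  genotype-QC tools report).
- **P_N**: fraction of SNPs with `0 < a < n` in the population — any
  segregation counts; no MAF floor is applied because none is standard.
- **Rarefaction allelic richness** `A_R(g)`:
  `Σ_j [1 − C(n−a_j, g)/C(n, g)]` over the two allele counts, computed
  with log-gamma ratios; `C(m, g) = 0` for `m < g`. The standardized size
  `g` (chromosomes) is a required user parameter since it depends on the
  smallest population one wants to compare.
- **LD r²**: squared Pearson correlation of unphased dosage vectors over
  pairwise-complete samples (composite/genotypic r² — appropriate for
  unphased array data). Zero-variance pairs are undefined and
  prune-ineligible.
- **LD pruning**: sliding windows of `window_snps = 50` advancing by
  `step_snps = 5` (the common array-QC idiom; both configurable). Within
  a window the worst offending pair ≥ `r2_max` loses its lower-MAF SNP
  (tie: the later map position), until all retained pairs are below the
  threshold. The procedure is deterministic and idempotent.
- **Allele sharing**: `d(x,y) = 1 − (IBS2 + 0.5·IBS1)/M` over the `M`
  SNPs genotyped in both samples — equivalently `mean(|x−y|)/2` on
  dosages.
- **Neighbor joining**: Saitou–Nei with the Q-criterion; ties break to
  the smallest (i, j) pair in input order, and only the upper triangle is
  searched since Q is symmetric up to rounding. Negative branch estimates
  are clamped to 0 with the deficit moved to the sister branch
  (PHYLIP-compatible); the final three nodes form a trifurcation, so the
  tree is unrooted. On additive matrices the generating tree is recovered
  exactly (verified against an independent implementation).

## Synthetic data

The simulator emulates a mid-density SNP array over structured
populations. Ancestral frequencies are Uniform(0.05, 0.95) — an
ascertained-array spectrum in which most SNPs survive a MAF filter. Each
population draws `p_i ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` (Balding–Nichols;
`E[p_i] = p`, `Var = F p(1−p)`), with `F = 0` as the exact no-drift
limit. Genotypes are `Binomial(2, p_i)` per individual (HWE within
populations, verified by aggregated chi-square goodness of fit), and
calls are masked missing independently at rate 0.02 (within the 1–5%
range typical of array data). Randomness flows from one integer seed
through numpy's PCG64 generator; identical configs give byte-identical
PED output.

**Selection** is a post-hoc frequency shift, not a forward sweep: at each
planted locus the ancestrally minor allele gains `δ` in the focal
population (frequencies clamped to [0, 1]; `δ = 1` fixes the selected
allele). Directing the shift toward the ancestrally rarer allele pushes
the focal frequency away from where the unselected populations
concentrate, which is the focal-branch signature the scan detects — an
undirected shift frequently lands back inside the contrast groups' range
and models no detectable selection. An absolute target frequency is
available as an alternative.

**Canonical study design** (`scan_study_config`): 10,000 SNPs; one focal
population of 20 diploids, two sister populations of 15 forming contrast
group 1, and ten reference breeds of 10 forming contrast group 2, every
population drifting independently at F = 0.1 — pooled contrast groups
mirror real multi-breed reference panels and keep the neutral LSBL tail
realistic (a single population carrying the whole contrast group's drift
inflates it). Default planted effect is 20 loci at δ = 0.7, a strong
sweep taking typical ancestral minor frequencies near fixation; measured
pooled recovery at the 0.5% threshold is ~90% over 20 replicate panels
(δ = 0.5 sits at the neutral tail's edge and recovers only ~half).

What the simulator does **not** model: linkage between loci (every SNP is
independent, so LD pruning on simulated panels is nearly a no-op and
hitchhiking-based signals are absent), admixture or migration,
ascertainment toward any particular population, genotyping error beyond
missingness, and sex chromosomes. Passing tests therefore demonstrate
correctness of the statistics and the calling machinery under drift plus
single-locus frequency shifts — not power on realistically linked or
admixed data.

## Numerical and interface choices

- Missing genotypes use a single sentinel (−1) internally and `0 0` in
  PED; dosage 0 is never conflated with missing.
- QC thresholds: call rate and MAF filters are strict inequalities
  (matching "> 95%", "> 0.05" conventions); the common-SNP subset filter
  (`subset_by_maf`) exposes an inclusive flag for the "≥" dialect.
- MAF is computed over all non-missing chromosomes of the whole panel.
- PED round-trips are exact on (samples, SNPs, dosage) whenever the
  counted allele is observed at a SNP; a SNP monomorphic for the other
  allele re-reads with complementary orientation, which is a limitation
  of the format (no allele order stored), not of the statistics.
- Map positions are 1-based (MAP convention) and converted to half-open
  0-based only inside annotation; candidate regions are reported 1-based
  closed.
- The CLI never overwrites outputs without `--force`, logs stage counts
  (input SNPs, post-QC, N_valid), and stamps every metadata sidecar with
  a hash of the resolved parameters and the seed.

## Problem sizes

The validation suite runs array-scale where the behaviour depends on it
(a 41,495-SNP scan for the exact outlier-count rule; 41,495 + 49 panel
merge) and 5,000–10,000 SNPs elsewhere (drift calibration, recovery over
20 replicate panels), sizes at which every quantity is stable to well
within the asserted tolerances while the whole suite and the acceptance
script each finish in well under a minute.
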