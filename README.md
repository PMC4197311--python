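# lsblscan

Selection scans for local adaptation on biallelic SNP-array panels, built
around the three-group **locus-specific branch length (LSBL)** statistic.
The package targets population geneticists analysing structured panels of
diploid genotypes — for example highland livestock populations contrasted
with their lowland relatives — who want to nominate loci whose allele
frequencies have diverged specifically in one focal group.

## The statistic

Differentiation between two groups is measured per SNP with the
Hudson-type unbiased F_ST estimator from allele counts `(a_i, n_i)`
(`a_i` copies of allele A among `n_i` genotyped chromosomes):

```
h_i  = a_i (n_i − a_i) / (n_i (n_i − 1))
N    = (a_1/n_1 − a_2/n_2)² − h_1/n_1 − h_2/n_2
D    = N + h_1 + h_2
F_ST = N / D          (negative values clipped to 0)
```

Given a focal group and two contrast groups, the three pairwise values
`d_f1`, `d_f2`, `d_12` decompose into the focal group's own branch:

```
LSBL(focal) = (d_f1 + d_f2 − d_12) / 2
```

A large focal branch marks allele-frequency change specific to the focal
group. Candidate loci are the top 0.5% of the empirical LSBL distribution
(no parametric null); each outlier is extended ±50 kb into a candidate
region, overlapping genes are collected, and user-supplied gene sets
(GMT) are tested by the hypergeometric upper tail with Bonferroni
correction.

Supporting machinery: PLINK text PED/MAP I/O, call-rate/MAF QC filters,
panel merging, per-population diversity (H_E, P_N, rarefaction allelic
richness), composite-r² LD pruning, IBS allele-sharing distances with
Saitou–Nei neighbor joining, and a Balding–Nichols simulator that plants
selective sweeps with known truth for end-to-end validation.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
panel: 150 individuals in 13 populations (one highland focal population
carrying 20 planted sweeps, two sister highland populations, ten lowland
reference breeds), 10,000 unlinked SNPs, 2% missing calls.

```
$ python analysis/01_simulate_panel.py
study panel: 150 samples x 10000 SNPs (2.0% missing), 20 planted sweeps; ...

$ python analysis/03_lsbl_scan.py
scan: 10000 valid SNPs, 50 outliers at the top 0.5% (LSBL cutoff 0.389)
planted-sweep recovery: 18/20 (90%) of selected loci called
null panel: 50 outliers called by construction (cutoff 0.370); planted overlap 0
```

The scan keeps exactly `floor(0.005 × N_valid)` SNPs (here 50 of 10,000);
18 of the 20 planted sweeps rank above the empirical cutoff, while the
matching all-neutral panel yields only tail noise with zero overlap with
any planted set. `analysis/02_diversity_and_tree.py` adds per-population
diversity and an NJ tree in which all 13 simulated populations form their
own subtree; `04` maps outliers to a synthetic gene annotation and finds
the sweep-neighborhood gene set enriched (`p_cor ≈ 3e-56`) while random
sets are not; `05` merges a 49-SNP follow-up panel into the array panel
and re-scans with a recomputed threshold.

The same operations are available as subcommands of the `lsblscan`
console script (`simulate`, `filter`, `scan`, `diversity`, `tree`,
`annotate`), each writing TSV outputs with a JSON metadata sidecar.

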