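"""Per-SNP and per-population statistics on allele counts.

The central estimator is the Hudson-type unbiased F_ST of Reich et al.
(2009), computed from allele counts (a, n) per population, where ``a``
counts copies of allele A among ``n`` successfully genotyped chromosomes:

    h_i = a_i (n_i - a_i) / (n_i (n_i - 1))
    N   = (a_1/n_1 - a_2/n_2)^2 - h_1/n_1 - h_2/n_2
    D   = N + h_1 + h_2
    F_ST = N / D

``h_i`` is the unbiased within-population heterozygosity term; subtracting
``h_i/n_i`` removes the sampling variance of the frequency difference, so
the estimator is unbiased in N and D separately. Negative per-SNP values
have no biological interpretation and are clipped to 0 for reporting.

The module also provides the diversity measures used to summarize panels
(expected heterozygosity H_E, proportion of polymorphic markers P_N,
rarefaction allelic richness A_R), composite LD r^2 with sliding-window
pruning, and the allele-sharing (IBS) distance behind the NJ tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix, PopulationAssignment, snp_maf


@dataclass(frozen=True)
class AlleleCount:
    """Allele-A count ``a`` among ``n`` genotyped chromosomes at one SNP."""

    a: int
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.a <= self.n:
            raise ValueError(f"require 0 <= a <= n, got a={self.a}, n={self.n}")

    @property
    def p(self) -> float:
        return self.a / self.n


@dataclass(frozen=True)
class FstValue:
    """Raw estimator output and its non-negative clipped form."""

    raw: float
    clipped: float


@dataclass(frozen=True)
class AlleleCountArray:
    """Vectorized allele counts across SNPs for one group of samples."""

    a: np.ndarray  # allele-A chromosomes per SNP
    n: np.ndarray  # genotyped chromosomes per SNP

    def __getitem__(self, j: int) -> AlleleCount:
        return AlleleCount(int(self.a[j]), int(self.n[j]))


@dataclass(frozen=True)
class DiversitySummary:
    """Panel-mean diversity of one population.

    h_e: mean unbiased expected heterozygosity over SNPs with n >= 2.
    p_n: fraction of SNPs segregating (0 < a < n) in the population.
    a_r: mean rarefaction allelic richness at g chromosomes, over SNPs
         with n >= g (1 <= a_r <= 2 per biallelic SNP).
    """

    population: str
    h_e: float
    p_n: float
    a_r: float
    g: int
    n_snps: int


def allele_counts(g: GenotypeMatrix, members) -> AlleleCountArray:
    """Per-SNP allele-A counts over the given samples.

    ``a`` sums dosages over non-missing members, ``n`` is twice the count of
    non-missing members (diploid chromosomes). SNPs where every member is
    missing get (0, 0).
    """
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    idx = g.sample_index(members)
    d = g.dosage[idx, :]
    obs = d != MISSING
    a = np.where(obs, d, 0).sum(axis=0).astype(np.int64)
    n = 2 * obs.sum(axis=0).astype(np.int64)
    return AlleleCountArray(a=a, n=n)


# ---------------------------------------------------------------------------
# Reich/Hudson F_ST


def reich_fst_arrays(
    a1: np.ndarray, n1: np.ndarray, a2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Reich F_ST; returns (raw, clipped, valid).

    SNPs with fewer than 2 chromosomes in either group are invalid (NaN in
    raw/clipped, False in valid). D = 0 — both groups fixed for the same
    allele — yields F_ST = 0 by convention.
    """
    a1 = np.asarray(a1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    valid = (n1 >= 2) & (n2 >= 2)
    n1s = np.where(valid, n1, 2.0)
    n2s = np.where(valid, n2, 2.0)
    h1 = a1 * (n1s - a1) / (n1s * (n1s - 1.0))
    h2 = a2 * (n2s - a2) / (n2s * (n2s - 1.0))
    num = (a1 / n1s - a2 / n2s) ** 2 - h1 / n1s - h2 / n2s
    den = num + h1 + h2
    raw = np.where(den != 0.0, num / np.where(den == 0.0, 1.0, den), 0.0)
    raw = np.where(valid, raw, np.nan)
    clipped = np.clip(raw, 0.0, None)
    return raw, clipped, valid


def reich_fst(c1: AlleleCount, c2: AlleleCount) -> FstValue:
    """Reich unbiased F_ST between two allele counts at one SNP."""
    if c1.n < 2 or c2.n < 2:
        raise ValueError(
            f"F_ST undefined for n < 2 chromosomes (got n1={c1.n}, n2={c2.n})"
        )
    raw, clipped, _ = reich_fst_arrays(
        np.array([c1.a]), np.array([c1.n]), np.array([c2.a]), np.array([c2.n])
    )
    return FstValue(raw=float(raw[0]), clipped=float(clipped[0]))


def genomewide_fst(
    a1: np.ndarray, n1: np.ndarray, a2: np.ndarray, n2: np.ndarray
) -> float:
    """Genome-wide F_ST as the ratio of summed numerators to denominators.

    This is the averaging Reich et al. use across SNPs: sum N / sum D over
    valid SNPs, clipped at 0. Under a two-population Balding-Nichols model
    with drift F in each population its expectation is F.
    """
    a1 = np.asarray(a1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    valid = (n1 >= 2) & (n2 >= 2)
    a1, n1, a2, n2 = a1[valid], n1[valid], a2[valid], n2[valid]
    h1 = a1 * (n1 - a1) / (n1 * (n1 - 1.0))
    h2 = a2 * (n2 - a2) / (n2 * (n2 - 1.0))
    num = (a1 / n1 - a2 / n2) ** 2 - h1 / n1 - h2 / n2
    den = num + h1 + h2
    total = den.sum()
    if total == 0.0:
        return 0.0
    return max(float(num.sum() / total), 0.0)


# ---------------------------------------------------------------------------
# Diversity measures


def expected_heterozygosity(c: AlleleCount) -> float:
    """Unbiased expected heterozygosity H_E = 2 p (1-p) n/(n-1)."""
    if c.n < 2:
        raise ValueError(f"H_E undefined for n < 2 (got n={c.n})")
    p = c.a / c.n
    return 2.0 * p * (1.0 - p) * c.n / (c.n - 1.0)


def proportion_polymorphic(counts: AlleleCountArray) -> float:
    """Fraction of SNPs segregating (0 < a < n) among SNPs with n >= 2."""
    ok = counts.n >= 2
    if not ok.any():
        raise ValueError("no SNP with >= 2 genotyped chromosomes")
    a, n = counts.a[ok], counts.n[ok]
    return float(((a > 0) & (a < n)).mean())


def allelic_richness(c: AlleleCount, g: int) -> float:
    """Rarefaction allelic richness: expected allele count in g chromosomes.

    A_R(g) = sum_j [1 - C(n - a_j, g) / C(n, g)] over the two allele counts
    a_j in {a, n-a}; C(m, g) = 0 when m < g. Between 1 and 2 for a biallelic
    SNP; exactly 1 when fixed, approaches 2 as both alleles become common.
    """
    if not (isinstance(g, (int, np.integer)) and g >= 1):
        raise ValueError(f"g must be a positive integer, got {g}")
    if g > c.n:
        raise ValueError(f"standardized size g={g} exceeds sample n={c.n}")
    total = 0.0
    for aj in (c.a, c.n - c.a):
        m = c.n - aj
        if m < g:
            miss = 0.0
        else:
            # C(m, g)/C(n, g) via log-gammas for numerical safety
            miss = np.exp(
                gammaln(m + 1) - gammaln(m - g + 1) - (gammaln(c.n + 1) - gammaln(c.n - g + 1))
            )
        total += 1.0 - miss
    return float(total)


def diversity_summary(
    g: GenotypeMatrix, assign: PopulationAssignment, rarefaction_g: int
) -> list[DiversitySummary]:
    """Per-population H_E / P_N / A_R summaries over a panel.

    SNPs with fewer than 2 genotyped chromosomes in a population are dropped
    from that population's H_E and P_N; SNPs with n < rarefaction_g are
    dropped from its A_R mean.
    """
    out = []
    for pop in assign.populations():
        members = [s for s in g.samples if assign.mapping.get(s) == pop]
        counts = allele_counts(g, members)
        ok = counts.n >= 2
        a, n = counts.a[ok].astype(float), counts.n[ok].astype(float)
        p = a / n
        h_e = float((2.0 * p * (1.0 - p) * n / (n - 1.0)).mean()) if ok.any() else float("nan")
        p_n = proportion_polymorphic(counts)
        ar_ok = counts.n >= rarefaction_g
        ar_vals = [
            allelic_richness(counts[j], rarefaction_g)
            for j in np.nonzero(ar_ok)[0]
        ]
        a_r = float(np.mean(ar_vals)) if ar_vals else float("nan")
        out.append(
            DiversitySummary(
                population=pop, h_e=h_e, p_n=p_n, a_r=a_r,
                g=rarefaction_g, n_snps=int(ok.sum()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def ld_r2(g: GenotypeMatrix, snp_i: int, snp_j: int) -> float:
    """Composite (genotypic) r^2: squared Pearson correlation of dosages.

    Computed over samples non-missing at both SNPs. NaN when either SNP has
    zero dosage variance on that subset (the pair is prune-ineligible).
    """
    x = g.dosage[:, snp_i].astype(float)
    y = g.dosage[:, snp_j].astype(float)
    ok = (g.dosage[:, snp_i] != MISSING) & (g.dosage[:, snp_j] != MISSING)
    if ok.sum() < 2:
        raise ValueError("need >= 2 samples non-missing at both SNPs")
    x, y = x[ok], y[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _window_r2(d: np.ndarray) -> np.ndarray:
    """Pairwise composite r^2 over the columns of a dosage block.

    Missing-aware: each pair uses its pairwise-complete samples. NaN on
    zero-variance pairs.
    """
    obs = (d != MISSING).astype(float)
    x = np.where(d != MISSING, d, 0).astype(float)
    cnt = obs.T @ obs                     # pairwise-complete sample counts
    sx = x.T @ obs                        # sum of x_i over pairwise-complete samples
    sxx = (x * x).T @ obs                 # sum of x_i^2 over the same
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = sx / cnt
        my = mx.T
        cov = sxy / cnt - mx * my
        vx = sxx / cnt - mx * mx
        vy = vx.T
        r2 = cov * cov / (vx * vy)
    r2[(cnt < 2) | ~np.isfinite(r2)] = np.nan
    np.fill_diagonal(r2, np.nan)
    return r2


def ld_prune(
    g: GenotypeMatrix, r2_max: float = 0.3, window_snps: int = 50, step_snps: int = 5
) -> GenotypeMatrix:
    """Sliding-window LD pruning: greedily drop SNPs until all retained
    intra-window pairs have r^2 < ``r2_max``.

    Within each window the SNP with lower panel MAF of the worst offending
    pair is removed (tie: the later map position). Windows of
    ``window_snps`` SNPs advance by ``step_snps`` along each chromosome;
    SNPs must be sorted by (chrom, pos).
    """
    keys = [(s.chrom, s.pos) for s in g.snps]
    by_chrom: dict[str, list[int]] = {}
    for j, s in enumerate(g.snps):
        by_chrom.setdefault(s.chrom, []).append(j)
    for idxs in by_chrom.values():
        pos = [g.snps[j].pos for j in idxs]
        if pos != sorted(pos):
            raise ValueError("SNPs must be sorted by (chrom, pos); sort the panel first")
    del keys

    maf = np.nan_to_num(snp_maf(g), nan=-1.0)
    keep = np.ones(g.n_snps, dtype=bool)
    for idxs in by_chrom.values():
        start = 0
        while start < len(idxs):
            window = [j for j in idxs[start : start + window_snps] if keep[j]]
            while True:
                if len(window) < 2:
                    break
                d = g.dosage[:, window]
                r2 = _window_r2(d)
                with np.errstate(invalid="ignore"):
                    offending = np.argwhere(r2 >= r2_max)
                if offending.size == 0:
                    break
                # worst pair first for determinism
                vals = r2[offending[:, 0], offending[:, 1]]
                i, j = offending[np.argmax(vals)]
                gi, gj = window[i], window[j]
                if maf[gi] < maf[gj]:
                    drop = gi
                elif maf[gj] < maf[gi]:
                    drop = gj
                else:
                    drop = gi if g.snps[gi].pos > g.snps[gj].pos else gj
                keep[drop] = False
                window = [w for w in window if w != drop]
            if start + window_snps >= len(idxs):
                break
            start += step_snps
    return g.take_snps(keep)


# ---------------------------------------------------------------------------
# Allele sharing


def allele_sharing_distance(g: GenotypeMatrix):
    """Pairwise IBS allele-sharing distance between samples.

    d(x, y) = 1 - (IBS2 + 0.5 IBS1)/M over the M SNPs genotyped in both
    samples, where IBS2/IBS1 count SNPs sharing two/one allele. For dosage
    vectors this is mean(|x - y|)/2. Raises if a pair shares no genotyped
    SNP. Returns a :class:`lsblscan.tree.DistanceMatrix`.
    """
    from .tree import DistanceMatrix

    if g.n_samples < 2 or g.n_snps < 1:
        raise ValueError("need >= 2 samples and >= 1 SNP")
    n = g.n_samples
    obs = g.dosage != MISSING
    d = np.zeros((n, n))
    x = g.dosage.astype(float)
    for i in range(n):
        for j in range(i + 1, n):
            ok = obs[i] & obs[j]
            m = ok.sum()
            if m == 0:
                raise ValueError(
                    f"samples {g.samples[i]!r} and {g.samples[j]!r} share no genotyped SNP"
                )
            d[i, j] = d[j, i] = np.abs(x[i, ok] - x[j, ok]).mean() / 2.0
    return DistanceMatrix(labels=list(g.samples), matrix=d)
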