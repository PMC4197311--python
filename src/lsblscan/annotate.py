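"""Candidate-region definition, gene overlap and gene-set enrichment.

Outlier SNPs are extended to candidate regions (+/- 50 kb by default,
clamped at the chromosome start); genes intersecting a region by at least
one base pair are nominated as candidates. Enrichment of the candidate
gene set in user-supplied gene sets (GMT) uses the hypergeometric upper
tail with Bonferroni correction across tested terms.

Coordinates: BED is 0-based half-open, GFF3 and SNP/region reports are
1-based closed; everything is normalized to 0-based half-open internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .lsbl_scan import OutlierSet


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, internally 0-based half-open."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"gene {self.gene_id}: empty chromosome")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: require start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CandidateRegion:
    """The flanking window around one outlier SNP (1-based closed report)."""

    snp_id: str
    chrom: str
    window_start: int  # 1-based inclusive
    window_end: int    # 1-based inclusive

    @property
    def zstart(self) -> int:
        """0-based half-open start."""
        return self.window_start - 1

    @property
    def zend(self) -> int:
        return self.window_end


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int        # candidate genes in term
    K: int        # universe genes in term
    n: int        # candidate genes
    N: int        # universe size
    p_raw: float
    p_corrected: float
    genes: tuple[str, ...] = ()


def candidate_regions(outliers: OutlierSet, flank: int = 50_000) -> list[CandidateRegion]:
    """One +/- ``flank`` bp window per outlier SNP, clamped at position 1."""
    regions = []
    for row in outliers.outliers.itertuples(index=False):
        pos = int(row.pos)
        regions.append(
            CandidateRegion(
                snp_id=row.snp_id,
                chrom=str(row.chrom),
                window_start=max(1, pos - flank),
                window_end=pos + flank,
            )
        )
    return regions


def read_bed(path) -> list[GeneModel]:
    """BED with >= 4 columns (chrom, start, end, name[, score, strand])."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns")
            strand = f[5] if len(f) >= 6 else "."
            genes.append(GeneModel(f[3], f[0], int(f[1]), int(f[2]), strand))
    return genes


def read_gff3(path, feature_type: str = "gene", id_keys=("gene_id", "ID")) -> list[GeneModel]:
    """Gene intervals from GFF3 (1-based closed converted to half-open)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
            if f[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene_id = next((attrs[k] for k in id_keys if k in attrs), None)
            if gene_id is None:
                raise ValueError(
                    f"{path}:{lineno}: none of {id_keys} in attributes"
                )
            genes.append(GeneModel(gene_id, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return genes


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: term, description, then member gene ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs >= 3 columns")
            sets[f[0]] = {g for g in f[2:] if g}
    return sets


def map_regions_to_genes(
    regions: list[CandidateRegion], genes: list[GeneModel]
) -> pd.DataFrame:
    """Genes intersecting each candidate region by >= 1 bp.

    Returns a table (snp_id, gene_id, overlap_bp). The candidate gene set
    of a scan is the deduplicated union of ``gene_id``. Chromosomes named
    in regions but absent from the annotation draw a warning (zero hits).
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        trees.setdefault(gene.chrom, IntervalTree()).addi(gene.start, gene.end, gene)
    seen_missing: set[str] = set()
    rows = []
    for region in regions:
        tree = trees.get(region.chrom)
        if tree is None:
            if region.chrom not in seen_missing:
                seen_missing.add(region.chrom)
                warnings.warn(
                    f"chromosome {region.chrom!r} has no annotated gene; "
                    "check chromosome naming",
                    stacklevel=2,
                )
            continue
        for iv in sorted(tree.overlap(region.zstart, region.zend)):
            gene = iv.data
            overlap = min(gene.end, region.zend) - max(gene.start, region.zstart)
            rows.append((region.snp_id, gene.gene_id, overlap))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "overlap_bp"])


def candidate_gene_set(hits: pd.DataFrame) -> set[str]:
    return set(hits["gene_id"])


def gene_set_enrichment(
    candidates: set[str], universe: set[str], gene_sets: dict[str, set[str]]
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test per term, Bonferroni-corrected.

    p_raw = P(X >= k) drawing n candidates from a universe of N genes of
    which K belong to the term (term membership intersected with the
    universe first). Terms with no universe member are skipped; k = 0 terms
    report p_raw = 1 and are retained so the correction count is explicit.
    Results are sorted by ascending corrected p, then term id.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not candidates:
        raise ValueError("empty candidate gene set")
    stray = candidates - universe
    if stray:
        raise ValueError(f"candidates outside the universe: {sorted(stray)[:5]}")
    N = len(universe)
    n = len(candidates)
    tested = {t: s & universe for t, s in gene_sets.items() if s & universe}
    m = len(tested)
    results = []
    for term, members in tested.items():
        K = len(members)
        hit_genes = tuple(sorted(candidates & members))
        k = len(hit_genes)
        p_raw = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
        p_raw = min(p_raw, 1.0)
        results.append(
            EnrichmentResult(
                term_id=term, k=k, K=K, n=n, N=N,
                p_raw=p_raw, p_corrected=min(1.0, p_raw * m), genes=hit_genes,
            )
        )
    results.sort(key=lambda r: (r.p_corrected, r.p_raw, r.term_id))
    return results


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    pd.DataFrame(
        [
            {
                "term_id": r.term_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p_raw": r.p_raw, "p_corrected": r.p_corrected,
                "genes": ",".join(r.genes),
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
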