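#!/usr/bin/env python
"""Candidate regions, gene overlap and enrichment for the scan outliers.

Extends each outlier SNP by +/- 50 kb, intersects the windows with a
synthetic gene annotation (genes tiled along the simulated chromosomes;
no real genome is involved), and tests a synthetic gene-set collection
for over-representation. One gene set is constructed from genes near
planted sweeps, so it should surface with a small Bonferroni-corrected
p-value; the remaining sets are random draws and should not.
"""

import importlib.util
from pathlib import Path

import numpy as np

from lsblscan import build_shared_spec, run_scan
from lsblscan.annotate import (
    GeneModel,
    candidate_gene_set,
    candidate_regions,
    gene_set_enrichment,
    map_regions_to_genes,
    write_enrichment_tsv,
)
from lsblscan.synthetic_data import STUDY_FOCAL, STUDY_REFERENCES, STUDY_SISTERS

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

spec_ = importlib.util.spec_from_file_location(
    "sim01", Path(__file__).parent / "01_simulate_panel.py"
)
sim01 = importlib.util.module_from_spec(spec_)
spec_.loader.exec_module(sim01)


def synthetic_annotation(g, gene_length=30_000, spacing=80_000):
    """Genes tiled along each simulated chromosome (synthetic stand-in)."""
    genes = []
    k = 0
    for chrom in dict.fromkeys(s.chrom for s in g.snps):
        last = max(s.pos for s in g.snps if s.chrom == chrom)
        for start in range(0, last + spacing, spacing):
            genes.append(GeneModel(f"gene{k}", chrom, start, start + gene_length))
            k += 1
    return genes


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    (g, assign, truth), _, _ = sim01.study_panels()
    spec = build_shared_spec(
        assign, {STUDY_FOCAL}, set(STUDY_SISTERS), set(STUDY_REFERENCES)
    )
    _, outliers = run_scan(g, spec, top_fraction=0.005)

    regions = candidate_regions(outliers, flank=50_000)
    genes = synthetic_annotation(g)
    hits = map_regions_to_genes(regions, genes)
    candidates = candidate_gene_set(hits)
    universe = {gm.gene_id for gm in genes}
    print(
        f"{len(regions)} candidate regions (+/- 50 kb) over {len(genes)} "
        f"annotated genes -> {len(candidates)} candidate genes"
    )
    hits.to_csv(RESULTS / "candidate_genes.tsv", sep="\t", index=False)

    # gene sets: one built around planted sweeps, nine random
    rng = np.random.default_rng(sim01.STUDY_SEED)
    planted_pos = {
        (r.chrom, r.pos)
        for r in truth.table.itertuples()
        if r.selected_in == STUDY_FOCAL
    }
    sweep_genes = {
        gm.gene_id
        for gm in genes
        if any(
            c == gm.chrom and gm.start - 50_000 <= p <= gm.end + 50_000
            for c, p in planted_pos
        )
    }
    gene_sets = {"sweep_neighborhood": sweep_genes}
    for i in range(9):
        gene_sets[f"random_set_{i}"] = set(
            rng.choice(sorted(universe), size=len(sweep_genes), replace=False)
        )
    results = gene_set_enrichment(candidates, universe, gene_sets)
    write_enrichment_tsv(results, RESULTS / "enrichment.tsv")
    print("enrichment (Bonferroni-corrected):")
    for r in results[:3]:
        print(f"  {r.term_id}: k={r.k}/{r.K}, p_cor={r.p_corrected:.3g}")


if __name__ == "__main__":
    main()
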