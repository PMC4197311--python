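#!/usr/bin/env python
"""Simulate the synthetic study panels.

Builds the canonical three-group design: one highland focal population
(20 diploids, drift F = 0.1) carrying 20 planted sweeps (ancestrally
minor allele shifted by 0.7), two sister highland populations, and ten
lowland reference breeds — 150 individuals, 10,000 SNPs, 2% missing
calls. Also simulates the matching all-neutral null panel and a 49-SNP
fine-mapping panel over the same samples for the merge re-scan.

Full PED/MAP/truth files land under scratch/panels/ (they are several
MB); results/ gets a compact per-population summary. Every downstream
analysis script regenerates the same panels deterministically from
STUDY_SEED, so the scratch files are a convenience, not a dependency.
"""

import json
from pathlib import Path

import pandas as pd

from lsblscan import scan_study_config, simulate_panel, write_ped_map
from lsblscan.genotype_io import write_population_assignment
from lsblscan.synthetic_data import SimConfig

STUDY_SEED = 20140834
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "panels"
RESULTS = ROOT / "results"


def study_panels():
    """The three panels every analysis step shares (deterministic)."""
    cfg = scan_study_config(seed=STUDY_SEED)
    study = simulate_panel(cfg)
    null = simulate_panel(scan_study_config(seed=STUDY_SEED + 1, n_selected=0))
    fm_cfg = SimConfig(
        n_snps=49,
        populations=cfg.populations,
        missing_rate=cfg.missing_rate,
        seed=STUDY_SEED + 2,
    )
    g_fm, a_fm, t_fm = simulate_panel(fm_cfg)
    g_fm.snps = [
        type(s)(f"fm_{s.snp_id}", s.chrom, s.pos + 7, s.allele_a, s.allele_b)
        for s in g_fm.snps
    ]
    return study, null, (g_fm, a_fm, t_fm)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    (study_g, study_a, study_t), (null_g, null_a, null_t), (fm_g, _, fm_t) = (
        study_panels()
    )

    for name, g, a, t in (
        ("study", study_g, study_a, study_t),
        ("null", null_g, null_a, null_t),
    ):
        write_ped_map(g, SCRATCH / name)
        write_population_assignment(a, SCRATCH / f"{name}.pops.tsv")
        t.table.to_csv(SCRATCH / f"{name}.truth.tsv", sep="\t", index=False)
    write_ped_map(fm_g, SCRATCH / "finemap")

    pops = pd.Series(study_a.mapping).value_counts()
    summary = {
        "seed": STUDY_SEED,
        "n_samples": study_g.n_samples,
        "n_snps": study_g.n_snps,
        "populations": pops.to_dict(),
        "planted_sweeps_focal": len(study_t.selected_snp_ids()),
        "missing_fraction": round(float((study_g.dosage == -1).mean()), 4),
        "finemap_snps": fm_g.n_snps,
    }
    with open(RESULTS / "panel_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    print(
        f"study panel: {study_g.n_samples} samples x {study_g.n_snps} SNPs "
        f"({summary['missing_fraction']:.1%} missing), "
        f"{summary['planted_sweeps_focal']} planted sweeps; "
        f"null panel and {fm_g.n_snps}-SNP fine-mapping panel written to {SCRATCH}"
    )


if __name__ == "__main__":
    main()
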