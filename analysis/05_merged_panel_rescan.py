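#!/usr/bin/env python
"""Merge the fine-mapping panel into the array panel and re-scan.

Emulates targeted follow-up genotyping: 49 extra SNPs typed on the same
individuals are merged into the array panel (disjoint SNP ids, shared
samples) and the three-group scan is repeated on the combined panel with
its own recomputed 0.5% threshold. Reports how the fine-mapping SNPs
rank in the merged empirical distribution.
"""

import importlib.util
from pathlib import Path

from lsblscan import build_shared_spec, merge_panels, run_scan
from lsblscan.synthetic_data import STUDY_FOCAL, STUDY_REFERENCES, STUDY_SISTERS

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

spec_ = importlib.util.spec_from_file_location(
    "sim01", Path(__file__).parent / "01_simulate_panel.py"
)
sim01 = importlib.util.module_from_spec(spec_)
spec_.loader.exec_module(sim01)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    (g, assign, _), _, (g_fm, _, _) = sim01.study_panels()
    merged = merge_panels(g, g_fm)
    print(
        f"merged panel: {g.n_snps} array + {g_fm.n_snps} fine-mapping SNPs "
        f"= {merged.n_snps} SNPs over {merged.n_samples} shared samples"
    )

    spec = build_shared_spec(
        assign, {STUDY_FOCAL}, set(STUDY_SISTERS), set(STUDY_REFERENCES)
    )
    result, outliers = run_scan(merged, spec, top_fraction=0.005)
    fm_ids = {s.snp_id for s in g_fm.snps}
    fm_rows = result.table[result.table.snp_id.isin(fm_ids)].copy()
    fm_called = set(fm_rows.snp_id) & set(outliers.snp_ids)
    print(
        f"re-scan: {outliers.n_valid} valid SNPs, recomputed 0.5% cutoff "
        f"{outliers.cutoff:.3f}, {len(outliers.outliers)} outliers"
    )
    print(
        f"fine-mapping SNPs above the threshold: {len(fm_called)} "
        "(neutral follow-up SNPs are expected to stay below it)"
    )
    fm_rows.sort_values("lsbl", ascending=False).to_csv(
        RESULTS / "finemap_rescan.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
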