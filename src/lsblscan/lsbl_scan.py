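"""Three-group locus-specific branch length (LSBL) selection scan.

A scan contrasts a focal group against two reference groups. At each SNP
the three pairwise Reich F_ST values — d_f1 (focal vs contrast 1), d_f2
(focal vs contrast 2) and d_12 (contrast 1 vs contrast 2) — are decomposed
into the length of the focal group's own branch:

    LSBL(focal) = (d_f1 + d_f2 - d_12) / 2

A large LSBL marks allele-frequency divergence specific to the focal
group, the signature expected at a locally selected locus. Candidate loci
are called as the upper tail of the empirical LSBL distribution (top 0.5%
by default); no parametric null is assumed.

F_ST inputs are clipped at 0; LSBL itself is not clipped (negative values
exist but can never enter the upper tail).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PopulationAssignment
from .popgen_stats import allele_counts, reich_fst_arrays


@dataclass(frozen=True)
class GroupSpec:
    """The three-group contrast defining one scan.

    ``focal`` is the population under test (e.g. one highland population);
    ``contrast1``/``contrast2`` are the two reference groups. The three
    sample sets must be pairwise disjoint and non-empty.
    """

    focal: tuple[str, ...]
    contrast1: tuple[str, ...]
    contrast2: tuple[str, ...]
    focal_label: str = "focal"
    contrast1_label: str = "contrast1"
    contrast2_label: str = "contrast2"

    def __post_init__(self) -> None:
        sets = {
            self.focal_label: set(self.focal),
            self.contrast1_label: set(self.contrast1),
            self.contrast2_label: set(self.contrast2),
        }
        for name, s in sets.items():
            if not s:
                raise ValueError(f"group {name!r} is empty")
        names = list(sets)
        for i in range(3):
            for j in range(i + 1, 3):
                clash = sets[names[i]] & sets[names[j]]
                if clash:
                    raise ValueError(
                        f"groups {names[i]!r} and {names[j]!r} share samples: "
                        f"{sorted(clash)[:5]}"
                    )


def build_shared_spec(
    assign: PopulationAssignment,
    focal_pops,
    contrast1_pops,
    contrast2_pops,
    labels: tuple[str, str, str] = ("focal", "contrast1", "contrast2"),
) -> GroupSpec:
    """Population-shared design: the focal group pools several populations
    (e.g. all highland populations) against two reference unions."""
    f, c1, c2 = (set(x) for x in (focal_pops, contrast1_pops, contrast2_pops))
    for a, b, na, nb in (
        (f, c1, "focal", "contrast1"),
        (f, c2, "focal", "contrast2"),
        (c1, c2, "contrast1", "contrast2"),
    ):
        if a & b:
            raise ValueError(f"{na} and {nb} share population labels: {sorted(a & b)}")
    return GroupSpec(
        focal=tuple(assign.samples_in(f)),
        contrast1=tuple(assign.samples_in(c1)),
        contrast2=tuple(assign.samples_in(c2)),
        focal_label=labels[0],
        contrast1_label=labels[1],
        contrast2_label=labels[2],
    )


def build_specific_spec(
    assign: PopulationAssignment,
    focal_pop: str,
    other_focal_pops,
    reference_pops,
) -> GroupSpec:
    """Population-specific design: one focal population versus its sister
    populations (contrast 1) and a pooled reference panel (contrast 2)."""
    others = set(other_focal_pops)
    if not others:
        raise ValueError("other_focal_pops must be non-empty (three-group model)")
    return build_shared_spec(
        assign,
        {focal_pop},
        others,
        set(reference_pops),
        labels=(focal_pop, "+".join(sorted(others)), "reference"),
    )


def lsbl(d_f1: float, d_f2: float, d_12: float) -> float:
    """Focal branch length from three pairwise (clipped) F_ST values."""
    for name, v in (("d_f1", d_f1), ("d_f2", d_f2), ("d_12", d_12)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a clipped F_ST in [0, 1], got {v}")
    return (d_f1 + d_f2 - d_12) / 2.0


@dataclass
class ScanResult:
    """Per-SNP scan table plus validity bookkeeping.

    ``table`` columns: snp_id, chrom, pos, d_f1, d_f2, d_12, lsbl, valid.
    A SNP is valid when every pairwise F_ST is defined (>= 2 chromosomes
    genotyped in each group).
    """

    table: pd.DataFrame
    spec: GroupSpec

    @property
    def n_valid(self) -> int:
        return int(self.table["valid"].sum())


def three_group_fst(g: GenotypeMatrix, spec: GroupSpec) -> ScanResult:
    """Pairwise Reich F_ST and LSBL at every SNP for a three-group contrast."""
    cf = allele_counts(g, spec.focal)
    c1 = allele_counts(g, spec.contrast1)
    c2 = allele_counts(g, spec.contrast2)
    _, d_f1, v1 = reich_fst_arrays(cf.a, cf.n, c1.a, c1.n)
    _, d_f2, v2 = reich_fst_arrays(cf.a, cf.n, c2.a, c2.n)
    _, d_12, v3 = reich_fst_arrays(c1.a, c1.n, c2.a, c2.n)
    valid = v1 & v2 & v3
    lsbl_vals = (d_f1 + d_f2 - d_12) / 2.0
    table = pd.DataFrame(
        {
            "snp_id": g.snp_ids(),
            "chrom": [s.chrom for s in g.snps],
            "pos": [s.pos for s in g.snps],
            "d_f1": d_f1,
            "d_f2": d_f2,
            "d_12": d_12,
            "lsbl": lsbl_vals,
            "valid": valid,
        }
    )
    return ScanResult(table=table, spec=spec)


@dataclass
class OutlierSet:
    """The empirically thresholded top tail of a scan.

    ``outliers`` is ordered by descending LSBL (ties by genomic order);
    ``cutoff`` is the LSBL of the last included SNP. Exactly
    floor(top_fraction x N_valid) SNPs are included.
    """

    top_fraction: float
    cutoff: float
    outliers: pd.DataFrame
    n_valid: int

    @property
    def snp_ids(self) -> list[str]:
        return list(self.outliers["snp_id"])


def empirical_outliers(result: ScanResult, top_fraction: float = 0.005) -> OutlierSet:
    """Call the top ``top_fraction`` of valid SNPs by LSBL.

    Sorting is by descending LSBL with ties broken by (chrom, pos)
    ascending, so the call set is deterministic.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError(f"top_fraction must be in (0, 1), got {top_fraction}")
    valid = result.table[result.table["valid"]].copy()
    n_valid = len(valid)
    if n_valid == 0:
        raise ValueError("no valid SNP in scan result")
    valid = valid.sort_values(
        by=["lsbl", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    k = math.floor(top_fraction * n_valid)
    out = valid.iloc[:k].copy()
    out["rank"] = np.arange(1, k + 1)
    cutoff = float(out["lsbl"].iloc[-1]) if k > 0 else float("inf")
    return OutlierSet(
        top_fraction=top_fraction, cutoff=cutoff, outliers=out, n_valid=n_valid
    )


def run_scan(
    g: GenotypeMatrix, spec: GroupSpec, top_fraction: float = 0.005
) -> tuple[ScanResult, OutlierSet]:
    """Full scan: three-group F_ST, LSBL and empirical outlier calling."""
    result = three_group_fst(g, spec)
    return result, empirical_outliers(result, top_fraction)


def frequency_table(
    g: GenotypeMatrix, assign: PopulationAssignment, snp_ids
) -> pd.DataFrame:
    """Allele-A frequency per population at the requested SNPs.

    Rows are populations, columns SNP ids; NaN where a population has no
    genotyped chromosome. The heat-map input for inspecting top loci.
    """
    snp_ids = list(snp_ids)
    index = {sid: j for j, sid in enumerate(g.snp_ids())}
    missing_ids = [s for s in snp_ids if s not in index]
    if missing_ids:
        raise KeyError(f"unknown snp_id(s): {missing_ids[:5]}")
    cols = [index[s] for s in snp_ids]
    rows = {}
    for pop in assign.populations():
        members = [s for s in g.samples if assign.mapping.get(s) == pop]
        if not members:
            continue
        counts = allele_counts(g, members)
        a = counts.a[cols].astype(float)
        n = counts.n[cols].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, a / np.maximum(n, 1), np.nan)
        rows[pop] = p
    return pd.DataFrame(rows, index=snp_ids).T


def write_scan_tsv(result: ScanResult, outliers: OutlierSet, path) -> None:
    """Scan table TSV with is_outlier/rank columns."""
    table = result.table.copy()
    rank = dict(zip(outliers.outliers["snp_id"], outliers.outliers["rank"]))
    table["is_outlier"] = table["snp_id"].isin(rank).astype(int)
    table["rank"] = [rank.get(s, 0) for s in table["snp_id"]]
    table.to_csv(path, sep="\t", index=False)
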