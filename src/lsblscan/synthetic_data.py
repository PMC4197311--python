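"""Synthetic multi-population SNP panels with known selected loci.

Populations diverge from a shared ancestral allele frequency under the
Balding-Nichols model: at each SNP the ancestral frequency p is drawn
uniformly from a configurable range, and each population's frequency is

    p_i ~ Beta(p (1-F_i)/F_i, (1-p) (1-F_i)/F_i)

so that E[p_i] = p and Var(p_i) = F_i p (1-p) — F_i is the population's
drift from the ancestor and is what pairwise F_ST measures. Selection is
modeled as a post-hoc allele-frequency shift at designated loci in a
designated population (delta added and clamped to [0, 1], or an absolute
target frequency), which creates the focal-branch signature an LSBL scan
detects. Genotypes are Binomial(2, p_i) per diploid individual (HWE
within populations) with independent missingness.

All randomness flows from a single integer seed through numpy's PCG64
generator, so a config reproduces its panel bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PopulationAssignment, SnpRecord


@dataclass(frozen=True)
class PopulationConfig:
    label: str
    n_individuals: int
    drift: float  # Balding-Nichols F in (0, 1); 0 allowed as the no-drift limit

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"{self.label}: need >= 1 individual")
        if not 0.0 <= self.drift < 1.0:
            raise ValueError(f"{self.label}: drift F must be in [0, 1), got {self.drift}")


@dataclass(frozen=True)
class SelectionConfig:
    """Planted selection: shift the focal population's frequency at n_loci SNPs."""

    population: str
    n_loci: int
    shift: float | None = None         # delta added to p_i, clamped to [0, 1]
    target_freq: float | None = None   # or an absolute replacement frequency

    def __post_init__(self) -> None:
        if (self.shift is None) == (self.target_freq is None):
            raise ValueError("specify exactly one of shift / target_freq")
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study design for one synthetic panel.

    Defaults emulate a mid-density SNP array over structured pig-like
    populations: tens of thousands of independent biallelic SNPs, an
    ascertained ancestral frequency range (0.05-0.95), and ~2% missing
    genotype calls.
    """

    n_snps: int
    populations: tuple[PopulationConfig, ...]
    selected: tuple[SelectionConfig, ...] = ()
    ancestral_maf_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.02
    seed: int = 0
    n_chromosomes: int = 18
    snp_spacing_bp: int = 60_000

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not self.populations:
            raise ValueError("at least one population required")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        lo, hi = self.ancestral_maf_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("ancestral_maf_range must satisfy 0 <= lo <= hi <= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        total_sel = sum(s.n_loci for s in self.selected)
        if total_sel > self.n_snps:
            raise ValueError("more selected loci than SNPs")
        for s in self.selected:
            if s.population not in labels:
                raise ValueError(f"selected population {s.population!r} not simulated")


@dataclass
class SimTruth:
    """Ground truth: per-SNP ancestral and per-population frequencies.

    ``table`` columns: snp_id, chrom, pos, ancestral_p, selected_in (empty
    string for neutral SNPs), then p_<label> per population.
    """

    table: pd.DataFrame
    config: SimConfig

    def selected_snp_ids(self, population: str | None = None) -> list[str]:
        t = self.table
        mask = t["selected_in"] != "" if population is None else t["selected_in"] == population
        return list(t.loc[mask, "snp_id"])


def _snp_coords(cfg: SimConfig) -> list[tuple[str, int]]:
    """Spread SNPs over autosomes in contiguous equally spaced blocks."""
    per_chrom = int(np.ceil(cfg.n_snps / cfg.n_chromosomes))
    coords = []
    for j in range(cfg.n_snps):
        chrom = j // per_chrom + 1
        offset = j % per_chrom
        coords.append((str(chrom), (offset + 1) * cfg.snp_spacing_bp))
    return coords


def simulate_frequencies(cfg: SimConfig) -> SimTruth:
    """Draw ancestral and per-population frequencies; plant selection shifts.

    Selected loci are chosen without replacement across all selection
    entries, so the planted sets are disjoint. Drift F = 0 is the exact
    no-drift limit (p_i = p).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_maf_range
    p = rng.uniform(lo, hi, cfg.n_snps)

    freqs: dict[str, np.ndarray] = {}
    for pop in cfg.populations:
        if pop.drift == 0.0:
            freqs[pop.label] = p.copy()
        else:
            scale = (1.0 - pop.drift) / pop.drift
            freqs[pop.label] = rng.beta(p * scale, (1.0 - p) * scale)

    selected_in = np.full(cfg.n_snps, "", dtype=object)
    total_sel = sum(s.n_loci for s in cfg.selected)
    if total_sel:
        chosen = rng.choice(cfg.n_snps, size=total_sel, replace=False)
        offset = 0
        for sel in cfg.selected:
            loci = chosen[offset : offset + sel.n_loci]
            offset += sel.n_loci
            selected_in[loci] = sel.population
            if sel.shift is not None:
                # Selection favors the ancestrally minor allele: its focal
                # frequency rises by delta (clamped), i.e. allele-A moves up
                # where the ancestral p <= 0.5 and down otherwise. The shift
                # is directed away from where the unselected populations
                # concentrate, the signature a focal-branch scan detects.
                cur = freqs[sel.population][loci]
                up = p[loci] <= 0.5
                freqs[sel.population][loci] = np.clip(
                    np.where(up, cur + sel.shift, cur - sel.shift), 0.0, 1.0
                )
            else:
                freqs[sel.population][loci] = sel.target_freq

    coords = _snp_coords(cfg)
    table = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1}" for j in range(cfg.n_snps)],
            "chrom": [c for c, _ in coords],
            "pos": [bp for _, bp in coords],
            "ancestral_p": p,
            "selected_in": selected_in,
        }
    )
    for pop in cfg.populations:
        table[f"p_{pop.label}"] = freqs[pop.label]
    return SimTruth(table=table, config=cfg)


def simulate_genotypes(
    truth: SimTruth, cfg: SimConfig | None = None
) -> tuple[GenotypeMatrix, PopulationAssignment]:
    """Sample diploid genotypes from the truth table.

    Dosages are Binomial(2, p_pop) per individual per SNP (HWE within
    populations); each call is then masked missing independently with
    probability ``missing_rate``. The genotype RNG is seeded from the
    config seed (offset so it does not replay the frequency stream).
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng((cfg.seed, 1))
    n_snps = len(truth.table)
    samples: list[str] = []
    assign: dict[str, str] = {}
    blocks = []
    for pop in cfg.populations:
        p_pop = truth.table[f"p_{pop.label}"].to_numpy()
        block = rng.binomial(2, p_pop, size=(pop.n_individuals, n_snps)).astype(np.int8)
        if cfg.missing_rate > 0.0:
            mask = rng.random((pop.n_individuals, n_snps)) < cfg.missing_rate
            block[mask] = -1
        blocks.append(block)
        for i in range(pop.n_individuals):
            sid = f"{pop.label}_{i + 1}"
            samples.append(sid)
            assign[sid] = pop.label
    dosage = np.vstack(blocks)
    snps = [
        SnpRecord(row.snp_id, row.chrom, int(row.pos), "A", "B")
        for row in truth.table.itertuples(index=False)
    ]
    return (
        GenotypeMatrix(samples=samples, snps=snps, dosage=dosage),
        PopulationAssignment(assign),
    )


def simulate_panel(cfg: SimConfig):
    """Convenience: frequencies + genotypes in one call."""
    truth = simulate_frequencies(cfg)
    g, assign = simulate_genotypes(truth, cfg)
    return g, assign, truth


#: Population labels of the canonical three-group validation design.
STUDY_FOCAL = "highland"
STUDY_SISTERS = ("sisterA", "sisterB")
STUDY_REFERENCES = tuple(f"low{i}" for i in range(1, 11))


def scan_study_config(
    seed: int,
    n_snps: int = 10_000,
    n_selected: int = 20,
    shift: float = 0.7,
    drift: float = 0.1,
) -> SimConfig:
    """The canonical validation design for the three-group scan.

    One focal population (20 diploids, drift F), two sister populations
    (15 each) forming contrast group 1, and ten reference breeds (10 each)
    forming contrast group 2 — every population drifting independently at
    F, mirroring a pooled-breed contrast design. ``n_selected`` loci carry
    a strong sweep (ancestrally minor allele up by ``shift``) in the focal
    population; ``n_selected=0`` gives the all-neutral null panel.
    """
    pops = (
        (PopulationConfig(STUDY_FOCAL, 20, drift),)
        + tuple(PopulationConfig(lbl, 15, drift) for lbl in STUDY_SISTERS)
        + tuple(PopulationConfig(lbl, 10, drift) for lbl in STUDY_REFERENCES)
    )
    selected = (
        (SelectionConfig(STUDY_FOCAL, n_selected, shift=shift),)
        if n_selected
        else ()
    )
    return SimConfig(n_snps=n_snps, populations=pops, selected=selected, seed=seed)
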