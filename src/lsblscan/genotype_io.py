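"""Reading, writing, filtering and merging biallelic SNP genotype panels.

Genotypes live in a :class:`GenotypeMatrix`: a samples x SNPs matrix of
allele-A dosages (0, 1, 2) with a single missing sentinel. The on-disk
format is PLINK text PED/MAP; missing genotypes are the PED ``0 0`` pair.
Coordinates are 1-based base-pair positions as in MAP files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Internal missing-genotype sentinel. Never a valid dosage.
MISSING: int = -1


class PedParseError(ValueError):
    """Raised when a PED/MAP file is malformed."""


class NonBiallelicError(ValueError):
    """Raised when a SNP shows more than two distinct alleles."""


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP: identifier, map position and its two alleles.

    ``allele_a`` is the allele counted by the dosage matrix. Orientation is
    arbitrary but deterministic (see :func:`read_ped_map`); every statistic
    downstream (F_ST, LSBL) is invariant to the choice.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1, got {self.pos}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"SNP {self.snp_id}: alleles must differ")


@dataclass
class GenotypeMatrix:
    """Diploid allele-A dosage matrix over named samples and SNPs.

    ``dosage[i, j]`` counts copies of ``snps[j].allele_a`` carried by
    ``samples[i]``; value ``MISSING`` (-1) marks a failed genotype call.
    """

    samples: list[str]
    snps: list[SnpRecord]
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.snps)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp ids")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be in {0, 1, 2, MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def take_snps(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.arange(self.n_snps)[mask_or_index]
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[j] for j in idx],
            dosage=self.dosage[:, idx].copy(),
        )

    def take_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = self.sample_index(sample_ids)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            snps=list(self.snps),
            dosage=self.dosage[idx, :].copy(),
        )


@dataclass
class PopulationAssignment:
    """Mapping from sample id to population label."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for s, p in self.mapping.items():
            if not p:
                raise ValueError(f"sample {s!r} has an empty population label")

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.mapping.values():
            seen.setdefault(p)
        return list(seen)

    def samples_in(self, labels) -> list[str]:
        if isinstance(labels, str):
            labels = {labels}
        labels = set(labels)
        unknown = labels - set(self.mapping.values())
        if unknown:
            raise KeyError(f"unknown population label(s): {sorted(unknown)}")
        return [s for s, p in self.mapping.items() if p in labels]

    def check_covers(self, g: GenotypeMatrix) -> None:
        missing = [s for s in g.samples if s not in self.mapping]
        if missing:
            raise ValueError(f"samples without population label: {missing[:5]}...")


def read_population_assignment(path) -> PopulationAssignment:
    """Read a 2-column TSV (sample_id, population); a header row is allowed."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise PedParseError(f"{path}: expected 2 columns, got {df.shape[1]}")
    rows = df.iloc[:, :2].values.tolist()
    if rows and rows[0][0].lower() in {"sample", "sample_id", "id"}:
        rows = rows[1:]
    return PopulationAssignment(dict((s, p) for s, p in rows))


def write_population_assignment(assign: PopulationAssignment, path) -> None:
    pd.DataFrame(
        {"sample_id": list(assign.mapping), "population": list(assign.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PED/MAP I/O


def _read_map(map_path) -> list[tuple[str, str, int]]:
    out = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise PedParseError(
                    f"{map_path}:{lineno}: expected 4 columns "
                    f"(chrom, snp_id, cM, bp), got {len(fields)}"
                )
            chrom, snp_id, _cm, bp = fields[:4]
            out.append((chrom, snp_id, int(bp)))
    return out


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Parse PLINK text PED/MAP into a :class:`GenotypeMatrix`.

    Allele orientation per SNP: in the first informative genotype the
    lexicographically smaller allele becomes ``allele_a`` when both alleles
    are observed there; a homozygous first observation fixes ``allele_a`` to
    that allele and ``allele_b`` to the next distinct allele seen (placeholder
    ``"0"`` if the SNP is monomorphic in the file). ``"0 0"`` pairs are
    missing. A third distinct allele raises :class:`NonBiallelicError`.
    """
    snp_meta = _read_map(map_path)
    m = len(snp_meta)

    samples: list[str] = []
    rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PedParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns "
                    f"(6 + 2 per SNP), got {len(fields)}"
                )
            samples.append(fields[1])
            geno = fields[6:]
            rows.append([(geno[2 * j], geno[2 * j + 1]) for j in range(m)])

    n = len(samples)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    snps: list[SnpRecord] = []
    for j, (chrom, snp_id, pos) in enumerate(snp_meta):
        allele_a: str | None = None
        allele_b: str | None = None
        for i in range(n):
            x, y = rows[i][j]
            if x == "0" or y == "0":
                continue
            for al in (x, y) if x <= y else (y, x):
                if allele_a is None:
                    allele_a = al
                elif al != allele_a and allele_b is None:
                    allele_b = al
                elif al not in (allele_a, allele_b):
                    raise NonBiallelicError(
                        f"SNP {snp_id}: >2 distinct alleles "
                        f"({allele_a}, {allele_b}, {al})"
                    )
            # keep orientation deterministic: smaller observed allele first
            if allele_b is not None and allele_b < allele_a:
                allele_a, allele_b = allele_b, allele_a
        if allele_a is None:
            allele_a, allele_b = "A", "0"  # fully missing column
        if allele_b is None:
            allele_b = "0"
        snps.append(SnpRecord(snp_id, chrom, pos, allele_a, allele_b))
        for i in range(n):
            x, y = rows[i][j]
            if x == "0" or y == "0":
                continue
            dosage[i, j] = (x == allele_a) + (y == allele_a)

    return GenotypeMatrix(samples=samples, snps=snps, dosage=dosage)


def write_ped_map(g: GenotypeMatrix, out_prefix) -> tuple[str, str]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; missing becomes ``0 0``.

    Round-trips with :func:`read_ped_map` on (samples, snps, dosage).
    """
    ped_path = f"{out_prefix}.ped"
    map_path = f"{out_prefix}.map"
    with open(map_path, "w") as fh:
        for s in g.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")
    pair = {
        2: lambda s: f"{s.allele_a} {s.allele_a}",
        1: lambda s: f"{s.allele_a} {s.allele_b}",
        0: lambda s: f"{s.allele_b} {s.allele_b}",
        MISSING: lambda s: "0 0",
    }
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(g.samples):
            cells = [pair[int(g.dosage[i, j])](s) for j, s in enumerate(g.snps)]
            fh.write(f"FAM{i + 1} {sample} 0 0 0 -9 " + " ".join(cells) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Filtering and merging


def _freqs(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (call rate, allele-A frequency, non-missing chromosome count)."""
    obs = g.dosage != MISSING
    n_chrom = 2 * obs.sum(axis=0)
    a = np.where(g.dosage == MISSING, 0, g.dosage).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, a / np.maximum(n_chrom, 1), np.nan)
    call_rate = obs.mean(axis=0) if g.n_samples else np.zeros(g.n_snps)
    return call_rate, p, n_chrom


def snp_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per SNP over all non-missing chromosomes.

    NaN where every call is missing.
    """
    _, p, _ = _freqs(g)
    return np.minimum(p, 1.0 - p)


def filter_snps(g: GenotypeMatrix, min_call_rate: float, min_maf: float) -> GenotypeMatrix:
    """Keep SNPs with call rate > ``min_call_rate`` and MAF > ``min_maf``.

    Both inequalities are strict, matching array-QC convention (call rate
    above 95%, MAF above 0.05). Sample set and SNP order are unchanged; the
    result may have zero SNPs.
    """
    for name, v in (("min_call_rate", min_call_rate), ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    call_rate, p, _ = _freqs(g)
    maf = np.minimum(p, 1.0 - p)
    keep = (call_rate > min_call_rate) & (np.nan_to_num(maf, nan=-1.0) > min_maf)
    return g.take_snps(keep)


def subset_by_maf(g: GenotypeMatrix, min_maf: float, inclusive: bool = True) -> GenotypeMatrix:
    """Keep SNPs by a MAF threshold, inclusive (>=) or strict (>)."""
    if not 0.0 <= min_maf <= 1.0:
        raise ValueError(f"min_maf must be in [0, 1], got {min_maf}")
    maf = np.nan_to_num(snp_maf(g), nan=-1.0)
    keep = maf >= min_maf if inclusive else maf > min_maf
    return g.take_snps(keep)


def merge_panels(g1: GenotypeMatrix, g2: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two panels with disjoint SNP sets over their shared samples.

    The result has all SNPs of ``g1`` followed by all SNPs of ``g2``, and the
    samples present in both panels in ``g1`` order. Each genotype comes from
    the panel that carries the SNP.
    """
    ids1, ids2 = set(g1.snp_ids()), set(g2.snp_ids())
    clash = ids1 & ids2
    if clash:
        raise ValueError(f"duplicate snp_id across panels: {sorted(clash)[:5]}")
    shared = [s for s in g1.samples if s in set(g2.samples)]
    if not shared:
        raise ValueError("panels share no samples")
    a = g1.take_samples(shared)
    b = g2.take_samples(shared)
    return GenotypeMatrix(
        samples=shared,
        snps=list(a.snps) + list(b.snps),
        dosage=np.hstack([a.dosage, b.dosage]),
    )
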