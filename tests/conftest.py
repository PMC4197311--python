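import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lsblscan import (
    GenotypeMatrix,
    PopulationAssignment,
    PopulationConfig,
    SimConfig,
    SnpRecord,
    simulate_panel,
)


def make_matrix(dosage, chroms=None, positions=None, sample_prefix="s"):
    """GenotypeMatrix from a raw dosage array (use -1 for missing)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    chroms = chroms or ["1"] * m
    positions = positions or [100 * (j + 1) for j in range(m)]
    snps = [
        SnpRecord(f"rs{j + 1}", chroms[j], positions[j], "A", "B") for j in range(m)
    ]
    return GenotypeMatrix(
        samples=[f"{sample_prefix}{i + 1}" for i in range(n)], snps=snps, dosage=dosage
    )


@pytest.fixture
def tiny_panel():
    """3 samples x 2 SNPs with one missing call; dosages hand-chosen."""
    return make_matrix([[2, 1], [1, 0], [-1, 2]])


@pytest.fixture
def sim_small():
    """Three modestly drifted populations, ~1k SNPs, with missingness."""
    cfg = SimConfig(
        n_snps=1_000,
        populations=(
            PopulationConfig("popA", 12, 0.05),
            PopulationConfig("popB", 12, 0.1),
            PopulationConfig("popC", 12, 0.2),
        ),
        missing_rate=0.03,
        seed=11,
    )
    return simulate_panel(cfg)


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(5)
    d = rng.integers(0, 3, size=(20, 60)).astype(np.int8)
    d[rng.random(d.shape) < 0.05] = -1
    return make_matrix(d)


@pytest.fixture
def assignment():
    return PopulationAssignment(
        {f"s{i + 1}": ("left" if i < 10 else "right") for i in range(20)}
    )
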