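"""Shared fixtures: tiny PLINK text fixtures and small simulated populations."""

import numpy as np
import pandas as pd
import pytest

from epigwas import GenotypeMatrix, SimConfig, simulate_population


@pytest.fixture
def tiny_ped_map(tmp_path):
    """3 individuals x 2 SNPs as .ped/.map; genotypes 11, 12, 22 at s1."""
    (tmp_path / "tiny.map").write_text(
        "1\ts1\t0\t1000\n1\ts2\t0\t2000\n"
    )
    (tmp_path / "tiny.ped").write_text(
        "f1 i1 0 0 0 -9 1 1 1 1\n"
        "f2 i2 0 0 0 -9 1 2 1 2\n"
        "f3 i3 0 0 0 -9 2 2 2 2\n"
    )
    return tmp_path / "tiny"


@pytest.fixture
def small_genotypes():
    """Deterministic 12 x 3 genotype matrix built in memory."""
    rng = np.random.default_rng(7)
    codes = rng.integers(0, 3, size=(12, 3)).astype(np.int8)
    snp_map = pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3"],
            "chromosome": ["1", "1", "2"],
            "position_bp": [100, 500, 100],
            "allele1": ["A", "1", "C"],
            "allele2": ["G", "2", "T"],
        }
    )
    return GenotypeMatrix([f"i{k}" for k in range(12)], snp_map, codes)


@pytest.fixture(scope="session")
def sim_population():
    """A small crossbred population shared by read-only tests."""
    cfg = SimConfig(n_individuals=500, n_snps=40, n_chromosomes=2, seed=11)
    return cfg, *simulate_population(cfg)
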