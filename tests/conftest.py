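import numpy as np
import pandas as pd
import pytest

from clineflower import genio, simulate
from clineflower.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_accessions=60, n_snps=500, n_subpops=2,
                            n_causal=2, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    g = simulate.simulate_genotypes(small_config)
    pheno, truth = simulate.simulate_phenotypes(g, small_config)
    return g, pheno, truth


@pytest.fixture(scope="session")
def toy_matrix():
    """5 accessions x 6 SNPs, hand-enterable dosages, no missing."""
    dosage = np.array([
        [0, 2, 1, 0, 2, 0],
        [0, 2, 0, 0, 2, 1],
        [2, 0, 2, 0, 0, 2],
        [2, 0, 1, 0, 0, 2],
        [1, 1, 2, 0, 1, 2],
    ], dtype=float)
    return genio.GenotypeMatrix(
        accession_ids=[f"A{i}" for i in range(5)],
        snp_ids=[f"s{j}" for j in range(6)],
        chrom=["1", "1", "1", "2", "2", "2"],
        pos=[100, 200, 300, 100, 200, 300],
        ref=["A"] * 6,
        alt=["G"] * 6,
        dosage=dosage,
    )


def make_pheno(days_by_accession, n_reps=3, latitude=None, jitter=None):
    """Build a replicate phenotype table from accession -> mean days."""
    rows = []
    for i, (acc, mean) in enumerate(days_by_accession.items()):
        lat = latitude[acc] if latitude else 35.0
        for r in range(n_reps):
            d = mean + (jitter[acc][r] if jitter else 0.0)
            rows.append({"accession": acc, "replicate": r + 1, "environment": 1,
                         "days": d, "flowered": True, "latitude": lat})
    return pd.DataFrame(rows, columns=simulate.PHENO_COLUMNS)
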