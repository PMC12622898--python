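"""Shared study definition for the numbered analysis scripts.

One synthetic study (fixed seed) threads through every step so the numbered
scripts can be run independently and still agree; regeneration is cheap and
deterministic.  Large intermediates (full VCF, full association table) go to
scratch/, small result tables to results/.
"""

from __future__ import annotations

from pathlib import Path

from clineflower import amm, genio, phenostats, simulate
from clineflower.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY_SEED = 20250331
STUDY = SimulationConfig(seed=STUDY_SEED)
# a second, longer-day environment for the ratio/clustering analyses
STUDY_TWO_ENV = SimulationConfig(seed=STUDY_SEED, n_environments=2)


def study_data():
    g = simulate.simulate_genotypes(STUDY)
    pheno, truth = simulate.simulate_phenotypes(g, STUDY)
    ann = simulate.simulate_annotation(STUDY)
    return g, pheno, truth, ann


def scan_inputs():
    """Filtered/imputed panel, kinship and accession-mean phenotype."""
    g, pheno, truth, ann = study_data()
    means = phenostats.accession_means(pheno)
    accs = list(means.accession)
    panel = genio.filter_maf(g, 0.1)
    gs = genio.impute_naive(panel, "mean").take_accessions(accs)
    K = amm.kinship(gs)
    y = means.set_index("accession")["mean_days"]
    return g, panel, gs, K, y, means, truth, ann


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
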