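"""Synthetic clinal genotype/phenotype generator.

Emulates the study design that the downstream analyses assume: ~130 inbred
accessions sampled along a latitudinal cline in 2-3 subpopulations, tens of
thousands of biallelic SNPs on six chromosomes plus an unanchored
"chromosome 0" contig group, a small number of causal flowering-time SNPs
jointly explaining a tunable fraction of phenotypic variance, a polygenic
background giving a high broad-sense heritability, three replicate plants per
accession, an optional second day-length environment with genotype-by-
environment effects, and right-censoring of accessions that never flower
within the observation window (default 200 days).

Population structure follows a Balding-Nichols-style model: each
subpopulation's allele frequency at a SNP is a Beta draw around a shared
ancestral frequency, with divergence controlled by ``fst_like_divergence``
(approximately the expected Hudson Fst between subpopulations).

Variance budget. ``target_causal_r2``, ``polygenic_h2`` and the residual
fraction partition the *single-plant* phenotypic variance; components are
orthogonalised and scaled to their exact sample variances, so the realized
fractions reported in :class:`TruthRecord` are exact and broad-sense
heritability equals ``target_causal_r2 + polygenic_h2`` by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genio
from .genio import GenotypeMatrix, GeneAnnotation

PHENO_COLUMNS = ["accession", "replicate", "environment", "days", "flowered", "latitude"]


class InvalidConfigError(ValueError):
    """Raised when a SimulationConfig is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 132 accessions in 3 latitudinal
    subpopulations, 6 chromosomes plus chromosome "0", 2 causal SNPs jointly
    explaining 60% of single-plant variance, polygenic background bringing
    total genetic variance to 0.9, 3 replicate plants, censoring at 200 days.
    """

    n_accessions: int = 132
    n_snps: int = 5000
    n_chromosomes: int = 6
    chrom_length_bp: int = 45_000_000
    chrom0_fraction: float = 0.05
    n_subpops: int = 3
    fst_like_divergence: float = 0.15
    n_causal: int = 2
    target_causal_r2: float = 0.6
    polygenic_h2: float = 0.3
    n_replicates: int = 3
    residual_sd: float | None = None     # days; None -> derived from budget
    total_sd: float = 35.0               # single-plant phenotypic SD, days
    baseline_days: float = 60.0          # approximate earliest flowering day
    censor_days: float = 200.0
    n_environments: int = 1
    gxe_fraction: float = 0.5
    env_delta_scale: float = 0.5         # env-2 delta as a fraction of the effect
    het_rate: float = 0.02
    missing_rate: float = 0.02
    clinal_causal: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_subpops > self.n_accessions:
            raise InvalidConfigError("n_subpops cannot exceed n_accessions")
        if not (0.0 <= self.fst_like_divergence < 1.0):
            raise InvalidConfigError("fst_like_divergence must be in [0, 1)")
        if self.target_causal_r2 < 0 or self.polygenic_h2 < 0:
            raise InvalidConfigError("variance fractions must be non-negative")
        if self.target_causal_r2 + self.polygenic_h2 > 1.0:
            raise InvalidConfigError(
                "target_causal_r2 + polygenic_h2 must be <= 1 "
                f"(got {self.target_causal_r2 + self.polygenic_h2:.3f})")
        if self.n_causal > self.n_snps:
            raise InvalidConfigError("n_causal cannot exceed n_snps")
        if self.n_replicates < 1:
            raise InvalidConfigError("n_replicates must be >= 1")
        if self.censor_days <= 0:
            raise InvalidConfigError("censor_days must be positive")
        if self.n_environments not in (1, 2):
            raise InvalidConfigError("n_environments must be 1 or 2")
        if not (0.0 <= self.gxe_fraction <= 1.0):
            raise InvalidConfigError("gxe_fraction must be in [0, 1]")

    @property
    def residual_fraction(self) -> float:
        return 1.0 - self.target_causal_r2 - self.polygenic_h2

    def derived_residual_sd(self) -> float:
        if self.residual_sd is not None:
            return self.residual_sd
        return self.total_sd * np.sqrt(max(self.residual_fraction, 0.0))


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset, for parameter-recovery tests."""

    causal_snp_ids: list[str]
    causal_effects: list[float]              # days per alt dose
    env_deltas: dict[str, float]             # env-2 additional effect, days/dose
    subpop_assignment: dict[str, int]
    polygenic_values: dict[str, float]       # days, centered
    var_causal: float                        # days^2, single-plant scale
    var_polygenic: float
    var_residual: float
    target_fractions: dict[str, float]
    realized_mean_scale_fractions: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _distinct_sorted_positions(rng: np.random.Generator, length: int,
                               m: int) -> np.ndarray:
    """m distinct sorted 1-based positions in [1, length] without a full arange."""
    if m > length:
        raise InvalidConfigError("more SNPs than base pairs on a chromosome")
    pos = np.unique(rng.integers(1, length + 1, size=int(m * 1.2) + 16))
    while len(pos) < m:
        extra = rng.integers(1, length + 1, size=m)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=m, replace=False))


def subpop_assignment(config: SimulationConfig) -> np.ndarray:
    """Deterministic balanced subpopulation labels, shared across operations."""
    i = np.arange(config.n_accessions)
    return (i * config.n_subpops) // config.n_accessions


def accession_names(config: SimulationConfig) -> list[str]:
    return [f"ACC-{i + 1:03d}" for i in range(config.n_accessions)]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a structured inbred-panel dosage matrix.

    Balding-Nichols subpopulation frequencies around a uniform ancestral
    frequency; accessions are near-homozygous (het rate ``het_rate``) with a
    ``missing_rate`` fraction of calls dropped.  Positions are strictly
    increasing within each chromosome; chromosome "0" is a short unanchored
    group holding ``chrom0_fraction`` of the SNPs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_acc, n_snp = config.n_accessions, config.n_snps
    n0 = int(round(config.chrom0_fraction * n_snp))
    per_chrom = np.full(config.n_chromosomes, (n_snp - n0) // config.n_chromosomes)
    per_chrom[: (n_snp - n0) % config.n_chromosomes] += 1

    chroms, poss = [], []
    lengths = {"0": max(config.chrom_length_bp // 10, 10 * max(n0, 1))}
    if n0 > 0:
        p0 = _distinct_sorted_positions(rng, lengths["0"], n0)
        chroms.append(np.full(n0, "0", dtype=object))
        poss.append(p0)
    for c in range(1, config.n_chromosomes + 1):
        lengths[str(c)] = config.chrom_length_bp
        m = per_chrom[c - 1]
        p = _distinct_sorted_positions(rng, config.chrom_length_bp, m)
        chroms.append(np.full(m, str(c), dtype=object))
        poss.append(p)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)

    anc = rng.uniform(0.05, 0.95, size=n_snp)
    F = config.fst_like_divergence
    if F > 0:
        a = anc * (1 - F) / F
        b = (1 - anc) * (1 - F) / F
        subfreq = rng.beta(a, b, size=(config.n_subpops, n_snp))
    else:
        subfreq = np.tile(anc, (config.n_subpops, 1))

    subpop = subpop_assignment(config)
    q = subfreq[subpop, :]                         # per accession x SNP alt freq
    dosage = 2.0 * (rng.random((n_acc, n_snp)) < q)
    if config.het_rate > 0:
        het = rng.random((n_acc, n_snp)) < config.het_rate
        dosage[het] = 1.0
    if config.missing_rate > 0:
        dosage[rng.random((n_acc, n_snp)) < config.missing_rate] = np.nan

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n_snp)
    alt_i = (ref_i + rng.integers(1, 4, size=n_snp)) % 4

    return GenotypeMatrix(
        accession_ids=accession_names(config),
        snp_ids=[f"chr{c}_{p}" for c, p in zip(chrom, pos)],
        chrom=chrom,
        pos=pos,
        ref=bases[ref_i],
        alt=bases[alt_i],
        dosage=dosage,
    )


def chromosome_lengths(config: SimulationConfig) -> dict[str, int]:
    out = {str(c): config.chrom_length_bp for c in range(1, config.n_chromosomes + 1)}
    out["0"] = max(config.chrom_length_bp // 10, 10)
    return out


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _pick_causal(g_imp: GenotypeMatrix, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Choose causal SNP indices on chromosomes 1..C with MAF >= 0.1.

    With ``clinal_causal`` the candidates are ranked by the gradient of their
    subpopulation alt-allele frequencies and the causal set is drawn from the
    top tercile, yielding a latitude-aligned but not maximally structure-
    confounded architecture.
    """
    eligible = np.flatnonzero((g_imp.chrom != "0") & (g_imp.maf() >= 0.1))
    if len(eligible) < config.n_causal:
        raise InvalidConfigError("not enough eligible SNPs for the causal set")
    if not config.clinal_causal or config.n_subpops < 2:
        return rng.choice(eligible, size=config.n_causal, replace=False)
    subpop = subpop_assignment(config)
    centers = np.arange(config.n_subpops, dtype=float)
    centers -= centers.mean()
    freq = np.vstack([
        g_imp.dosage[subpop == k][:, eligible].mean(axis=0) / 2.0
        for k in range(config.n_subpops)
    ])
    grad = centers @ freq                      # northward frequency slope
    order = eligible[np.argsort(grad)[::-1]]
    pool = order[: max(len(order) // 3, config.n_causal)]
    return rng.choice(pool, size=config.n_causal, replace=False)


def _center_scale(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center x and rescale to an exact sample variance (0 if target is 0)."""
    x = x - x.mean()
    v = x.var()
    if target_var <= 0 or v == 0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def _residualize(x: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Remove the in-sample projection of x onto the columns of basis."""
    if basis.size == 0:
        return x
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return x - basis @ coef


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate replicate flowering-day phenotypes over a genotype panel.

    Accession genetic value = causal dosages x effects + polygenic term with
    covariance proportional to the realized kinship; each replicate adds
    i.i.d. residual noise.  In a two-environment design a subset of causal
    SNPs carries an additional (delaying) effect in environment 2.  Accessions
    whose accession-mean exceeds ``censor_days`` in an environment are flagged
    non-flowered there, with replicate values masked.
    """
    from .amm import kinship

    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    g_imp = genio.impute_naive(genotypes, mode="mean")
    n = g_imp.n_accessions
    total_var = config.total_sd ** 2

    causal_idx = _pick_causal(g_imp, config, rng)
    # comparable per-locus magnitudes (the MAF spread still differentiates
    # marginal contributions, roughly 2:1 for two loci)
    effects = rng.uniform(0.8, 1.2, size=config.n_causal)
    Gc = g_imp.dosage[:, causal_idx]
    raw = Gc @ effects
    causal_vals = _center_scale(raw, config.target_causal_r2 * total_var)
    if raw.std() > 0 and config.target_causal_r2 > 0:
        effects = effects * np.sqrt(config.target_causal_r2 * total_var / raw.var())
    else:
        effects = np.zeros_like(effects)

    K = kinship(g_imp).K
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    u = L @ rng.standard_normal(n)
    u = _residualize(u, np.column_stack([np.ones(n), Gc]))
    poly_vals = _center_scale(u, config.polygenic_h2 * total_var)

    resid_sd = config.derived_residual_sd()
    R = config.n_replicates
    # accession-level noise means, orthogonal to the genetic components so the
    # realized mean-scale variance fractions are exact
    m = rng.standard_normal(n)
    m = _residualize(m, np.column_stack([np.ones(n), causal_vals, poly_vals]))
    m = _center_scale(m, resid_sd ** 2 / R)

    center = config.baseline_days + 2.0 * config.total_sd
    accession_value = center + causal_vals + poly_vals

    n_gxe = int(round(config.gxe_fraction * config.n_causal))
    gxe_idx = causal_idx[:n_gxe]
    env_delta = config.env_delta_scale * np.abs(effects[:n_gxe])
    env2_shift = g_imp.dosage[:, gxe_idx] @ env_delta if n_gxe else np.zeros(n)

    rows = []
    lat = simulate_latitudes(config)
    for env in range(1, config.n_environments + 1):
        base = accession_value + (env2_shift if env == 2 else 0.0)
        # replicate deviations around the orthogonalised accession noise mean
        dev = rng.standard_normal((n, R)) * resid_sd
        dev = dev - dev.mean(axis=1, keepdims=True)
        days = base[:, None] + m[:, None] + dev
        days = np.maximum(days, 1.0)
        acc_mean = days.mean(axis=1)
        flowered = acc_mean <= config.censor_days
        for i, acc in enumerate(g_imp.accession_ids):
            for r in range(R):
                rows.append({
                    "accession": acc,
                    "replicate": r + 1,
                    "environment": env,
                    "days": days[i, r] if flowered[i] else np.nan,
                    "flowered": bool(flowered[i]),
                    "latitude": lat[i],
                })
    pheno = pd.DataFrame(rows, columns=PHENO_COLUMNS)

    var_resid = resid_sd ** 2
    denom = causal_vals.var() + poly_vals.var() + var_resid
    mean_total = causal_vals.var() + poly_vals.var() + var_resid / R
    truth = TruthRecord(
        causal_snp_ids=[str(s) for s in g_imp.snp_ids[causal_idx]],
        causal_effects=[float(e) for e in effects],
        env_deltas={str(g_imp.snp_ids[j]): float(d)
                    for j, d in zip(gxe_idx, env_delta)},
        subpop_assignment={a: int(k) for a, k in
                           zip(g_imp.accession_ids, subpop_assignment(config))},
        polygenic_values={a: float(v) for a, v in zip(g_imp.accession_ids, poly_vals)},
        var_causal=float(causal_vals.var()),
        var_polygenic=float(poly_vals.var()),
        var_residual=float(var_resid),
        target_fractions={
            "causal": config.target_causal_r2,
            "polygenic": config.polygenic_h2,
            "residual": config.residual_fraction,
        },
        realized_mean_scale_fractions={
            "causal": float(causal_vals.var() / mean_total),
            "polygenic": float(poly_vals.var() / mean_total),
            "residual": float(var_resid / R / mean_total),
            "plant_scale_heritability": float(
                (causal_vals.var() + poly_vals.var()) / denom),
        },
    )
    return pheno, truth


def simulate_latitudes(config: SimulationConfig) -> np.ndarray:
    """Subpopulation center (south to north across Japan) plus uniform jitter.

    Metadata only; never used by inference.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    centers = np.linspace(31.0, 43.0, config.n_subpops)
    sub = subpop_assignment(config)
    return centers[sub] + rng.uniform(-1.5, 1.5, size=config.n_accessions)


# ---------------------------------------------------------------------------
# Annotation and fixtures
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig,
                        genes_per_mbp: float = 60.0) -> GeneAnnotation:
    """Random non-overlapping gene intervals on every chromosome."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    rows = []
    for c, length in chromosome_lengths(config).items():
        n_genes = max(int(genes_per_mbp * length / 1e6), 1)
        pos = 1
        for k in range(n_genes):
            gap = int(rng.exponential(max(length / n_genes, 2000.0)))
            start = pos + gap
            glen = int(rng.uniform(1000, 8000))
            end = start + glen - 1
            if end > length:
                break
            rows.append({
                "gene_id": f"Lj{c}g{len(rows):05d}",
                "chrom": c,
                "start": start,
                "end": end,
                "strand": rng.choice(["+", "-"]),
                "description": "synthetic gene",
            })
            pos = end + 1
    return GeneAnnotation(pd.DataFrame(rows))


def write_fixture(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame,
                  annotation: GeneAnnotation, truth: TruthRecord,
                  dir_path: str | Path,
                  contig_lengths: dict[str, int] | None = None) -> dict[str, Path]:
    """Emit VCF + phenotype TSV + BED genes + truth JSON into a directory.

    Files round-trip losslessly through :mod:`clineflower.genio`.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": d / "genotypes.vcf",
        "pheno": d / "phenotypes.tsv",
        "bed": d / "genes.bed",
        "truth": d / "truth.json",
    }
    genio.write_vcf(genotypes, paths["vcf"], contig_lengths=contig_lengths)
    phenotypes.to_csv(paths["pheno"], sep="\t", index=False)
    genio.write_bed(annotation, paths["bed"])
    paths["truth"].write_text(truth.to_json())
    return paths


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise genio.GenioError(f"phenotype table missing columns: {sorted(missing)}")
    return df
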