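"""Top-SNP variance-explained modelling.

Workflow mirrored here: remove the unanchored chromosome "0", greedily select
the top-k association SNPs subject to pairwise LD r^2 < 0.5 (one
representative per linked set, lowest p first), fit nested OLS models of
accession-mean flowering days on the first m selected dosages (the stepwise
R^2 curve and per-step prediction formulas), and judge the observed R^2
against a permutation null of random SNPs (or SNP combinations) matched on
the exact minor-allele count (MAC) of each selected SNP, drawn from
chromosomes 1..C.  Also provides the genotype-class phenotype comparison and
the genotype-by-latitude export used for geographic interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .amm import AssociationResult, _align_y
from .genio import GenotypeMatrix, InvalidParameterError


class PredictError(ValueError):
    pass


class InfeasibleMatchError(PredictError):
    pass


@dataclass
class LdMatrix:
    snp_ids: list[str]
    r2: np.ndarray

    def lookup(self, a: str, b: str) -> float:
        i, j = self.snp_ids.index(a), self.snp_ids.index(b)
        return float(self.r2[i, j])


def ld_r2(g: GenotypeMatrix, snp_subset: list[str] | None = None) -> LdMatrix:
    """Squared Pearson correlation between dosage columns.

    Zero-variance SNPs are excluded with a warning (their r^2 is undefined).
    """
    snp_ids = list(snp_subset) if snp_subset is not None else list(g.snp_ids)
    idx = g.snp_index(snp_ids)
    D = g.dosage[:, idx]
    if np.isnan(D).any():
        raise PredictError("ld_r2 needs imputed dosages")
    sd = D.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [s for s, k in zip(snp_ids, keep) if not k]
        warnings.warn(f"ld_r2: excluding zero-variance SNPs {dropped}", stacklevel=2)
        snp_ids = [s for s, k in zip(snp_ids, keep) if k]
        D = D[:, keep]
    if D.shape[1] == 0:
        raise PredictError("no polymorphic SNPs in subset")
    r = np.corrcoef(D, rowvar=False)
    r = np.atleast_2d(r)
    return LdMatrix(snp_ids=snp_ids, r2=r * r)


def select_top_snps(
    res: AssociationResult,
    g: GenotypeMatrix,
    k: int = 10,
    r2_threshold: float = 0.5,
    exclude_chroms: tuple[str, ...] = ("0",),
) -> list[str]:
    """Greedy p-value-ordered LD pruning.

    Walk SNPs by ascending p-value; accept one iff its dosage r^2 with every
    already-accepted SNP is below ``r2_threshold``.  Stop at ``k`` accepted.
    Excluded chromosomes (the unanchored group by default) are never
    considered.  Returns fewer than k (with a warning) if the panel runs out.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    t = res.table
    t = t[~t["monomorphic"] & ~t["chrom"].astype(str).isin(exclude_chroms)]
    t = t.sort_values(["p_value", "chrom", "pos"], kind="stable")
    idx_of = {s: i for i, s in enumerate(g.snp_ids)}
    D = g.dosage
    accepted: list[str] = []
    accepted_cols: list[np.ndarray] = []
    for snp in t["snp_id"]:
        col = D[:, idx_of[snp]]
        if col.std() == 0:
            continue
        ok = True
        for other in accepted_cols:
            r = np.corrcoef(col, other)[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(snp)
            accepted_cols.append(col)
            if len(accepted) == k:
                break
    if len(accepted) < k:
        warnings.warn(f"only {len(accepted)} SNPs acceptable at "
                      f"r2<{r2_threshold} (requested {k})", stacklevel=2)
    return accepted


@dataclass
class SnpModel:
    snp_ids: list[str]                       # rank order
    r2_curve: list[float]                    # R^2 for models of size 1..K
    coefficients: list[dict[str, float]]     # per step: intercept + per-SNP betas
    coef_pvalues: list[dict[str, float]]
    formulas: list[str]
    predictions: list[np.ndarray] = field(default_factory=list)
    collinear_steps: list[int] = field(default_factory=list)

    def formula(self, m: int) -> str:
        return self.formulas[m - 1]


def _format_formula(coef: dict[str, float]) -> str:
    terms = [f"{coef['intercept']:.4g}"]
    for name, b in coef.items():
        if name == "intercept":
            continue
        terms.append(f"{'+' if b >= 0 else '-'} {abs(b):.4g}*{name}")
    return "days = " + " ".join(terms)


def stepwise_r2(
    y: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    ranked_snps: list[str],
) -> SnpModel:
    """Nested OLS fits of phenotype on the first m ranked SNP dosages.

    For m = 1..K stores R^2, joint-refit coefficients with two-sided
    p-values, the prediction formula, and fitted values.  A rank-deficient
    step (collinearity the pruning missed) is flagged and fit by minimum
    norm, with p-values NaN.
    """
    import statsmodels.api as sm

    yv = _align_y(y, list(g.accession_ids))
    idx = g.snp_index(ranked_snps)
    D = g.dosage[:, idx]
    if np.isnan(D).any():
        raise PredictError("stepwise_r2 needs imputed dosages")
    n = len(yv)
    if n <= len(ranked_snps) + 1:
        raise PredictError("need more accessions than model parameters")
    model = SnpModel(snp_ids=list(ranked_snps), r2_curve=[], coefficients=[],
                     coef_pvalues=[], formulas=[])
    for m in range(1, len(ranked_snps) + 1):
        X = sm.add_constant(D[:, :m], has_constant="add")
        names = ["intercept"] + list(ranked_snps[:m])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            model.collinear_steps.append(m)
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            fitted = X @ beta
            ssr = float(np.sum((yv - fitted) ** 2))
            sst = float(np.sum((yv - yv.mean()) ** 2))
            r2 = 1.0 - ssr / sst if sst > 0 else 0.0
            pvals = {nm: float("nan") for nm in names}
        else:
            fit = sm.OLS(yv, X).fit()
            beta = fit.params
            fitted = fit.fittedvalues
            r2 = float(fit.rsquared)
            pvals = dict(zip(names, (float(p) for p in fit.pvalues)))
        coef = dict(zip(names, (float(b) for b in beta)))
        model.r2_curve.append(r2)
        model.coefficients.append(coef)
        model.coef_pvalues.append(pvals)
        model.formulas.append(_format_formula(coef))
        model.predictions.append(np.asarray(fitted, dtype=float))
    return model


@dataclass
class MatchedNull:
    template_snp_ids: list[str]
    template_macs: list[int]
    n_draws: int
    r2_null: np.ndarray
    observed_r2: float
    quantiles: dict[float, float]
    p_value: float              # empirical, (r+1)/(n+1)
    seed: int


def matched_permutation_null(
    y: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    template_snps: list[str],
    n_draws: int = 1000,
    seed: int = 0,
    exclude_chroms: tuple[str, ...] = ("0",),
    quantile_levels: tuple[float, ...] = (0.95, 0.99),
) -> MatchedNull:
    """Allele-count-matched permutation null for the top-SNP R^2.

    Each draw samples, for every template SNP, a random SNP from chromosomes
    1..C with *exactly* the template's minor-allele count (without
    replacement within a draw; templates may re-enter their own null), fits
    the same OLS, and records R^2.  The observed model's R^2 is ranked in
    this null with the (r+1)/(n+1) empirical p-value.

    Requires integer dosages (use major-mode imputation first) so MAC
    matching is exact.
    """
    if not g.is_integer_dosage():
        raise InvalidParameterError(
            "matched null needs integer dosages; impute with mode='major'")
    yv = _align_y(y, list(g.accession_ids))
    rng = np.random.default_rng(seed)
    mac = g.mac()
    pool_mask = ~pd.Series(g.chrom).astype(str).isin(exclude_chroms).to_numpy()
    tmpl_idx = g.snp_index(template_snps)
    tmpl_mac = [int(mac[j]) for j in tmpl_idx]
    pools = {}
    for mc in set(tmpl_mac):
        cand = np.flatnonzero(pool_mask & (mac == mc))
        if len(cand) == 0:
            raise InfeasibleMatchError(f"no SNP on chromosomes 1..C has MAC={mc}")
        pools[mc] = cand

    def fit_r2(cols: np.ndarray) -> float:
        X = np.column_stack([np.ones(len(yv)), cols])
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        sst = float(np.sum((yv - yv.mean()) ** 2))
        return 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 0.0

    observed = fit_r2(g.dosage[:, tmpl_idx])
    r2_null = np.empty(n_draws)
    for t in range(n_draws):
        chosen: list[int] = []
        for mc in tmpl_mac:
            cand = pools[mc]
            if len(chosen) > 0:
                cand = cand[~np.isin(cand, chosen)]
            if len(cand) == 0:
                raise InfeasibleMatchError(
                    f"pool exhausted for MAC={mc} within a draw")
            chosen.append(int(rng.choice(cand)))
        r2_null[t] = fit_r2(g.dosage[:, chosen])
    r = int(np.sum(r2_null >= observed))
    return MatchedNull(
        template_snp_ids=list(template_snps),
        template_macs=tmpl_mac,
        n_draws=n_draws,
        r2_null=r2_null,
        observed_r2=observed,
        quantiles={q: float(np.quantile(r2_null, q)) for q in quantile_levels},
        p_value=(r + 1) / (n_draws + 1),
        seed=seed,
    )


def genotype_group_compare(
    y: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    snp_id: str,
    groups: list[str] | None = None,
) -> dict:
    """Phenotype by genotype class at one SNP, with a rank-sum test.

    Classes are ref-homozygote (dose 0), heterozygote (1), alt-homozygote
    (2).  The two-sided Wilcoxon rank-sum test compares the homozygote
    classes; heterozygotes are summarised but excluded from the test.
    ``groups`` restricts to an accession subset (e.g. one subpopulation).
    """
    accs = list(g.accession_ids)
    yv = _align_y(y, accs)
    j = int(g.snp_index([snp_id])[0])
    dose = g.dosage[:, j]
    if groups is not None:
        keep = np.isin(accs, list(groups))
        yv, dose = yv[keep], dose[keep]
    summaries = []
    cls_vals = {}
    for dose_val, name in ((0.0, "ref_hom"), (1.0, "het"), (2.0, "alt_hom")):
        vals = yv[dose == dose_val]
        vals = vals[~np.isnan(vals)]
        cls_vals[name] = vals
        summaries.append({
            "class": name, "n": int(len(vals)),
            "mean_days": float(vals.mean()) if len(vals) else np.nan,
            "median_days": float(np.median(vals)) if len(vals) else np.nan,
            "sd_days": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
        })
    out = {"snp_id": snp_id, "summary": pd.DataFrame(summaries),
           "statistic": np.nan, "p_value": None}
    if len(cls_vals["ref_hom"]) >= 2 and len(cls_vals["alt_hom"]) >= 2:
        stat, p = stats.mannwhitneyu(cls_vals["ref_hom"], cls_vals["alt_hom"],
                                     alternative="two-sided")
        out["statistic"], out["p_value"] = float(stat), float(p)
    else:
        warnings.warn(f"{snp_id}: a homozygote class has <2 accessions; "
                      "test skipped", stacklevel=2)
    return out


def genotype_geography_table(
    g: GenotypeMatrix,
    snp_ids: list[str],
    metadata: pd.DataFrame,
    late_allele: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-accession genotype classes with latitude for geographic export.

    ``metadata`` needs columns accession, latitude.  ``late_allele`` maps
    each SNP to the allele ('ref' or 'alt') carried by late-flowering
    accessions; default 'alt'.  Per-SNP classes are early / het / late; for
    the first two SNPs a combined class (both_early, both_late, mixed, het)
    partitions the accessions as in a two-locus genotype map.
    """
    late_allele = late_allele or {}
    idx = g.snp_index(snp_ids)
    lat = metadata.set_index("accession")["latitude"] if "latitude" in metadata \
        else pd.Series(dtype=float)
    rows = []
    for i, acc in enumerate(g.accession_ids):
        row: dict = {"accession": acc,
                     "latitude": float(lat[acc]) if acc in lat.index
                     and not pd.isna(lat[acc]) else np.nan}
        classes = []
        for s, j in zip(snp_ids, idx):
            d = g.dosage[i, j]
            late_dose = 0.0 if late_allele.get(s, "alt") == "ref" else 2.0
            if np.isnan(d):
                c = "missing"
            elif d == 1.0:
                c = "het"
            elif d == late_dose:
                c = "late"
            else:
                c = "early"
            row[f"class_{s}"] = c
            classes.append(c)
        if len(classes) >= 2:
            c1, c2 = classes[0], classes[1]
            if "missing" in (c1, c2):
                combined = "missing"
            elif "het" in (c1, c2):
                combined = "het"
            elif c1 == c2 == "early":
                combined = "both_early"
            elif c1 == c2 == "late":
                combined = "both_late"
            else:
                combined = "mixed"
            row["combined_class"] = combined
        rows.append(row)
    return pd.DataFrame(rows)
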