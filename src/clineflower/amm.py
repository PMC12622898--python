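"""Accelerated mixed-model (EMMAX-style) association scan.

The phenotype of accession i is modelled as

    y = X beta + u + e,    u ~ N(0, sigma2_g K),    e ~ N(0, sigma2_e I)

with K a VanRaden centered-dosage kinship matrix.  The variance components
are estimated once by REML on the null model (intercept only), then held
fixed for every per-SNP generalized-least-squares test — the "accelerated"
approximation that makes a genome-wide scan a sequence of 2-parameter
weighted regressions after a single eigendecomposition of K.

Per-SNP inference is a Wald F test with 1 and n-2 degrees of freedom on the
dosage coefficient, with the residual scale re-estimated per SNP on the
whitened data.  With K = I this reduces exactly to the classical per-SNP
t-test, which the test suite asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import GenotypeMatrix


class AmmError(ValueError):
    pass


class DegenerateKinshipError(AmmError):
    pass


class OptimizationFailureError(AmmError):
    pass


@dataclass
class KinshipMatrix:
    accession_ids: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.accession_ids)
        if self.K.shape != (n, n):
            raise AmmError("kinship shape does not match accession count")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise AmmError("kinship must be symmetric")

    def align(self, accessions: list[str]) -> "KinshipMatrix":
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        idx = np.array([lookup[a] for a in accessions])
        return KinshipMatrix(list(accessions), self.K[np.ix_(idx, idx)])


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    delta: float                # sigma2_e / sigma2_g
    reml_loglik: float

    @property
    def heritability_ratio(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


@dataclass
class AssociationResult:
    table: pd.DataFrame         # snp_id chrom pos beta se stat p_value neglog10p monomorphic
    n_accessions: int
    n_snps: int
    phenotype_name: str = "trait"

    def to_tsv(self, path) -> None:
        cols = ["snp_id", "chrom", "pos", "beta", "se", "stat", "p_value", "neglog10p"]
        self.table[cols].to_csv(path, sep="\t", index=False)


def kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden centered-dosage kinship: K = Z Z' / sum(2 p (1-p)).

    Columns are centered by twice the alt frequency; monomorphic SNPs
    contribute nothing.  Requires a fully imputed dosage matrix.
    """
    if np.isnan(g.dosage).any():
        raise AmmError("kinship needs imputed dosages (no missing values)")
    p = g.dosage.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise DegenerateKinshipError("all SNPs are monomorphic")
    Z = g.dosage[:, poly] - 2.0 * p[poly]
    norm = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    K = (Z @ Z.T) / norm
    return KinshipMatrix(list(g.accession_ids), K)


def _eig(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s, U = np.linalg.eigh(K)
    if s.min() < -1e-8 * max(s.max(), 1.0):
        raise DegenerateKinshipError("kinship is not positive semidefinite")
    return np.clip(s, 0.0, None), U


def _align_y(y: pd.Series | np.ndarray, accession_ids: list[str]) -> np.ndarray:
    if isinstance(y, pd.Series):
        missing = [a for a in accession_ids if a not in y.index]
        if missing:
            raise AmmError(f"phenotype missing accessions: {missing[:5]}...")
        return y.loc[accession_ids].to_numpy(dtype=float)
    arr = np.asarray(y, dtype=float)
    if len(arr) != len(accession_ids):
        raise AmmError("phenotype length does not match accession count")
    return arr


def fit_null_reml(
    y: pd.Series | np.ndarray,
    K: KinshipMatrix,
    covariates: np.ndarray | None = None,
    log10_delta_range: tuple[float, float] = (-5.0, 5.0),
    n_grid: int = 100,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """One-time REML fit of (sigma2_g, sigma2_e) under the null model.

    Profiles the restricted likelihood over delta = sigma2_e/sigma2_g on a
    log10 grid, then refines the best bracket with bounded Brent search.
    The intercept is always included in the fixed effects.
    """
    yv = _align_y(y, K.accession_ids)
    n = len(yv)
    X = np.ones((n, 1))
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    p = X.shape[1]
    s, U = eig if eig is not None else _eig(K.K)
    yt = U.T @ yv
    Xt = U.T @ X
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)
    if sign <= 0:
        raise AmmError("collinear covariates")

    def reml_ll(log10_delta: float) -> float:
        delta = 10.0 ** log10_delta
        w = 1.0 / (s + delta)
        XtW = Xt * w[:, None]
        XtWX = Xt.T @ XtW
        beta = np.linalg.solve(XtWX, XtW.T @ yt)
        r = yt - Xt @ beta
        rss = float(np.sum(w * r * r))
        if rss <= 0:
            return -np.inf
        sigma_g = rss / (n - p)
        sign2, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign2 <= 0:
            return -np.inf
        return -0.5 * (
            (n - p) * (np.log(2 * np.pi * sigma_g) + 1.0)
            + np.sum(np.log(s + delta))
            + logdet_xwx - logdet_xx
        )

    lo, hi = log10_delta_range
    grid = np.linspace(lo, hi, n_grid)
    lls = np.array([reml_ll(g) for g in grid])
    if not np.isfinite(lls).any():
        raise OptimizationFailureError(
            f"restricted likelihood non-finite everywhere on 10^[{lo},{hi}]")
    i = int(np.nanargmax(np.where(np.isfinite(lls), lls, -np.inf)))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(lambda t: -reml_ll(t), bounds=(a, b),
                                   method="bounded")
    best_t, best_ll = (res.x, -res.fun) if -res.fun >= lls[i] else (grid[i], lls[i])
    delta = 10.0 ** best_t
    w = 1.0 / (s + delta)
    XtW = Xt * w[:, None]
    beta = np.linalg.solve(Xt.T @ XtW, XtW.T @ yt)
    r = yt - Xt @ beta
    sigma_g = float(np.sum(w * r * r)) / (n - p)
    return VarianceComponents(
        sigma2_g=float(sigma_g),
        sigma2_e=float(sigma_g * delta),
        delta=float(delta),
        reml_loglik=float(best_ll),
    )


def scan(
    y: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    K: KinshipMatrix,
    vc: VarianceComponents,
    phenotype_name: str = "trait",
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> AssociationResult:
    """Per-SNP GLS scan with variance components fixed from the null fit.

    Each SNP is tested by regressing the whitened phenotype on the whitened
    [intercept, dosage] design; Wald F with (1, n-2) degrees of freedom.
    SNPs monomorphic in the tested accessions get p = 1 and a flag, keeping
    row alignment for permutation reuse.
    """
    if np.isnan(g.dosage).any():
        raise AmmError("scan needs imputed dosages")
    Kal = K.align(list(g.accession_ids)) if K.accession_ids != list(g.accession_ids) else K
    yv = _align_y(y, list(g.accession_ids))
    n, m = g.dosage.shape
    if n <= 2:
        raise AmmError("need more than 2 accessions")
    s, U = eig if eig is not None else _eig(Kal.K)
    # whitening weights; overall scale cancels in the F statistic but is kept
    w = 1.0 / (vc.sigma2_g * s + vc.sigma2_e)
    sw = np.sqrt(w)
    yt = sw * (U.T @ yv)
    ones_t = sw * U.T.sum(axis=1)            # whitened intercept column
    Gt = sw[:, None] * (U.T @ g.dosage)

    a = float(ones_t @ ones_t)
    b = ones_t @ Gt                          # per-SNP cross terms
    c = np.einsum("ij,ij->j", Gt, Gt)
    x1y = float(ones_t @ yt)
    x2y = yt @ Gt
    yy = float(yt @ yt)
    det = a * c - b * b

    mono = np.nanstd(g.dosage, axis=0) == 0
    degenerate = mono | (det <= 1e-12 * np.maximum(a * c, 1e-300))

    with np.errstate(divide="ignore", invalid="ignore"):
        beta1 = (c * x1y - b * x2y) / det
        beta2 = (a * x2y - b * x1y) / det
        rss = yy - beta1 * x1y - beta2 * x2y
        rss = np.maximum(rss, 0.0)
        s2 = rss / (n - 2)
        var_beta2 = s2 * a / det
        with np.errstate(all="ignore"):
            fstat = beta2 * beta2 / var_beta2
    fstat = np.where(degenerate, 0.0, fstat)
    pvals = stats.f.sf(fstat, 1, n - 2)
    pvals = np.where(degenerate, 1.0, pvals)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    beta2 = np.where(degenerate, 0.0, beta2)
    se = np.where(degenerate, np.nan, np.sqrt(var_beta2))

    table = pd.DataFrame({
        "snp_id": g.snp_ids,
        "chrom": g.chrom,
        "pos": g.pos,
        "beta": beta2,
        "se": se,
        "stat": fstat,
        "p_value": pvals,
        "neglog10p": -np.log10(pvals),
        "monomorphic": degenerate,
    })
    return AssociationResult(table=table, n_accessions=n, n_snps=m,
                             phenotype_name=phenotype_name)


def qq_lambda(res: AssociationResult) -> tuple[float, pd.DataFrame]:
    """Genomic inflation factor and QQ table.

    lambda = median observed chi-square (from p-values, 1 df) divided by the
    chi-square_1 median 0.4549...; the QQ table pairs expected vs observed
    -log10 p for external plotting.
    """
    p = res.table.loc[~res.table["monomorphic"], "p_value"].to_numpy()
    if len(p) < 100:
        raise AmmError("qq_lambda needs >=100 tested SNPs")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
    obs = np.sort(p)
    k = len(obs)
    qq = pd.DataFrame({
        "expected_neglog10p": -np.log10((np.arange(1, k + 1) - 0.5) / k),
        "observed_neglog10p": -np.log10(obs),
    })
    return lam, qq
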