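"""Permutation-based genome-wide significance thresholds.

The family-wise null is built by permuting the phenotype across accessions,
re-fitting the null REML variance components, re-running the full scan, and
recording the maximum -log10 p of each permuted scan.  The alpha-level
threshold is the (1 - alpha) empirical quantile of that maximum, taken as the
ceiling order statistic so it is always an achieved sample value.

Phenotype permutation breaks the phenotype-kinship link, so under strong
structure the null is slightly conservative; see the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import amm
from .genio import GenotypeMatrix


class PermError(ValueError):
    pass


@dataclass
class PermutationNull:
    n_permutations: int
    max_neglog10p: np.ndarray
    thresholds: dict[float, float]
    seed: int

    def __post_init__(self) -> None:
        self.max_neglog10p = np.asarray(self.max_neglog10p, dtype=float)

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "perm_index": np.arange(1, self.n_permutations + 1),
            "max_neglog10p": self.max_neglog10p,
        }).to_csv(path, sep="\t", index=False)


def empirical_threshold(max_values: np.ndarray, alpha: float) -> float:
    """Ceiling (type-1) order statistic: the ceil((1-alpha)*n)-th smallest."""
    x = np.sort(np.asarray(max_values, dtype=float))
    n = len(x)
    k = int(np.ceil((1.0 - alpha) * n))
    k = min(max(k, 1), n)
    return float(x[k - 1])


def permutation_thresholds(
    y: pd.Series | np.ndarray,
    g: GenotypeMatrix,
    K: amm.KinshipMatrix,
    alphas: tuple[float, ...] = (0.05, 0.10),
    n_perm: int = 1000,
    seed: int = 0,
    refit_reml: bool = True,
) -> PermutationNull:
    """Maximum-statistic permutation null for a mixed-model scan.

    Each permutation shuffles phenotype values over accessions (after sorting
    accessions by ID, so thresholds are invariant to joint input reordering),
    re-fits REML unless ``refit_reml=False`` (the fast mode reuses the
    observed-data components), and records the scan maximum -log10 p.
    """
    if n_perm < 20:
        raise PermError("n_perm must be >= 20")
    for a in alphas:
        if n_perm < 1.0 / a:
            warnings.warn(f"n_perm={n_perm} < 1/alpha={1 / a:.0f}: "
                          "quantile estimate unstable", stacklevel=2)
    order = sorted(range(g.n_accessions), key=lambda i: g.accession_ids[i])
    accs = [g.accession_ids[i] for i in order]
    gs = g.take_accessions(accs)
    Ks = K.align(accs)
    yv = amm._align_y(y, accs)
    eig = amm._eig(Ks.K)
    vc0 = amm.fit_null_reml(yv, Ks, eig=eig)

    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for t in range(n_perm):
        yp = yv[rng.permutation(len(yv))]
        vc = amm.fit_null_reml(yp, Ks, eig=eig) if refit_reml else vc0
        res = amm.scan(yp, gs, Ks, vc, eig=eig)
        maxima[t] = float(res.table["neglog10p"].max())
    thresholds = {float(a): empirical_threshold(maxima, a) for a in alphas}
    return PermutationNull(n_permutations=n_perm, max_neglog10p=maxima,
                           thresholds=thresholds, seed=seed)


def call_significant(res: amm.AssociationResult, null: PermutationNull,
                     alpha: float) -> pd.DataFrame:
    """SNPs whose -log10 p strictly exceeds the alpha-level threshold."""
    if float(alpha) not in null.thresholds:
        raise PermError(f"alpha={alpha} not among computed thresholds "
                        f"{sorted(null.thresholds)}")
    thr = null.thresholds[float(alpha)]
    out = res.table[res.table["neglog10p"] > thr].copy()
    out.attrs["alpha"] = float(alpha)
    out.attrs["threshold"] = thr
    return out.reset_index(drop=True)
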