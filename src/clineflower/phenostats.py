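"""Accession-level phenotype construction and descriptive statistics.

Replicate flowering-day records are collapsed to accession means (dropping or
sentinel-censoring non-flowered accessions), compared across day-length
environments as ratios, and summarised by a one-way random-effects ANOVA
broad-sense heritability, a Pearson latitude correlation, and a k-means
clustering of paired-condition flowering times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class PhenoError(ValueError):
    pass


class InvalidParameterError(PhenoError):
    pass


def accession_means(pheno: pd.DataFrame, drop_nonflowered: bool = True,
                    censor_value: float | None = None) -> pd.DataFrame:
    """Collapse replicate rows to one row per accession.

    Non-flowered accessions are excluded by default (the primary analysis
    mode); with ``drop_nonflowered=False`` they are assigned ``censor_value``
    (250 days in the sensitivity analysis this mirrors).

    Returns columns ``accession, mean_days, n_replicates, flowered, latitude``.
    """
    if not drop_nonflowered and censor_value is None:
        raise InvalidParameterError(
            "censor mode requires an explicit censor_value (e.g. 250)")
    if pheno.empty:
        raise PhenoError("empty phenotype table")
    rows = []
    for acc, grp in pheno.groupby("accession", sort=False):
        flowered = bool(grp["flowered"].iloc[0])
        lat = grp["latitude"].iloc[0] if "latitude" in grp.columns else np.nan
        if flowered:
            vals = grp["days"].dropna()
            if len(vals) == 0:
                raise PhenoError(f"accession {acc} flagged flowered but has no days")
            rows.append((acc, float(vals.mean()), int(len(vals)), True, lat))
        elif not drop_nonflowered:
            rows.append((acc, float(censor_value), 0, False, lat))
    return pd.DataFrame(rows, columns=["accession", "mean_days", "n_replicates",
                                       "flowered", "latitude"])


def flowering_ratio(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Per-accession ratio of mean flowering days, environment A over B.

    Defined on the intersection of accessions that flowered in both tables
    (``n_common`` attribute records its size).
    """
    am = a.set_index("accession")["mean_days"]
    bm = b.set_index("accession")["mean_days"]
    common = am.index.intersection(bm.index)
    if len(common) == 0:
        raise PhenoError("no accession flowered in both environments")
    out = pd.DataFrame({
        "accession": common,
        "ratio": (am.loc[common] / bm.loc[common]).to_numpy(),
    })
    out.attrs["n_common"] = int(len(common))
    return out


def broad_sense_heritability(pheno: pd.DataFrame) -> float:
    """Broad-sense heritability from one-way random-effects ANOVA.

    H^2 = sigma2_between / (sigma2_between + sigma2_within), with
    sigma2_between = max(0, (MSB - MSW) / n_bar) and n_bar the harmonic mean
    replicate count (robust to unbalanced replicate loss).  Clipped to [0, 1].
    """
    groups = [grp["days"].dropna().to_numpy()
              for _, grp in pheno[pheno["flowered"]].groupby("accession", sort=False)]
    groups = [g for g in groups if len(g) >= 1]
    multi = [g for g in groups if len(g) >= 2]
    if len(groups) < 2 or not multi:
        raise PhenoError("heritability needs >=2 accessions and replicated accessions")
    k = len(groups)
    n_i = np.array([len(g) for g in groups], dtype=float)
    N = n_i.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    msb = ssb / (k - 1)
    msw = ssw / (N - k) if N > k else 0.0
    n_bar = stats.hmean(n_i)
    sigma_b = max(0.0, (msb - msw) / n_bar)
    denom = sigma_b + msw
    if denom == 0:
        return 0.0
    return float(np.clip(sigma_b / denom, 0.0, 1.0))


def latitude_correlation(means: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of accession mean flowering days vs latitude.

    Returns (r, two-sided p).  Requires >=3 accessions with both values and
    non-constant inputs.
    """
    sub = means.dropna(subset=["mean_days", "latitude"])
    if len(sub) < 3:
        raise PhenoError("need >=3 accessions with latitude and mean days")
    x = sub["latitude"].to_numpy(float)
    y = sub["mean_days"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PhenoError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class KmeansResult:
    labels: pd.Series           # indexed by accession
    centroids: np.ndarray       # k x 2, (days_a, days_b)
    sizes: np.ndarray
    inertia: float


def kmeans_pairs(a: pd.DataFrame, b: pd.DataFrame, k: int = 2,
                 n_init: int = 10, seed: int = 0) -> KmeansResult:
    """k-means on paired accession means (days_a, days_b).

    Raw day scales (shared units, no standardisation), squared Euclidean
    distance, ``n_init`` restarts with best-objective selection; labels are
    deterministic given the seed.
    """
    from sklearn.cluster import KMeans

    am = a.set_index("accession")["mean_days"]
    bm = b.set_index("accession")["mean_days"]
    common = am.index.intersection(bm.index)
    X = np.column_stack([am.loc[common].to_numpy(), bm.loc[common].to_numpy()])
    if k < 1 or k > len(common):
        raise InvalidParameterError(f"k must be in [1, {len(common)}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    labels = pd.Series(km.labels_, index=common, name="cluster")
    sizes = np.bincount(km.labels_, minlength=k)
    return KmeansResult(labels=labels, centroids=km.cluster_centers_,
                        sizes=sizes, inertia=float(km.inertia_))
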