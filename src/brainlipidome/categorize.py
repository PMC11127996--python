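"""Five-category lipid classification against regional myelin content.

The classification protocol runs in two branches on a normalized lipids x
samples matrix:

1. Lipids with significant intensity differences among regions (one-way
   ANOVA, BH-adjusted p < ``anova_alpha``) are regressed (per-region mean
   intensity, ordinary least squares) on the regions' myelin content
   (T1w/T2w ratio): a significant positive slope (BH-adjusted p <
   ``myelin_alpha``) makes the lipid *myelin+*, a significant negative slope
   *myelin-*, and the rest are *unexplained*.
2. Lipids without regional differences are split on their within-region
   (inter-individual) variability at mu + sigma of the Gaussian component of
   that variability distribution: *housekeeping* below the threshold,
   *variable* above.

Also provided: cross-dataset profile-correlation permutation nulls,
category-concordance scoring between two datasets, and the Fisher-exact
validation of myelin+/- categories against an external white-vs-gray-matter
differential table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from .stats import bh_adjust, fisher_2x2, rank_tests

__all__ = [
    "CATEGORIES",
    "anova_region",
    "region_profiles",
    "myelin_model",
    "within_region_variability",
    "gaussian_threshold",
    "classify_lipids",
    "profile_null_correlation",
    "category_concordance",
    "wm_gm_fisher_validation",
]

CATEGORIES = ("myelin_pos", "myelin_neg", "unexplained", "housekeeping",
              "variable")


def _region_groups(columns: pd.Index, meta: pd.DataFrame) -> dict:
    regions = meta.loc[columns, "region_id"]
    return {r: np.asarray([columns.get_loc(c) for c in cols])
            for r, cols in regions.groupby(regions).groups.items()}


def anova_region(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per lipid across regions (individuals as
    replicates), BH-adjusted over lipids.  Model: lipid ~ region."""
    groups = _region_groups(matrix.columns, meta)
    if len(groups) < 2:
        raise ValueError("need >=2 regions for ANOVA")
    x = matrix.to_numpy(dtype=float)
    n_total = x.shape[1]
    k = len(groups)
    if n_total - k <= 0:
        raise ValueError("no within-region replication: every region has a "
                         "single sample")
    grand = x.mean(axis=1)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    for idx in groups.values():
        sub = x[:, idx]
        gm = sub.mean(axis=1)
        ssb += idx.size * (gm - grand) ** 2
        ssw += ((sub - gm[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = sps.f.sf(f, df_b, df_w)
    p = np.where(np.isnan(f), 1.0, p)  # zero within+between variance
    p = np.where(np.isinf(f), 0.0, p)
    return pd.DataFrame(
        {"F": f, "p": p, "p_adj": bh_adjust(p)}, index=matrix.index
    )


def region_profiles(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-region mean intensity profiles (averaged over individuals):
    lipids x regions."""
    regions = meta.loc[matrix.columns, "region_id"].to_numpy()
    return matrix.T.groupby(regions).mean().T


def myelin_model(profiles: pd.DataFrame, myelin: pd.Series) -> pd.DataFrame:
    """OLS of each lipid's per-region mean intensity on myelin content.

    Returns slope and the two-sided slope p-value per lipid.
    """
    shared = [r for r in profiles.columns if r in myelin.index]
    if len(shared) < 3:
        raise ValueError("need >=3 regions with myelin values")
    m = myelin.loc[shared].to_numpy(dtype=float)
    if np.ptp(m) == 0:
        raise ValueError("myelin content is constant across regions")
    y = profiles[shared].to_numpy(dtype=float)
    mc = m - m.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (mc ** 2).sum()
    slope = yc @ mc / sxx
    n = len(shared)
    resid = yc - np.outer(slope, mc)
    sigma2 = (resid ** 2).sum(axis=1) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(sigma2 / sxx)
    p = 2 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.isinf(t) | np.isnan(p), np.where(slope == 0, 1.0, 0.0), p)
    return pd.DataFrame({"myelin_slope": slope, "myelin_p": p},
                        index=profiles.index)


def within_region_variability(matrix: pd.DataFrame,
                              meta: pd.DataFrame) -> pd.Series:
    """Pooled standard deviation of residuals after removing per-region means.

    Captures inter-individual variability within regions; invariant to any
    region-level offsets.
    """
    groups = _region_groups(matrix.columns, meta)
    x = matrix.to_numpy(dtype=float)
    n, k = x.shape[1], len(groups)
    if n - k <= 0:
        raise ValueError("within-region variability needs >=2 individuals "
                         "per region")
    ssw = np.zeros(x.shape[0])
    for idx in groups.values():
        sub = x[:, idx]
        ssw += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return pd.Series(np.sqrt(ssw / (n - k)), index=matrix.index,
                     name="within_region_variability")


def gaussian_threshold(values, method: str = "robust") -> float:
    """mu + sigma of the Gaussian component of a value distribution.

    ``robust`` (default): mu = median, sigma = 1.4826 * MAD, which tracks the
    dominant mode and ignores a heavy right tail.  ``mixture``: two-component
    Gaussian mixture, taking the lower-mean component.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValueError("gaussian_threshold needs >=10 values")
    if np.ptp(v) == 0:
        return float(v[0])
    if method == "robust":
        mu = float(np.median(v))
        sigma = 1.4826 * float(np.median(np.abs(v - mu)))
        return mu + sigma
    if method == "mixture":
        gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
        gm.fit(v[:, None])
        lo = int(np.argmin(gm.means_.ravel()))
        return float(gm.means_.ravel()[lo]
                     + np.sqrt(gm.covariances_.ravel()[lo]))
    raise ValueError(f"unknown method {method!r}")


def classify_lipids(matrix: pd.DataFrame, meta: pd.DataFrame,
                    region_meta: pd.DataFrame, anova_alpha: float = 0.01,
                    myelin_alpha: float = 0.05,
                    gaussian_method: str = "robust",
                    per_sample_myelin_fit: bool = False) -> pd.DataFrame:
    """Assign every lipid to one of the five profile categories.

    ``matrix`` must be a normalized lipids x samples table; ``meta`` maps
    samples to regions/individuals; ``region_meta`` carries the per-region
    ``myelin`` values.  BH correction for the myelin model is applied within
    the ANOVA-selected subset.  Deterministic given inputs; the categories
    partition the lipid set.
    """
    anova = anova_region(matrix, meta)
    selected = anova.index[anova["p_adj"] < anova_alpha]
    rest = anova.index.difference(selected, sort=False)

    result = pd.DataFrame(
        index=matrix.index,
        columns=["category", "anova_p_adj", "myelin_slope", "myelin_p_adj",
                 "within_region_variability"],
    )
    result["anova_p_adj"] = anova["p_adj"]
    result["within_region_variability"] = within_region_variability(matrix,
                                                                    meta)

    if len(selected):
        if per_sample_myelin_fit:
            prof = matrix
            mm_meta = meta.loc[matrix.columns, "region_id"]
            myelin = region_meta["myelin"].loc[mm_meta.to_numpy()]
            myelin.index = matrix.columns
            mm = myelin_model(prof.loc[selected], myelin)
        else:
            prof = region_profiles(matrix, meta)
            mm = myelin_model(prof.loc[selected], region_meta["myelin"])
        mm["myelin_p_adj"] = bh_adjust(mm["myelin_p"])
        result.loc[selected, "myelin_slope"] = mm["myelin_slope"]
        result.loc[selected, "myelin_p_adj"] = mm["myelin_p_adj"]
        sig = mm["myelin_p_adj"] < myelin_alpha
        result.loc[selected, "category"] = np.where(
            sig & (mm["myelin_slope"] > 0), "myelin_pos",
            np.where(sig & (mm["myelin_slope"] < 0), "myelin_neg",
                     "unexplained"),
        )

    if len(rest):
        wrv = result.loc[rest, "within_region_variability"].astype(float)
        thr = gaussian_threshold(wrv.to_numpy(), method=gaussian_method)
        result.loc[rest, "category"] = np.where(wrv <= thr, "housekeeping",
                                                "variable")
    return result


def profile_null_correlation(dataset_a: pd.DataFrame, dataset_b: pd.DataFrame,
                             n_perm: int = 1000, seed: int | None = None):
    """Per-lipid cross-dataset profile correlations vs a permuted-label null.

    Both datasets are lipids x regions over shared lipids and regions.  The
    null permutes B's region labels ``n_perm`` times; the returned p is a
    one-sided paired rank test of the true correlations against each lipid's
    median null correlation.
    """
    lipids = dataset_a.index.intersection(dataset_b.index)
    regions = dataset_a.columns.intersection(dataset_b.columns)
    if len(regions) < 3:
        raise ValueError("need >=3 shared regions")
    a = dataset_a.loc[lipids, regions].to_numpy(dtype=float)
    b = dataset_b.loc[lipids, regions].to_numpy(dtype=float)

    def _rows_r(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        uc = u - u.mean(axis=1, keepdims=True)
        vc = v - v.mean(axis=1, keepdims=True)
        denom = np.sqrt((uc ** 2).sum(axis=1) * (vc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return (uc * vc).sum(axis=1) / denom

    true_r = _rows_r(a, b)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(lipids)))
    for i in range(n_perm):
        null[i] = _rows_r(a, b[:, rng.permutation(len(regions))])
    med_null = np.median(null, axis=0)
    test = rank_tests(true_r, med_null, alternative="greater", paired=True)
    return (pd.Series(true_r, index=lipids, name="r"),
            pd.DataFrame(null, columns=lipids), test)


def category_concordance(result_a: pd.DataFrame, result_b: pd.DataFrame,
                         anova_alpha: float = 0.01) -> pd.Series:
    """Good / neutral / bad concordance of category calls between datasets.

    good: same category.  neutral: different categories, but the lipid shows
    no significant regional differences (ANOVA) in at least one dataset.
    bad: different categories with regional significance in both.
    Lipids absent from either result are excluded (reported via the series'
    ``attrs['n_excluded']``).
    """
    shared = result_a.index.intersection(result_b.index)
    out = pd.Series(index=shared, dtype=object, name="concordance")
    same = result_a.loc[shared, "category"] == result_b.loc[shared, "category"]
    nonsig_any = (
        (result_a.loc[shared, "anova_p_adj"] >= anova_alpha)
        | (result_b.loc[shared, "anova_p_adj"] >= anova_alpha)
    )
    out[same] = "good"
    out[~same & nonsig_any] = "neutral"
    out[~same & ~nonsig_any] = "bad"
    out.attrs["n_excluded"] = (
        len(result_a.index.union(result_b.index)) - len(shared)
    )
    return out


def wm_gm_fisher_validation(external_de: pd.DataFrame,
                            categories: pd.Series, fc_threshold: float = 2.0,
                            alpha: float = 0.05):
    """Fisher-exact association of myelin+/- calls with external white-vs-gray
    differential intensities.

    ``external_de`` needs columns ``log10_diff`` (white minus gray, log10
    scale) and ``p_adj``.  Lipids passing both the adjusted-p and fold-change
    gates and categorized myelin_pos/myelin_neg enter a 2x2 table of
    difference sign x category; returns ``(TestResult or None, table)`` with
    ``None`` when no testable lipids remain.
    """
    lfc = np.log10(fc_threshold)
    passing = external_de[(external_de["p_adj"] < alpha)
                          & (external_de["log10_diff"].abs() >= lfc)]
    cats = categories.reindex(passing.index)
    mask = cats.isin(["myelin_pos", "myelin_neg"])
    passing, cats = passing[mask], cats[mask]
    table = np.zeros((2, 2), dtype=int)
    up = passing["log10_diff"] > 0
    table[0, 0] = int((up & (cats == "myelin_pos")).sum())
    table[0, 1] = int((up & (cats == "myelin_neg")).sum())
    table[1, 0] = int((~up & (cats == "myelin_pos")).sum())
    table[1, 1] = int((~up & (cats == "myelin_neg")).sum())
    if table.sum() == 0:
        return None, table
    return fisher_2x2(table), table
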