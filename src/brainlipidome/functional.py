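"""Association of lipid profiles with brain functional architecture.

Covers principal-component anchors of the regional lipidome, the cortical
processing-hierarchy linear model (levels 1-4: primary, secondary,
associative, limbic), chemical-property binomial tests on hierarchy-associated
lipid sets, the outer-product Mantel test against the functional-connectivity
(FC) matrix, per-category/class comparisons of Mantel correlations, FC
principal components, and region hierarchical clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch

from .stats import bh_adjust, permutation_engine, rank_tests

__all__ = [
    "pca_scores",
    "myelin_pc_correlation",
    "hr_association",
    "hr_property_tests",
    "fc_mantel",
    "fc_mantel_batch",
    "fc_category_comparison",
    "fc_pc1",
    "cluster_regions",
    "read_fc_matrix",
]


def read_fc_matrix(path, region_map: pd.Series | None = None) -> pd.DataFrame:
    """Read a square FC CSV (region ids as header/index).

    ``region_map`` optionally maps FC parcel ids to atlas region ids; when
    several parcels map to one region their connectivity values are averaged.
    """
    fc = pd.read_csv(path, index_col=0)
    fc.columns = fc.columns.astype(str)
    fc.index = fc.index.astype(str)
    if region_map is not None:
        fc = fc.groupby(region_map.reindex(fc.index)).mean()
        fc = fc.T.groupby(region_map.reindex(fc.columns)).mean().T
    _check_fc(fc)
    return fc


def _check_fc(fc: pd.DataFrame) -> None:
    if fc.shape[0] != fc.shape[1] or list(fc.index) != list(fc.columns):
        raise ValueError("FC matrix must be square with matching region ids")
    if not np.allclose(fc.to_numpy(), fc.to_numpy().T, atol=1e-8):
        raise ValueError("FC matrix must be symmetric")


def pca_scores(profiles: pd.DataFrame, n_components: int = 5,
               orient_by: pd.Series | None = None):
    """Principal-component scores of a regions x lipids profile matrix.

    Columns (lipids) are mean-centered before the decomposition.  Sign
    convention: each component is oriented to correlate positively with
    ``orient_by`` (e.g. myelin content) when given, otherwise so that its
    largest-magnitude loading is positive.  Returns (scores DataFrame,
    explained variance ratios).
    """
    if profiles.shape[0] < 2:
        raise ValueError("need >=2 regions for PCA")
    x = profiles.to_numpy(dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        if orient_by is not None:
            anchor = orient_by.reindex(profiles.index).to_numpy(dtype=float)
            if np.corrcoef(scores[:, j], anchor)[0, 1] < 0:
                scores[:, j] *= -1
        elif vt[j, np.argmax(np.abs(vt[j]))] < 0:
            scores[:, j] *= -1
    evr = (s ** 2) / (s ** 2).sum()
    return (pd.DataFrame(scores, index=profiles.index,
                         columns=[f"PC{i + 1}" for i in range(k)]),
            evr[:k])


def myelin_pc_correlation(pc: pd.Series, myelin: pd.Series):
    """Pearson correlation between a PC score vector and myelin content."""
    shared = pc.index.intersection(myelin.index)
    r, p = sps.pearsonr(pc.loc[shared], myelin.loc[shared])
    return float(r), float(p)


def hr_association(profiles: pd.DataFrame, hr_levels: pd.Series,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-lipid OLS of region-mean intensity on the numeric hierarchy level.

    ``hr_levels`` maps cortical regions to levels 1-4.  Returns slope, p,
    BH-adjusted p and the hierarchy set label: ``HR+`` (significant positive
    slope), ``HR-`` (negative) or "" (non-significant).
    """
    levels = hr_levels.dropna()
    regions = profiles.columns.intersection(levels.index)
    lv = levels.loc[regions].to_numpy(dtype=float)
    if np.unique(lv).size < 2:
        raise ValueError("need >=2 distinct hierarchy levels")
    y = profiles[regions].to_numpy(dtype=float)
    lc = lv - lv.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (lc ** 2).sum()
    slope = yc @ lc / sxx
    n = len(regions)
    resid = yc - np.outer(slope, lc)
    sigma2 = (resid ** 2).sum(axis=1) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(sigma2 / sxx)
    p = 2 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.isinf(t), 0.0, np.where(np.isnan(p), 1.0, p))
    out = pd.DataFrame({"hr_slope": slope, "p": p, "p_adj": bh_adjust(p)},
                       index=profiles.index)
    out["hr_set"] = ""
    out.loc[(out["p_adj"] < alpha) & (out["hr_slope"] > 0), "hr_set"] = "HR+"
    out.loc[(out["p_adj"] < alpha) & (out["hr_slope"] < 0), "hr_set"] = "HR-"
    return out


def hr_property_tests(hr_sets: dict[str, list], annotations: pd.DataFrame,
                      properties: list[str] | None = None) -> pd.DataFrame:
    """Binomial tests of chemical-property prevalence in HR lipid sets.

    For every set and every boolean/categorical property column of
    ``annotations`` (lipid class allocation, residue unsaturation flags,
    omega-3/omega-6 prevalence, ...), the prevalence of each property value
    in the set is tested against its background prevalence among all lipids
    (two-sided exact binomial test), BH-corrected per family.
    """
    properties = properties or list(annotations.columns)
    rows = []
    for set_name, lipids in hr_sets.items():
        lipids = [l for l in lipids if l in annotations.index]
        if not lipids:
            continue
        for prop in properties:
            col = annotations[prop]
            values = ([True] if col.dtype == bool
                      else sorted(col.dropna().unique()))
            for val in values:
                p0 = float((col == val).mean())
                if p0 in (0.0, 1.0):
                    continue
                k = int((col.loc[lipids] == val).sum())
                res = sps.binomtest(k, len(lipids), p0,
                                    alternative="two-sided")
                rows.append((set_name, prop, val, k, len(lipids), p0,
                             res.pvalue))
    out = pd.DataFrame(rows, columns=["set", "property", "value", "hits",
                                      "set_size", "background_prevalence",
                                      "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"])
    return out


def _triangle(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def fc_mantel(profile: pd.Series, fc: pd.DataFrame, n_perm: int = 999,
              seed: int | None = None):
    """Mantel test of a lipid's outer-product matrix against the FC matrix.

    The lipid's region vector v (restricted to FC-covered regions) is turned
    into the similarity matrix v v^T; the statistic is the Pearson
    correlation of the upper off-diagonal triangles of v v^T and FC.  The
    null permutes region labels; one-sided (greater), add-one convention
    (exhaustive for <=7 regions).  Returns (r, p).
    """
    _check_fc(fc)
    regions = [r for r in fc.index if r in profile.index]
    if len(regions) < 4:
        raise ValueError("need >=4 FC-covered regions")
    v = profile.loc[regions].to_numpy(dtype=float)
    f = fc.loc[regions, regions].to_numpy(dtype=float)
    ft = _triangle(f)
    ftc = ft - ft.mean()
    denom_f = np.sqrt((ftc ** 2).sum())

    def stat(perm: np.ndarray) -> float:
        vt = _triangle(np.outer(v[perm], v[perm]))
        vtc = vt - vt.mean()
        denom = np.sqrt((vtc ** 2).sum()) * denom_f
        if denom == 0:
            return 0.0
        return float(vtc @ ftc / denom)

    obs, _null, p, _mode = permutation_engine(
        stat, len(regions), n_perm, seed=seed, alternative="greater"
    )
    return obs, p


def fc_mantel_batch(profiles: pd.DataFrame, fc: pd.DataFrame,
                    n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Vectorized Mantel tests for many lipids against one FC matrix.

    One shared set of ``n_perm`` region-label permutations is used across
    lipids.  Same statistic and one-sided add-one p as :func:`fc_mantel`.
    """
    _check_fc(fc)
    regions = [r for r in fc.index if r in profiles.columns]
    if len(regions) < 4:
        raise ValueError("need >=4 FC-covered regions")
    nr = len(regions)
    x = profiles[regions].to_numpy(dtype=float)
    f = fc.loc[regions, regions].to_numpy(dtype=float)
    ft = _triangle(f)
    ftc = ft - ft.mean()
    denom_f = np.sqrt((ftc ** 2).sum())
    iu = np.triu_indices(nr, k=1)

    def batch_r(vecs: np.ndarray) -> np.ndarray:
        # vecs: lipids x regions -> r over outer-product triangles
        tri = vecs[:, iu[0]] * vecs[:, iu[1]]
        tric = tri - tri.mean(axis=1, keepdims=True)
        denom = np.sqrt((tric ** 2).sum(axis=1)) * denom_f
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (tric @ ftc) / denom
        return np.nan_to_num(r, nan=0.0)

    obs = batch_r(x)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[0], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(nr)
        exceed += batch_r(x[:, perm]) >= obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    return pd.DataFrame({"mantel_r": obs, "mantel_p": p},
                        index=profiles.index)


def fc_category_comparison(mantel_r: pd.Series, groups: pd.Series,
                           alternative: str = "greater") -> pd.DataFrame:
    """One-sided rank test of each group's Mantel correlations vs the rest.

    Groups with fewer than two members are skipped; BH correction over the
    tested family.
    """
    shared = mantel_r.index.intersection(groups.index)
    r = mantel_r.loc[shared]
    g = groups.loc[shared]
    if g.nunique() < 2:
        raise ValueError("need >=2 groups")
    rows = []
    for name in g.dropna().unique():
        mask = g == name
        if int(mask.sum()) < 2 or int((~mask).sum()) < 2:
            continue
        res = rank_tests(r[mask], r[~mask], alternative=alternative)
        rows.append((name, int(mask.sum()), float(np.median(r[mask])),
                     res.statistic, res.p))
    out = pd.DataFrame(rows, columns=["group", "n", "median_r", "U", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"])
    return out


def fc_pc1(fc: pd.DataFrame, orient_by: pd.Series | None = None) -> pd.Series:
    """First principal component of the FC matrix (rows as region vectors).

    Oriented to correlate positively with ``orient_by`` when given (the
    conventional anchor is the lipidome PC2), otherwise by the
    largest-magnitude loading.
    """
    _check_fc(fc)
    scores, _ = pca_scores(fc, n_components=1, orient_by=orient_by)
    return scores["PC1"]


def cluster_regions(profiles: pd.DataFrame):
    """Hierarchical clustering of regions (Euclidean distance, complete
    linkage).  Returns (linkage matrix, leaf order as region ids)."""
    z = sch.linkage(profiles.to_numpy(dtype=float), method="complete",
                    metric="euclidean")
    order = sch.leaves_list(z)
    return z, [profiles.index[i] for i in order]
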