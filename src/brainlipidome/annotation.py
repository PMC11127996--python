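"""Automated LC-MS lipid annotation.

Consumes peak tables (m/z, retention time, per-sample intensities) and
produces candidate annotations against a theoretical m/z grid, then filters
them the way the untargeted procedure does: duplicate-peak collapse,
retention-time windowing, ppm matching, chromatographic grid-consistency
filtering (retention time should increase with chain carbons within a class
and decrease with added double bonds), cross-polarity validation, and
retention-time-warped matching between datasets.

Peak tables are pandas DataFrames with columns ``peak_id``, ``mz``, ``rt``
(minutes), ``polarity`` and one column per sample.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import HuberRegressor

from .chem import LipidClassSpec, LipidSpecies, default_registry, monoisotopic_mass

__all__ = [
    "PEAK_COLUMNS",
    "intensity_columns",
    "dedupe_peaks",
    "rt_window_filter",
    "build_theoretical_grid",
    "match_peaks_ppm",
    "grid_consistency_filter",
    "cross_mode_validate",
    "align_and_match_datasets",
]

PEAK_COLUMNS = ("peak_id", "mz", "rt", "polarity")


def intensity_columns(peaks: pd.DataFrame) -> list[str]:
    return [c for c in peaks.columns if c not in PEAK_COLUMNS]


def _check_peaks(peaks: pd.DataFrame) -> None:
    missing = [c for c in ("peak_id", "mz", "rt") if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table missing columns {missing}")
    if (peaks["mz"] <= 0).any():
        raise ValueError("m/z values must be positive")
    if (peaks["rt"] < 0).any():
        raise ValueError("retention times must be nonnegative")


def dedupe_peaks(peaks: pd.DataFrame, ppm_tol: float = 10.0,
                 rt_tol_s: float = 1.0) -> pd.DataFrame:
    """Collapse falsely duplicated peaks.

    Peaks within ``ppm_tol`` in mass and ``rt_tol_s`` seconds of each other
    are grouped by single linkage; only the group member with the highest
    total intensity survives.  Idempotent.
    """
    _check_peaks(peaks)
    n = len(peaks)
    if n <= 1:
        return peaks.copy()
    df = peaks.sort_values("mz", kind="stable").reset_index(drop=True)
    mz = df["mz"].to_numpy()
    rt = df["rt"].to_numpy()
    rt_tol = rt_tol_s / 60.0

    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        j = i + 1
        # mz sorted: neighbours beyond the ppm window can be skipped
        while j < n and (mz[j] - mz[i]) / mz[i] * 1e6 <= ppm_tol:
            if abs(rt[j] - rt[i]) <= rt_tol + 1e-12:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
            j += 1

    icols = intensity_columns(df)
    total = df[icols].sum(axis=1).to_numpy() if icols else np.zeros(n)
    groups = np.array([find(i) for i in range(n)])
    keep_idx = []
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        keep_idx.append(members[np.argmax(total[members])])
    return df.iloc[sorted(keep_idx)].reset_index(drop=True)


def rt_window_filter(peaks: pd.DataFrame, lo: float = 1.0,
                     hi: float = 18.3) -> pd.DataFrame:
    """Keep peaks with retention time in [lo, hi] minutes (inclusive)."""
    if lo >= hi:
        raise ValueError(f"invalid retention-time window [{lo}, {hi}]")
    _check_peaks(peaks)
    mask = (peaks["rt"] >= lo) & (peaks["rt"] <= hi)
    return peaks.loc[mask].reset_index(drop=True)


def build_theoretical_grid(
    registry: Mapping[str, LipidClassSpec] | None = None,
    classes: Sequence[str] | None = None,
    carbon_range: Iterable[int] = range(26, 49),
    db_range: Iterable[int] = range(0, 9),
    polarity: str | None = None,
) -> pd.DataFrame:
    """Enumerate theoretical (species, adduct, m/z) rows.

    Chain lengths and double-bond counts are varied over the given ranges for
    every requested class; rows are unique on (class, carbons, db, adduct).
    Classes without an eligible adduct for the requested polarity are skipped
    with a warning.
    """
    registry = registry if registry is not None else default_registry()
    classes = list(classes) if classes is not None else [
        c for c, s in registry.items() if not s.chainless
    ]
    carbons = sorted(set(carbon_range))
    dbs = sorted(set(db_range))
    if not carbons or not dbs:
        raise ValueError("carbon_range and db_range must be non-empty")
    rows = []
    for code in classes:
        spec = registry[code]
        adducts = [a for a in spec.adducts
                   if polarity is None or a.polarity == polarity]
        if not adducts:
            warnings.warn(f"class {code}: no eligible adduct, skipped",
                          stacklevel=2)
            continue
        for c in carbons:
            for d in dbs:
                if 2 * c - 2 * d < 0:
                    continue
                sp = LipidSpecies(f"{code} {c}:{d}", code, c, d)
                for a in adducts:
                    rows.append((code, c, d, a.name, a.polarity,
                                 monoisotopic_mass(sp, a, registry)))
    return pd.DataFrame(
        rows, columns=["class_code", "carbons", "double_bonds", "adduct",
                       "polarity", "mz_theo"],
    )


def match_peaks_ppm(peaks: pd.DataFrame, grid: pd.DataFrame,
                    tol_ppm: float = 10.0) -> pd.DataFrame:
    """All (peak, grid row) pairs within ``tol_ppm``; multiple candidates per
    peak are allowed at this stage."""
    _check_peaks(peaks)
    g = grid.sort_values("mz_theo", kind="stable").reset_index(drop=True)
    gm = g["mz_theo"].to_numpy()
    out = []
    for _, pk in peaks.iterrows():
        mz = pk["mz"]
        half = mz * tol_ppm * 1e-6
        lo = np.searchsorted(gm, mz - half, side="left")
        hi = np.searchsorted(gm, mz + half, side="right")
        for k in range(lo, hi):
            ppm = (mz - gm[k]) / gm[k] * 1e6
            if abs(ppm) <= tol_ppm:
                out.append((pk["peak_id"], mz, pk["rt"],
                            g.at[k, "class_code"], g.at[k, "carbons"],
                            g.at[k, "double_bonds"], g.at[k, "adduct"],
                            gm[k], ppm))
    return pd.DataFrame(
        out, columns=["peak_id", "mz", "rt", "class_code", "carbons",
                      "double_bonds", "adduct", "mz_theo", "ppm_error"],
    )


def grid_consistency_filter(candidates: pd.DataFrame,
                            residual_tol: float = 0.5,
                            min_group: int = 4,
                            standards_rt: Mapping[str, float] | None = None
                            ) -> pd.DataFrame:
    """Automated stand-in for visual grid curation on the m/z vs rt plane.

    Per (class, adduct) group with >= ``min_group`` candidates, a robust
    linear trend ``rt ~ a*carbons + b*double_bonds + c`` is fitted (Huber
    loss).  Candidates with |residual| > ``residual_tol`` minutes are
    removed.  Chromatographic sign expectations are enforced: a fitted carbon
    slope <= 0, or a positive double-bond slope where double bonds vary,
    rejects the whole group.  Smaller or degenerate groups pass through
    flagged ``unfiltered``.

    If a ``standards_rt`` table (class -> internal-standard retention time) is
    given, each group's retention times are first shifted so the fitted trend
    passes through the standard (per-class rt offset anchoring).

    Returns the candidate table with a ``status`` column; retained candidates
    have status ``retained`` or ``unfiltered``.
    """
    out = candidates.copy()
    out["status"] = "unfiltered"
    out["grid_residual"] = np.nan
    for (code, adduct), idx in out.groupby(
            ["class_code", "adduct"]).groups.items():
        idx = np.asarray(list(idx))
        sub = out.loc[idx]
        if len(sub) < min_group:
            continue
        X = sub[["carbons", "double_bonds"]].to_numpy(dtype=float)
        y = sub["rt"].to_numpy(dtype=float)
        if standards_rt and code in standards_rt:
            y = y - (np.median(y) - standards_rt[code])
        c_varies = np.unique(X[:, 0]).size > 1
        db_varies = np.unique(X[:, 1]).size > 1
        if not c_varies and not db_varies:
            out.loc[idx, "status"] = "degenerate"
            continue
        cols = [0] if not db_varies else ([1] if not c_varies else [0, 1])
        model = HuberRegressor(epsilon=1.35, max_iter=500)
        model.fit(X[:, cols], y)
        coef = dict(zip(cols, model.coef_))
        if (c_varies and coef.get(0, 1.0) <= 0) or \
           (db_varies and coef.get(1, -1.0) >= 0):
            out.loc[idx, "status"] = "rejected_sign"
            continue
        resid = y - model.predict(X[:, cols])
        out.loc[idx, "grid_residual"] = resid
        ok = np.abs(resid) <= residual_tol
        out.loc[idx[ok], "status"] = "retained"
        out.loc[idx[~ok], "status"] = "removed_residual"
    return out


def cross_mode_validate(pos_candidates: pd.DataFrame,
                        neg_candidates: pd.DataFrame,
                        rt_tol: float = 0.1) -> pd.DataFrame:
    """Mark species annotated in both polarities within ``rt_tol`` minutes.

    Both inputs are candidate tables over the same species space (class,
    carbons, double_bonds).  Returns the concatenated table with a
    ``validation`` column: ``cross_validated`` or ``single_mode``.
    """
    key = ["class_code", "carbons", "double_bonds"]
    combined = pd.concat(
        [pos_candidates.assign(_mode="pos"), neg_candidates.assign(_mode="neg")],
        ignore_index=True,
    )
    combined["validation"] = "single_mode"
    pos_rt = pos_candidates.groupby(key)["rt"].apply(list)
    neg_rt = neg_candidates.groupby(key)["rt"].apply(list)
    validated = set()
    for k in set(pos_rt.index) & set(neg_rt.index):
        dmin = min(abs(a - b) for a in pos_rt[k] for b in neg_rt[k])
        if dmin <= rt_tol:
            validated.add(k)
    if validated:
        keys = list(zip(*[combined[c] for c in key]))
        mask = np.array([k in validated for k in keys])
        combined.loc[mask, "validation"] = "cross_validated"
    return combined.drop(columns="_mode")


def _fit_rt_warp(rt_b: np.ndarray, rt_a: np.ndarray):
    """Monotone rt warping rt_B -> rt_A fitted on coarse anchor pairs."""
    order = np.argsort(rt_b, kind="stable")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(rt_b[order], rt_a[order])
    return iso.predict


def align_and_match_datasets(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame,
                             ppm: float = 10.0, rt_tol_s: float = 30.0,
                             coarse_rt_tol_s: float = 120.0,
                             min_anchors: int = 10) -> pd.DataFrame:
    """Match peaks between two datasets after retention-time alignment.

    A coarse pass pairs peaks within ``ppm`` and ``coarse_rt_tol_s``; the
    pairs serve as anchors for a smooth monotone retention-time warping of B
    onto A's time axis.  Final matches must fall within (``ppm``,
    ``rt_tol_s``) after warping, and any peak matched non-uniquely on either
    side is removed.

    With fewer than ``min_anchors`` coarse anchors the warp is refused and an
    identity warp is used (with a warning).
    """
    _check_peaks(peaks_a)
    _check_peaks(peaks_b)

    def _pairs(rt_b_mapped: np.ndarray, tol_s: float) -> list[tuple[int, int]]:
        got = []
        mz_a = peaks_a["mz"].to_numpy()
        rt_a = peaks_a["rt"].to_numpy()
        mz_b = peaks_b["mz"].to_numpy()
        order = np.argsort(mz_a, kind="stable")
        mz_sorted = mz_a[order]
        for jb in range(len(peaks_b)):
            half = mz_b[jb] * ppm * 1e-6
            lo = np.searchsorted(mz_sorted, mz_b[jb] - half, "left")
            hi = np.searchsorted(mz_sorted, mz_b[jb] + half, "right")
            for k in range(lo, hi):
                ia = order[k]
                if abs((mz_b[jb] - mz_a[ia]) / mz_a[ia]) * 1e6 > ppm:
                    continue
                if abs(rt_b_mapped[jb] - rt_a[ia]) * 60.0 <= tol_s:
                    got.append((ia, jb))
        return got

    rt_b = peaks_b["rt"].to_numpy()
    coarse = _pairs(rt_b, coarse_rt_tol_s)
    if len(coarse) < min_anchors:
        warnings.warn(
            f"only {len(coarse)} coarse anchors (<{min_anchors}); "
            "retention-time warping refused, identity warp used",
            stacklevel=2,
        )
        warped = rt_b
    else:
        ia, jb = np.array(coarse).T
        warp = _fit_rt_warp(rt_b[jb], peaks_a["rt"].to_numpy()[ia])
        warped = warp(rt_b)

    final = _pairs(warped, rt_tol_s)
    if not final:
        return pd.DataFrame(columns=["peak_id_a", "peak_id_b", "ppm_error",
                                     "rt_delta_s"])
    ia, jb = np.array(final).T
    # drop non-uniquely matched peaks on either side
    ua, ca = np.unique(ia, return_counts=True)
    ub, cb = np.unique(jb, return_counts=True)
    bad_a = set(ua[ca > 1])
    bad_b = set(ub[cb > 1])
    keep = [(i, j) for i, j in final if i not in bad_a and j not in bad_b]
    rows = []
    for i, j in keep:
        mz_a = peaks_a["mz"].iat[i]
        rows.append((
            peaks_a["peak_id"].iat[i],
            peaks_b["peak_id"].iat[j],
            (peaks_b["mz"].iat[j] - mz_a) / mz_a * 1e6,
            (warped[j] - peaks_a["rt"].iat[i]) * 60.0,
        ))
    return pd.DataFrame(rows, columns=["peak_id_a", "peak_id_b", "ppm_error",
                                       "rt_delta_s"])
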