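"""Cell-type assignment of lipids via marker-gene correlation.

Lipid intensity profiles (per-region means) are correlated with the
expression profiles of marker genes for the six main brain cell types:
oligodendrocytes (OD), microglia (MG), oligodendrocyte progenitors (OPC),
inhibitory (In) and excitatory (Ex) neurons, and astrocytes (Ast).  A lipid
takes the cell type of its best-correlated marker when the correlation clears
both gates (Pearson R > 0.5 and p < 0.01 by default); otherwise it stays
unassigned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, hypergeom_over, rank_tests

__all__ = [
    "CELL_TYPES",
    "assign_cell_types",
    "celltype_category_enrichment",
    "neuronal_sorted_score",
    "load_marker_map",
]

CELL_TYPES = ("OD", "MG", "OPC", "In", "Ex", "Ast")
NEURONAL = ("In", "Ex")


def load_marker_map(path) -> pd.Series:
    """Read a marker map CSV (columns gene_id, cell_type) into a Series."""
    df = pd.read_csv(path)
    m = pd.Series(df["cell_type"].to_numpy(), index=df["gene_id"],
                  name="cell_type")
    _validate_marker_map(m)
    return m


def _validate_marker_map(marker_map: pd.Series) -> None:
    if marker_map.index.duplicated().any():
        raise ValueError("duplicate marker genes in marker map")
    unknown = set(marker_map) - set(CELL_TYPES)
    if unknown:
        raise ValueError(f"unknown cell types in marker map: {unknown}")


def assign_cell_types(lipid_profiles: pd.DataFrame,
                      expr_profiles: pd.DataFrame, marker_map: pd.Series,
                      r_threshold: float = 0.5,
                      p_threshold: float = 0.01) -> pd.DataFrame:
    """Assign each lipid the cell type of its top-correlated marker gene.

    Both inputs are profiles over regions (lipids x regions, genes x
    regions); correlation runs over the shared region set.  The assignment
    requires the best marker's Pearson R > ``r_threshold`` and its two-sided
    p < ``p_threshold``; a tie between equally correlated markers of
    different cell types yields no assignment.
    """
    _validate_marker_map(marker_map)
    genes = [g for g in marker_map.index if g in expr_profiles.index]
    if not genes:
        raise ValueError("no marker genes found in the expression profiles")
    regions = lipid_profiles.columns.intersection(expr_profiles.columns)
    if len(regions) < 3:
        raise ValueError("need >=3 shared regions between lipid and "
                         "expression profiles")
    x = lipid_profiles[regions].to_numpy(dtype=float)
    y = expr_profiles.loc[genes, regions].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt(
        (xc ** 2).sum(axis=1)[:, None] * (yc ** 2).sum(axis=1)[None, :]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc.T) / denom
    r = np.nan_to_num(r, nan=0.0)
    n = len(regions)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r ** 2, 1e-300, None))
    p = 2 * sps.t.sf(np.abs(t), n - 2)

    rows = []
    for i, lipid in enumerate(lipid_profiles.index):
        best = int(np.argmax(r[i]))
        best_r, best_p = float(r[i, best]), float(p[i, best])
        ct = marker_map[genes[best]]
        ties = np.flatnonzero(r[i] == best_r)
        tie_types = {marker_map[genes[j]] for j in ties}
        if best_r > r_threshold and best_p < p_threshold \
                and len(tie_types) == 1:
            rows.append((lipid, ct, genes[best], best_r, best_p))
        else:
            rows.append((lipid, "none", genes[best], best_r, best_p))
    return pd.DataFrame(
        rows, columns=["lipid_id", "cell_type", "best_marker", "best_R",
                       "best_p"],
    ).set_index("lipid_id")


def celltype_category_enrichment(categories: pd.Series,
                                 assignments: pd.DataFrame) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each cell type within
    each lipid category, BH-corrected over all (category, cell type) pairs.

    The background population is all lipids covered by both inputs.
    """
    lipids = categories.index.intersection(assignments.index)
    cats = categories.loc[lipids]
    cts = assignments.loc[lipids, "cell_type"]
    pop = len(lipids)
    rows = []
    for cat in cats.dropna().unique():
        in_cat = cats == cat
        if int(in_cat.sum()) == 0:
            continue
        for ct in CELL_TYPES:
            pop_hits = int((cts == ct).sum())
            hits = int((in_cat & (cts == ct)).sum())
            p = hypergeom_over(hits, int(in_cat.sum()), pop_hits, pop)
            rows.append((cat, ct, hits, int(in_cat.sum()), pop_hits, pop, p))
    out = pd.DataFrame(rows, columns=["category", "cell_type", "hits",
                                      "category_size", "pop_hits",
                                      "pop_size", "p"])
    out["p_adj"] = bh_adjust(out["p"])
    return out


def neuronal_sorted_score(assignments: pd.DataFrame,
                          sorted_intensities: pd.DataFrame,
                          top_k: int = 20):
    """Neuronal vs non-neuronal validation against sorted-cell lipidomes.

    For each cell type the ``top_k`` lipid markers with the highest marker
    correlation (or all available, if fewer) are pooled into a *neuronal*
    (In + Ex) and a *non-neuronal* (OD, OPC, Ast, MG) group.
    ``sorted_intensities`` holds per-lipid intensities in the sorted neuron
    fraction and the non-neuronal fraction (columns ``neuron`` / ``other``).
    Returns per-lipid log10 neuron/other ratios plus a one-sided rank test
    that neuronal-marker ratios exceed non-neuronal ones.
    """
    markers: dict[str, list] = {}
    assigned = assignments[assignments["cell_type"] != "none"]
    for ct, grp in assigned.groupby("cell_type"):
        top = grp.sort_values("best_R", ascending=False).head(top_k)
        markers[ct] = list(top.index)
    neuronal = [l for ct in NEURONAL for l in markers.get(ct, [])]
    non_neuronal = [l for ct in CELL_TYPES if ct not in NEURONAL
                    for l in markers.get(ct, [])]
    avail = sorted_intensities.index
    neuronal = [l for l in neuronal if l in avail]
    non_neuronal = [l for l in non_neuronal if l in avail]
    if not neuronal or not non_neuronal:
        raise ValueError("sorted-cell intensities cover no markers of one "
                         "group")
    ratios = np.log10(sorted_intensities["neuron"]
                      / sorted_intensities["other"])
    test = rank_tests(ratios.loc[neuronal], ratios.loc[non_neuronal],
                      alternative="greater")
    out = pd.DataFrame({
        "log_ratio": pd.concat([ratios.loc[neuronal],
                                ratios.loc[non_neuronal]]),
        "group": ["neuronal"] * len(neuronal)
                 + ["non_neuronal"] * len(non_neuronal),
    })
    return out, test
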