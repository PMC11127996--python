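"""Synthetic brain-lipidome atlas with planted ground truth.

The generator emulates the structure of a regional lipidome study: 75 brain
regions sampled in 4 individuals; a bimodal per-region myelin covariate
(white-matter-like high mode); cell-type fractions whose oligodendrocyte
component tracks myelin, with matched marker-gene expression for the six main
brain cell types; a 4-level cortical processing-hierarchy gradient; and a
region x region functional-connectivity matrix structured by latent
communities aligned with the myelin axis.

Lipids are planted in the five profile categories (default sizes
274/71/46/20/8):

* myelin+ / myelin-: intensity tracks +-beta_myelin x myelin content;
* unexplained: regionally variable but myelin-independent, driven by either a
  (myelin-residualized) cell-type fraction or the hierarchy gradient;
* housekeeping: no regional signal, baseline noise;
* variable: no shared regional signal, but inflated individual x region
  interaction noise.

Raw-scale intensities are emitted (10**log10) together with planted wet
weights and per-sample standards medians, so the normalization cascade of
:mod:`brainlipidome.preprocess` applies end to end and recovers the planted
log-scale signals exactly in the noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .celltype import CELL_TYPES

__all__ = [
    "SyntheticConfig",
    "SyntheticAtlas",
    "generate_atlas",
    "evaluate_recovery",
    "generate_peaklist",
]

# marker genes per cell type (synthetic identifiers)
_MARKERS = {
    "OD": ["MARK_OD1", "MARK_OD2", "MARK_OD3"],
    "MG": ["MARK_MG1", "MARK_MG2"],
    "OPC": ["MARK_OPC1", "MARK_OPC2"],
    "In": ["MARK_IN1", "MARK_IN2", "MARK_IN3"],
    "Ex": ["MARK_EX1", "MARK_EX2", "MARK_EX3"],
    "Ast": ["MARK_AST1", "MARK_AST2"],
}

# lipid-class palette per planted category: (class, carbon range, db range).
# Myelin+ favours sphingolipids and ether lipids, myelin- LPC/PE/PC,
# housekeeping free fatty acids -- mirroring white/gray-matter lipid biology.
_CLASS_POOLS = {
    "myelin_pos": [("SM", (32, 44), (1, 3)), ("HexCer", (32, 44), (1, 3)),
                   ("SHexCer", (34, 44), (1, 3)), ("Cer", (32, 44), (1, 3)),
                   ("PE-O", (34, 44), (1, 6)), ("PE-P", (34, 44), (1, 6)),
                   ("PC-O", (32, 44), (0, 5))],
    "myelin_neg": [("LPC", (14, 22), (0, 4)), ("PE", (34, 44), (2, 8)),
                   ("PC", (30, 40), (0, 6))],
    "unexplained": [("PC", (30, 44), (0, 8)), ("PI", (34, 40), (2, 6)),
                    ("PS", (34, 44), (1, 6)), ("DAG", (30, 40), (0, 4))],
    "housekeeping": [("FA", (14, 24), (0, 6)), ("CAR", (12, 20), (0, 2)),
                     ("PG", (32, 40), (1, 4))],
    "variable": [("TAG", (44, 58), (0, 6)), ("CE", (14, 22), (0, 4))],
}

_ANATOMICAL_GROUPS = [
    "frontal_cortex", "parietal_cortex", "temporal_cortex",
    "occipital_cortex", "limbic_cortex", "insula", "basal_ganglia",
    "thalamus", "hypothalamus", "cerebellum", "white_matter",
]


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 419 lipids in planted proportions 274/71/46/20/8
    across 75 regions and 4 individuals."""

    n_regions: int = 75
    n_individuals: int = 4
    n_cortical: int = 56
    n_fc_regions: int = 59
    n_expr_regions: int = 35
    category_counts: dict = field(default_factory=lambda: {
        "myelin_pos": 274, "myelin_neg": 71, "unexplained": 46,
        "housekeeping": 20, "variable": 8,
    })
    n_hierarchy_lipids: int = 16  # subset of "unexplained" driven by hierarchy
    # myelin bimodality: (gray-like, white-like) T1w/T2w modes
    wm_fraction: float = 0.2
    myelin_means: tuple = (1.35, 1.90)
    myelin_sds: tuple = (0.12, 0.08)
    # effect sizes (log10-intensity units; drivers other than myelin are
    # z-scored, the myelin term uses the raw T1w/T2w scale)
    beta_myelin: float = 2.0
    beta_celltype: float = 0.8
    beta_hierarchy: float = 0.8
    noise_sd: float = 0.2
    variable_sd: float = 0.6  # extra individual x region interaction noise
    indiv_offset_sd: float = 0.15
    # cell-type composition latents and marker expression
    od_myelin_coupling: float = 1.5
    celltype_latent_sd: float = 0.7
    marker_noise_sd: float = 0.1
    fc_communities: int = 4
    fc_noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_regions < 4:
            problems.append("n_regions must be >=4")
        if self.n_individuals < 2:
            problems.append("n_individuals must be >=2")
        if not (0 < self.n_cortical <= self.n_regions):
            problems.append("n_cortical out of range")
        if not (4 <= self.n_fc_regions <= self.n_regions):
            problems.append("n_fc_regions out of range")
        if not (3 <= self.n_expr_regions <= self.n_regions):
            problems.append("n_expr_regions out of range")
        if any(v <= 0 for v in self.category_counts.values()):
            problems.append("category counts must be positive")
        if self.n_hierarchy_lipids > self.category_counts.get("unexplained", 0):
            problems.append("n_hierarchy_lipids exceeds unexplained count")
        if self.noise_sd < 0 or self.variable_sd <= 0:
            problems.append("noise sds must be positive")
        if not 0 < self.wm_fraction < 1:
            problems.append("wm_fraction must be in (0, 1)")
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))


@dataclass
class SyntheticAtlas:
    """Generator output bundle: matrices plus the planted truth."""

    intensity: pd.DataFrame          # lipids x samples, raw scale
    sample_meta: pd.DataFrame        # per-sample region/individual/weights
    standards_medians: pd.Series     # per-sample internal-standard median
    region_meta: pd.DataFrame        # myelin, group, hierarchy level, ...
    expression: pd.DataFrame         # marker genes x expression samples (TPM)
    expression_meta: pd.DataFrame
    marker_map: pd.Series            # gene -> cell type
    fc: pd.DataFrame                 # FC-covered regions x regions
    truth_lipids: pd.DataFrame
    truth_regions: pd.DataFrame
    config: SyntheticConfig


def _residualize(v: np.ndarray, against: np.ndarray) -> np.ndarray:
    """Residual of v after OLS on [1, against]; exactly orthogonal."""
    x = np.column_stack([np.ones_like(against), against])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def _make_lipid_names(rng: np.random.Generator,
                      counts: dict[str, int]) -> tuple[list[str], list[str]]:
    """Unique shorthand names with a category-typical class palette."""
    names: list[str] = []
    cats: list[str] = []
    used: set[str] = set()
    for cat, n in counts.items():
        pool = _CLASS_POOLS[cat]
        combos = []
        for code, (clo, chi), (dlo, dhi) in pool:
            for c in range(clo, chi + 1):
                for d in range(dlo, dhi + 1):
                    combos.append(f"{code} {c}:{d}")
        combos = [c for c in combos if c not in used]
        if n > len(combos):
            raise ValueError(f"category {cat}: not enough distinct species "
                             f"({n} requested, {len(combos)} available)")
        pick = rng.choice(len(combos), size=n, replace=False)
        for i in pick:
            names.append(combos[i])
            used.add(combos[i])
            cats.append(cat)
    return names, cats


def generate_atlas(config: SyntheticConfig | None = None) -> SyntheticAtlas:
    """Generate the full synthetic atlas; byte-identical under a fixed seed."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # ---- regions: hierarchy levels, anatomical groups, bimodal myelin ----
    region_ids = [f"R{i + 1:03d}" for i in range(cfg.n_regions)]
    levels = np.full(cfg.n_regions, np.nan)
    lv = np.resize(np.array([1, 2, 3, 4]), cfg.n_cortical).astype(float)
    levels[:cfg.n_cortical] = rng.permutation(lv)
    cortical_class = np.where(
        np.isnan(levels), "none",
        np.array(["", "primary", "secondary", "associative", "limbic"]
                 )[np.nan_to_num(levels).astype(int)],
    )
    n_wm = max(1, round(cfg.wm_fraction * cfg.n_regions))
    n_wm = min(n_wm, cfg.n_regions - cfg.n_cortical) or 1
    is_wm = np.zeros(cfg.n_regions, dtype=bool)
    non_cortical = np.arange(cfg.n_cortical, cfg.n_regions)
    is_wm[rng.choice(non_cortical, size=n_wm, replace=False)] = True
    myelin = np.where(
        is_wm,
        rng.normal(cfg.myelin_means[1], cfg.myelin_sds[1], cfg.n_regions),
        rng.normal(cfg.myelin_means[0], cfg.myelin_sds[0], cfg.n_regions),
    )
    myelin = np.clip(myelin, 0.5, None)
    groups = [
        _ANATOMICAL_GROUPS[10] if is_wm[i]
        else _ANATOMICAL_GROUPS[i % 10]
        for i in range(cfg.n_regions)
    ]
    region_meta = pd.DataFrame({
        "region_id": region_ids,
        "anatomical_group": groups,
        "cortical_class": cortical_class,
        "myelin": myelin,
        "hierarchy_level": levels,
    }).set_index("region_id")

    # ---- cell-type fractions: softmax latents, OD tied to myelin ----
    myelin_z = _zscore(myelin)
    latents = {}
    for ct in CELL_TYPES:
        z = rng.normal(0.0, cfg.celltype_latent_sd, cfg.n_regions)
        if ct == "OD":
            z = cfg.od_myelin_coupling * myelin_z + rng.normal(
                0.0, 0.3, cfg.n_regions)
        latents[ct] = z
    lat = np.column_stack([latents[ct] for ct in CELL_TYPES])
    ex = np.exp(lat - lat.max(axis=1, keepdims=True))
    fractions = ex / ex.sum(axis=1, keepdims=True)
    frac_df = pd.DataFrame(fractions, index=region_ids, columns=CELL_TYPES)
    log_frac = np.log10(fractions)

    # myelin-independent regional drivers (z-scored residuals)
    ct_driver = {
        ct: _zscore(_residualize(log_frac[:, j], myelin))
        for j, ct in enumerate(CELL_TYPES)
    }
    lv_filled = np.where(np.isnan(levels), np.nanmean(levels), levels)
    hr_driver = _zscore(_residualize(lv_filled, myelin))

    # ---- lipids: names, planted categories, drivers ----
    names, cats = _make_lipid_names(rng, cfg.category_counts)
    n_lipids = len(names)
    truth = pd.DataFrame({"lipid_id": names, "category": cats}).set_index(
        "lipid_id")
    truth["cell_type"] = ""
    truth["beta"] = 0.0
    truth["hierarchy_driven"] = False

    unexplained = truth.index[truth["category"] == "unexplained"]
    hr_lipids = list(unexplained[:cfg.n_hierarchy_lipids])
    truth.loc[hr_lipids, "hierarchy_driven"] = True
    truth.loc[hr_lipids, "beta"] = cfg.beta_hierarchy
    ct_lipids = [l for l in unexplained if l not in hr_lipids]
    non_od = [ct for ct in CELL_TYPES if ct != "OD"]
    truth.loc[ct_lipids, "cell_type"] = [
        non_od[i % len(non_od)] for i in range(len(ct_lipids))
    ]
    truth.loc[ct_lipids, "beta"] = cfg.beta_celltype
    truth.loc[truth["category"] == "myelin_pos", "beta"] = cfg.beta_myelin
    truth.loc[truth["category"] == "myelin_neg", "beta"] = -cfg.beta_myelin
    # myelin-coupled lipids are OD-associated by construction
    truth.loc[truth["category"] == "myelin_pos", "cell_type"] = "OD"

    # ---- intensity matrix (log10 scale, then exponentiated) ----
    samples = [f"{r}_I{k + 1}" for r in region_ids
               for k in range(cfg.n_individuals)]
    sample_region = np.repeat(np.arange(cfg.n_regions), cfg.n_individuals)
    sample_indiv = np.tile(np.arange(cfg.n_individuals), cfg.n_regions)

    base = rng.normal(6.0, 0.5, n_lipids)
    indiv_offset = rng.normal(0.0, cfg.indiv_offset_sd,
                              (n_lipids, cfg.n_individuals))
    myelin_c = myelin - myelin.mean()
    signal = np.zeros((n_lipids, cfg.n_regions))
    for i, lipid in enumerate(truth.index):
        row = truth.loc[lipid]
        if row["category"] in ("myelin_pos", "myelin_neg"):
            signal[i] = row["beta"] * myelin_c
        elif row["category"] == "unexplained":
            drv = hr_driver if row["hierarchy_driven"] \
                else ct_driver[row["cell_type"]]
            signal[i] = row["beta"] * drv

    x = (base[:, None]
         + indiv_offset[:, sample_indiv]
         + signal[:, sample_region]
         + rng.normal(0.0, cfg.noise_sd, (n_lipids, len(samples))))
    var_rows = np.flatnonzero(truth["category"].to_numpy() == "variable")
    if var_rows.size:
        x[var_rows] += rng.normal(0.0, cfg.variable_sd,
                                  (var_rows.size, len(samples)))

    # planted technical factors recovered by the normalization cascade
    weights = rng.uniform(9.0, 16.0, len(samples))
    standards = 10 ** rng.normal(5.0, 0.1, len(samples))
    s_term = np.log10(standards) - np.log10(standards).mean()
    w_term = np.log10(weights) - np.log10(weights).mean()
    raw = 10 ** (x + s_term[None, :] + w_term[None, :])

    intensity = pd.DataFrame(raw, index=truth.index, columns=samples)
    sample_meta = pd.DataFrame({
        "sample_id": samples,
        "region_id": [region_ids[r] for r in sample_region],
        "individual_id": [f"I{k + 1}" for k in sample_indiv],
        "sample_type": "tissue",
        "wet_weight_mg": weights,
        "batch_id": "B1",
        "dilution_factor": np.nan,
    }).set_index("sample_id")
    standards_medians = pd.Series(standards, index=samples,
                                  name="standards_median")

    # ---- marker gene expression (TPM) on a region subset ----
    expr_region_idx = np.arange(0, 2 * cfg.n_expr_regions, 2)[
        :cfg.n_expr_regions]
    expr_regions = [region_ids[i] for i in expr_region_idx]
    genes = [g for ct in CELL_TYPES for g in _MARKERS[ct]]
    gene_ct = {g: ct for ct in CELL_TYPES for g in _MARKERS[ct]}
    expr_samples = [f"{r}_I{k + 1}_rna" for r in expr_regions
                    for k in range(cfg.n_individuals)]
    er = np.repeat(expr_region_idx, cfg.n_individuals)
    ek = np.tile(np.arange(cfg.n_individuals), len(expr_regions))
    log_tpm = np.empty((len(genes), len(expr_samples)))
    for gi, g in enumerate(genes):
        ct = gene_ct[g]
        j = CELL_TYPES.index(ct)
        log_tpm[gi] = (2.0 + log_frac[er, j]
                       + rng.normal(0.0, cfg.marker_noise_sd,
                                    len(expr_samples)))
    expression = pd.DataFrame(10 ** log_tpm, index=genes,
                              columns=expr_samples)
    expression_meta = pd.DataFrame({
        "sample_id": expr_samples,
        "region_id": [region_ids[i] for i in er],
        "individual_id": [f"I{k + 1}" for k in ek],
    }).set_index("sample_id")
    marker_map = pd.Series(gene_ct, name="cell_type")

    # ---- FC matrix: community structure aligned with the myelin axis ----
    fc_region_idx = np.arange(cfg.n_fc_regions)
    fc_regions = [region_ids[i] for i in fc_region_idx]
    g_latent = myelin_z[fc_region_idx] + rng.normal(0.0, 0.5,
                                                    cfg.n_fc_regions)
    qs = np.quantile(g_latent, np.linspace(0, 1, cfg.fc_communities + 1)[1:-1])
    community = np.searchsorted(qs, g_latent)
    same = (community[:, None] == community[None, :]).astype(float)
    gg = np.outer(g_latent, g_latent)
    gg = gg / np.abs(gg).max()
    noise = rng.normal(0.0, cfg.fc_noise_sd,
                       (cfg.n_fc_regions, cfg.n_fc_regions))
    fc = 0.25 + 0.35 * same + 0.3 * gg + (noise + noise.T) / 2.0
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    fc_df = pd.DataFrame(fc, index=fc_regions, columns=fc_regions)

    truth_regions = region_meta.copy()
    truth_regions[list(CELL_TYPES)] = frac_df
    truth_regions["community"] = pd.Series(
        dict(zip(fc_regions, community)), dtype="Int64"
    ).reindex(region_ids)

    return SyntheticAtlas(
        intensity=intensity,
        sample_meta=sample_meta,
        standards_medians=standards_medians,
        region_meta=region_meta,
        expression=expression,
        expression_meta=expression_meta,
        marker_map=marker_map,
        fc=fc_df,
        truth_lipids=truth,
        truth_regions=truth_regions,
        config=cfg,
    )


def evaluate_recovery(truth: pd.DataFrame, results: pd.DataFrame,
                      categories=("myelin_pos", "myelin_neg", "unexplained",
                                  "housekeeping", "variable")):
    """Confusion matrix, accuracy and per-category sensitivity of a
    classification result against the planted truth."""
    if not truth.index.equals(results.index):
        if set(truth.index) != set(results.index):
            raise ValueError("truth and results cover different lipid sets")
        results = results.loc[truth.index]
    planted = pd.Categorical(truth["category"], categories=categories)
    called = pd.Categorical(results["category"], categories=categories)
    confusion = pd.crosstab(planted, called, rownames=["planted"],
                            colnames=["called"], dropna=False)
    correct = (truth["category"].to_numpy()
               == results["category"].to_numpy())
    accuracy = float(correct.mean())
    sensitivity = {
        cat: float(correct[truth["category"] == cat].mean())
        for cat in categories if (truth["category"] == cat).any()
    }
    return confusion, accuracy, sensitivity


def generate_peaklist(
    seed: int = 0,
    classes: dict | None = None,
    adduct: str = "[M+H]+",
    rt_slope_c: float = 0.30,
    rt_slope_db: float = -0.45,
    rt_intercept: float = -1.0,
    rt_noise_sd: float = 0.02,
    ppm_noise_sd: float = 1.5,
    decoy_fraction: float = 0.2,
    n_duplicates: int = 0,
    n_samples: int = 3,
    registry=None,
):
    """Synthetic annotated peak table for the annotation pipeline.

    True peaks follow the chromatographic grid rt = rt_slope_c*C +
    rt_slope_db*DB + intercept + noise with theoretical m/z perturbed by a
    small ppm error.  Decoy peaks are background features: m/z uniform over
    the observed mass range, rt uniform over the analytical window.
    Optionally injects near-exact duplicates (within 10 ppm / 1 s) of random
    true peaks.  Returns (peaks DataFrame, truth DataFrame).
    """
    from .chem import LipidSpecies, default_registry, monoisotopic_mass, ADDUCTS

    registry = registry if registry is not None else default_registry()
    # Default classes are mutually mass-unambiguous under one adduct (PC and
    # PE, by contrast, are exactly iso-elemental at a 3-carbon offset and can
    # only be told apart by class-specific adducts or fragmentation).
    classes = classes or {
        "PC": (range(30, 43), range(0, 7)),
        "SM": (range(32, 45), range(0, 5)),
        "Cer": (range(32, 45), range(0, 4)),
    }
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    pid = 0
    for code, (crange, drange) in classes.items():
        c_off = rng.uniform(-0.5, 0.5)  # class-specific elution offset
        for c in crange:
            for d in drange:
                sp = LipidSpecies(f"{code} {c}:{d}", code, c, d)
                mz0 = monoisotopic_mass(sp, ADDUCTS[adduct], registry)
                ppm = np.clip(rng.normal(0.0, ppm_noise_sd), -8.0, 8.0)
                rt = (rt_intercept + c_off + rt_slope_c * c
                      + rt_slope_db * d + rng.normal(0.0, rt_noise_sd))
                rt = float(np.clip(rt, 1.0, 18.3))
                pid += 1
                peak_id = f"P{pid:05d}"
                inten = 10 ** rng.normal(5.0, 0.4, n_samples)
                rows.append([peak_id, mz0 * (1 + ppm * 1e-6), rt, "pos",
                             *inten])
                truth_rows.append([peak_id, False, sp.lipid_id])
    mz_lo = min(r[1] for r in rows)
    mz_hi = max(r[1] for r in rows)
    n_decoys = int(round(decoy_fraction * len(rows)))
    for _ in range(n_decoys):
        pid += 1
        peak_id = f"P{pid:05d}"
        inten = 10 ** rng.normal(4.5, 0.4, n_samples)
        rows.append([peak_id, rng.uniform(mz_lo, mz_hi),
                     rng.uniform(1.0, 18.3), "pos", *inten])
        truth_rows.append([peak_id, True, ""])
    true_count = len(rows) - n_decoys
    for _ in range(n_duplicates):
        src = rows[int(rng.integers(0, true_count))]
        pid += 1
        dup = list(src)
        dup[0] = f"P{pid:05d}"
        dup[1] = src[1] * (1 + rng.uniform(-5, 5) * 1e-6)
        dup[2] = src[2] + rng.uniform(-0.8, 0.8) / 60.0
        for j in range(4, 4 + n_samples):
            dup[j] = src[j] * rng.uniform(0.1, 0.9)
        rows.append(dup)
        truth_rows.append([dup[0], False, f"dup:{src[0]}"])
    cols = ["peak_id", "mz", "rt", "polarity"] + [
        f"S{i + 1}" for i in range(n_samples)
    ]
    peaks = pd.DataFrame(rows, columns=cols)
    truth = pd.DataFrame(truth_rows,
                         columns=["peak_id", "is_decoy", "species"]
                         ).set_index("peak_id")
    return peaks, truth
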