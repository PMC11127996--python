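# brainlipidome

Analysis toolkit for regional brain lipidome atlases measured by LC-MS.
It is written for lipidomics and neurobiology groups who profile many
anatomically defined brain regions across a few individuals and want to
relate the regional lipid composition to myelin content, cellular
composition, and the brain's functional architecture.

## What it does

* **Lipid chemistry** — a data-driven registry of 23 lipid classes (plus
  cholesterol), shorthand-nomenclature parsing at the FA acyl/alkyl level
  (`PC 34:1`, `PC-P 36:2`, `Cer d18:1/17:0`), monoisotopic m/z for standard
  adducts, omega-3/omega-6 residue flags (DHA 22:6 / adrenic 22:4), and a
  membrane-fluidity score per lipid: with `d` double bonds per chain and `L`
  carbons per chain, each min-max normalized over the lipid set,

      fluidity = (d_norm + (1 − L_norm)) / 2  ∈ [0, 1].

* **Annotation** — theoretical m/z grid over (class, carbons, double bonds,
  adduct), 10 ppm matching, duplicate-peak collapse (10 ppm / 1 s), retention
  time windowing, automated chromatographic grid-consistency filtering
  (rt must increase with chain carbons and decrease with double bonds within
  a class), cross-polarity validation, and retention-time-warped peak
  matching between datasets (±10 ppm, ±30 s after a monotone warp fitted on
  ±120 s coarse anchors).

* **Preprocessing** — left-tail normal imputation of missing intensities,
  blank and QC coefficient-of-variation filters, the three-way MRM transition
  filter (blank ratio 0.1, CoV 0.25, dilution-series r ≥ 0.9), and the
  normalization cascade: log10, internal-standards and wet-weight correction,
  then per-(lipid, individual) centering over regions.

* **Classification** — the core computation. Per lipid, one-way ANOVA across
  regions (`lipid ~ region`, BH-adjusted p < 0.01) splits regionally variable
  from stable lipids; the variable ones are regressed on the regions' myelin
  content (T1w/T2w ratio, per-region means, BH-adjusted slope p < 0.05) into
  **myelin+** / **myelin−** / **unexplained**; the stable ones are split at
  μ + σ of the Gaussian component of their within-region (inter-individual)
  variability into **housekeeping** / **variable**.

* **Cell types** — lipids are assigned to the six main brain cell types (OD,
  MG, OPC, In, Ex, Ast) by the best-correlated marker-gene expression profile
  (Pearson R > 0.5 and p < 0.01 over shared regions), with hypergeometric
  category enrichment and a sorted-cell neuronal vs non-neuronal validation
  score.

* **Functional architecture** — lipidome principal components against myelin,
  per-lipid linear models on the 4-level cortical processing hierarchy
  (primary → limbic), binomial chemical-property tests on the
  hierarchy-associated sets, and an outer-product Mantel permutation test of
  each lipid's regional profile against the functional-connectivity matrix.

* **Synthetic atlas** — a generator that plants all of the above structure
  (category labels, cell types, hierarchy lipids, FC communities) with known
  effect sizes, so every stage is testable end to end without any external
  data.

## Worked example

```bash
brainlipidome simulate --seed 7 --out demo/        # synthetic atlas CSVs
brainlipidome report --data-dir demo/ --out demo_results/ --seed 7
```

The report run prints a summary like:

```json
{
  "category_sizes": {"myelin_pos": 274, "myelin_neg": 71,
                     "unexplained": 46, "housekeeping": 20, "variable": 8},
  "n_lipids": 419,
  "n_regions": 75,
  "pc1_myelin_r": 0.9999,
  "n_celltype_assigned": 304,
  "n_hr_pos": 16,
  "n_hr_neg": 0,
  "n_fc_significant": 345
}
```

Reading: of 419 lipids, 274 track myelin content positively and 71
negatively; 46 vary among regions for other (cell-type or hierarchy) reasons;
the lipidome's first principal component is essentially the myelin axis
(`pc1_myelin_r`); 16 lipids follow the cortical processing hierarchy; and 345
lipid profiles correlate with the functional-connectivity structure (Mantel
p < 0.005) — on synthetic data these are dominated by the myelin-coupled
lipids, the planted behaviour.

The same stages are available individually (`annotate`, `preprocess`,
`classify`, `celltype`, `functional`, `enrich`) and as library functions:

```python
from brainlipidome import SyntheticConfig, generate_atlas, classify_lipids
from brainlipidome.preprocess import IntensityMatrix, normalize_intensities

atlas = generate_atlas(SyntheticConfig(seed=7))
norm = normalize_intensities(IntensityMatrix(atlas.intensity),
                             atlas.sample_meta, atlas.standards_medians)
result = classify_lipids(norm.data, atlas.sample_meta, atlas.region_meta)
print(result["category"].value_counts())
```

## Documentation

`docs/methods.md` describes the statistical model behind each stage, the
synthetic-data generating process and its limitations, default parameter
choices, and numerical edge-case handling.
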