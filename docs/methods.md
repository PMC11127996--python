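# Methods

This note documents the statistical models behind each stage of the package,
the synthetic data-generating process used for validation, the default
parameters, and the numerical decisions taken where the procedure left
genuine freedom.

## Data model

An atlas is a lipids × samples intensity matrix, where samples are
(region, individual) pairs: many anatomically defined regions (default 75)
measured in a few individuals (default 4). Per-region covariates are the
myelin content (a structural-MRI T1w/T2w ratio, used as a unitless proxy),
an optional cortical processing-hierarchy level (1 primary, 2 secondary,
3 associative, 4 limbic), and an optional row of a symmetric
functional-connectivity (FC) matrix covering a subset of regions. Marker-gene
expression for the six main brain cell types — oligodendrocytes (OD),
microglia (MG), oligodendrocyte progenitors (OPC), inhibitory (In) and
excitatory (Ex) neurons, astrocytes (Ast) — may be available for a region
subset.

## Preprocessing

* **Imputation.** Zero and absent cells are both treated as missing (the two
  are indistinguishable in exported peak tables). Let D be the distribution
  of per-lipid minimal detected intensities. Fills are drawn from
  Normal(median(D), p16(D)) truncated at zero, seeded. Using the 16th
  percentile of D itself as the σ is a deliberately literal model of the
  left tail of detectability; when detection floors span orders of magnitude
  (the realistic case) p16(D) ≪ median(D) and truncation is negligible.
* **Filters.** Blank filter: mean tissue intensity ≥ 2 × mean blank. QC
  filter: per-batch coefficient of variation on the raw (unlogged) scale —
  the conventional scale for instrument QC — with the median over batches
  required below 0.25. Targeted (MRM) transitions face three gates: blank ≤
  0.1 × sample mean, QC CoV ≤ 0.25, and Pearson r ≥ 0.9 between log
  intensity and log dilution factor over the dilution-QC series.
* **Normalization.** x′ = log10(x) − (s_j − mean s) − (w_j − mean w), where
  s_j and w_j are the log10 internal-standards median and wet weight of
  sample j; then each lipid is centered per individual over that individual's
  regions. After this step per-(lipid, individual) means are exactly zero, so
  all downstream contrasts are within-brain. Expression data follow the
  analogous cascade: TPM > 1 in at least one sample, protein-coding only,
  log10 (zeros floored at 0.01 to keep the transform defined), per-sample
  median alignment, per-(gene, individual) centering.

## Annotation

The theoretical grid enumerates (class, total carbons, total double bonds,
adduct) with m/z composed from the class registry's base elemental formula
plus C_n H_(2n−2d). Matching is symmetric ±10 ppm. Duplicate peaks (≤10 ppm,
≤1 s apart) are grouped by single linkage and only the highest-total-intensity
member survives; single linkage makes the operation idempotent and
order-independent. The grid-consistency filter replaces visual curation of
the m/z–rt "grid": per (class, adduct) group of ≥4 candidates a robust (Huber)
fit rt ~ a·C + b·DB + c is required to satisfy the chromatographic sign
expectations (a > 0, and b < 0 where double bonds vary) — otherwise the whole
group is rejected — and candidates beyond 0.5 min of residual are dropped.
Groups too small or degenerate to fit pass through flagged `unfiltered`.
There is no printed ground truth to calibrate the 0.5 min threshold against;
it is configurable and was chosen as roughly ten times the retention-time
reproducibility of modern LC gradients.

Cross-dataset matching first pairs peaks within ±10 ppm and a coarse ±120 s
window, fits a monotone retention-time warp on those anchors (isotonic
regression with interpolation — the contract is only "smooth and monotone"),
re-matches within ±30 s after warping, and removes any peak matched
non-uniquely on either side. With fewer than 10 anchors the warp is refused
and an identity warp used, with a warning.

## Five-category classification

1. One-way fixed-effects ANOVA per lipid across regions, individuals as
   replicates (the model is `lipid ~ region`; no individual term, because the
   per-individual centering has already removed individual means), BH over
   lipids, default α = 0.01.
2. ANOVA-significant lipids: ordinary least squares of the per-region mean
   profile on myelin content. BH is applied within the ANOVA-selected subset
   (the only family actually tested), default α = 0.05. Significant positive
   slope → *myelin+*; negative → *myelin−*; otherwise *unexplained*. Fitting
   on per-region means matches the region-level picture of the myelin
   relationship; per-sample fitting is available as an option.
3. ANOVA-non-significant lipids: within-region variability is the pooled
   standard deviation of residuals after removing per-region means. The
   housekeeping/variable threshold is μ + σ of the Gaussian component of the
   variability distribution. "Gaussian component" is estimated robustly by
   default (μ = median, σ = 1.4826 × MAD), which tracks the dominant mode and
   ignores the heavy right tail contributed by genuinely variable lipids; a
   two-component Gaussian-mixture estimator (lower-mean component) is
   available behind a flag. Lipids at or below the threshold are
   *housekeeping*; above it, *variable*.

The categories always partition the input; the procedure is deterministic,
invariant to lipid order and equivariant under region relabeling. Note that
BH at α with hundreds of true discoveries implies a small number of expected
false entries from the null pool into the *unexplained* category (that is
what FDR control means); the recovery tests therefore assert an overall ≥95%
criterion and the strict absence of myelin+ ↔ myelin− sign confusions rather
than zero error.

Cross-dataset concordance labels a lipid **good** when two datasets agree on
its category, **neutral** when they disagree but the lipid shows no regional
significance in at least one dataset (the disagreement is then uninformative),
and **bad** when they disagree with regional significance in both. The
"neutral" wording in the underlying protocol is ambiguous; this reading is the
implemented one.

## Cell types, hierarchy, connectivity

* **Assignment.** Pearson correlation of each lipid's per-region profile with
  every marker gene's expression profile over the shared regions; the lipid
  takes the cell type of the top marker if R > 0.5 **and** two-sided
  p < 0.01. Both gates are enforced; at ~35 shared regions the R gate is
  binding, so the double gate changes nothing while satisfying both published
  threshold statements. An exact tie between markers of different cell types
  yields no assignment.
* **Enrichment.** One-sided hypergeometric over-representation of each cell
  type in each category against the all-lipids background, BH over pairs.
* **Hierarchy.** OLS of per-region mean intensity on the numeric level 1–4
  (treated as numeric, matching the published linear model; ordinal
  alternatives are out of scope), BH, α = 0.05 → HR+ / HR− sets. Chemical
  properties (class allocation, unsaturation, omega-3/omega-6 flags) of those
  sets are tested against background prevalence with two-sided exact binomial
  tests, BH per family.
* **Mantel.** For lipid profile v over FC-covered regions, the statistic is
  the Pearson correlation between the upper off-diagonal triangles of v vᵀ
  and the FC matrix (the FC similarity matrix is used directly). The null
  permutes region labels; p is one-sided (greater) with the add-one
  convention p = (1 + #{null ≥ obs})/(n_perm + 1), or exhaustive when ≤ 7
  regions. The batch variant shares one permutation set across lipids for
  speed. Note that v and −v give the same outer product, so both myelin+ and
  myelin− lipids can associate with an FC structure aligned with the myelin
  axis.
* **PC sign convention.** Principal components are oriented to correlate
  positively with a supplied anchor (myelin for the lipidome PCs, the
  lipidome PC for FC PCs); without an anchor, the largest-magnitude loading
  is made positive. The chosen anchor is recorded in the output.

## Statistical primitives

BH adjustment and the permutation engine are implemented in the package;
hypergeometric, Fisher-exact and rank tests wrap scipy's exact routines.
Every primitive is tested against an exhaustive-enumeration oracle on small
instances. Rank tests use the exact null for combined n ≤ 12 without ties and
the tie-corrected normal approximation otherwise, recording which mode was
used. Fisher's two-sided p uses the probability-ordering definition. Note
that step-up BH is *not* pointwise idempotent (e.g. [1.0, 0.25] → [1.0, 0.5]
→ [1.0, 1.0]); the suite asserts agreement with an independent implementation
and rank monotonicity instead.

## Synthetic atlas

The generator plants, per region: a bimodal myelin covariate (gray-like mode
1.35 ± 0.12, white-matter-like mode 1.90 ± 0.08, 20% of regions in the high
mode — the two-point summary of published T1w/T2w distributions); cell-type
fractions from a softmax of Gaussian latents with the OD latent coupled to
myelin (coupling 1.5, other latent sd 0.7); hierarchy levels 1–4 on the 56
cortical regions; and an FC matrix over 59 regions combining a
community-indicator term and a rank-one term aligned with the myelin axis,
symmetrized with unit diagonal.

Lipid log10 intensities are base + individual offset + category signal +
Normal(0, noise_sd) noise, with defaults noise_sd = 0.2 and:

* myelin±: ±β_myelin × centered myelin, β_myelin = 2.0 (≈ effect-to-noise 3
  at the observed myelin spread);
* unexplained: β = 0.8 times a z-scored driver — either a cell-type
  log-fraction or the hierarchy gradient — **residualized against myelin**,
  which makes these lipids regionally variable yet exactly
  myelin-uncorrelated in expectation (effect-to-noise 4);
* housekeeping: no regional term;
* variable: additional iid Normal(0, 0.6) individual × region noise — a
  high individual-by-region interaction with no shared regional profile.

Lipid names are drawn without replacement from category-typical class
palettes (sphingolipids and ether lipids for myelin+, LPC/PE/PC for myelin−,
free fatty acids among housekeeping), so class-enrichment and fluidity
analyses have realistic inputs. Technical factors (wet weights, standards
medians) are planted on the raw scale and removed exactly by the
normalization cascade; in the noiseless limit the fitted myelin slopes equal
the planted β to machine precision.

The synthetic peak-table generator plants a chromatographic grid
rt = 0.30·C − 0.45·DB + class offset with 0.02 min noise and ≤8 ppm mass
error, plus background decoys uniform in m/z and rt. Its default classes
(PC, SM, Cer) are mutually mass-unambiguous under one adduct; PC and PE, by
contrast, are exactly iso-elemental at a 3-carbon offset and can never be
separated by MS1 mass alone, which is why class-specific adducts and
fragmentation exist in real workflows.

**What the generator does not emulate:** correlated noise between lipids of
one class, batch and injection-order drift, adduct/isotope cross-talk,
nonlinear detector response, dropout that depends on abundance, and any
spatial structure within a region. Passing the recovery tests therefore
demonstrates the correctness and calibration of the procedures under the
stated generative model, not their field performance on real spectra.

## Problem sizes and runtime

Validation runs use the full default atlas (419 lipids × 300 samples), 1000
null lipids for ANOVA calibration, 250 replicate datasets for the BH
family-wise calibration, ~120 Mantel tests at 99–999 permutations, and
~250-peak tables for annotation recovery. The complete suite plus the
acceptance script finishes in well under a minute on one CPU.

## Known limitations

* The myelin model is a straight line in T1w/T2w; saturating or threshold
  relationships would be attributed partly to *unexplained*.
* The housekeeping/variable split inherits the μ + σ convention: about 16%
  of a genuinely Gaussian housekeeping bulk sits above μ + σ by definition,
  so the split is conservative toward *variable* when the bulk dominates.
* Cell-type assignment is correlation-based, not a deconvolution; strongly
  correlated marker profiles (e.g. neuronal subtypes) cannot be separated.
* With few individuals the within-region variability estimate is noisy;
  single-region effects may land in *housekeeping* or *variable* rather than
  *unexplained*.
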