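# Methods

## Scope and data model

The pipeline starts from segmented cells, not images: one row per cell with a
core id, planar coordinates in micrometers (origin at the core bounding-box
corner, y increasing downward — the image convention; documented, never
inferred), a tumor/stroma compartment call, and six boolean marker channels
(pan-CK, CD8, CD68, FOXP3, PD-1, PD-L1). The four lineage markers are treated
as mutually exclusive: a cell positive for more than one of CK/CD8/CD68/FOXP3
is a hard validation error by default, with an opt-in resolution mode that
keeps the highest-priority lineage (CK > CD8 > CD68 > FOXP3). PD-1 and PD-L1
are functional markers and may co-occur with any lineage. Cores are 1.2-mm
discs (area π·0.6² ≈ 1.13097 mm²) with at most two per patient.

## Synthetic cohort generator

The generator exists so that every downstream stage has planted ground truth.
It emulates:

- **Tumor architecture.** CK⁺ cells follow a Thomas-type parent–offspring
  cluster process: nest centers uniform in the core disc, offspring isotropic
  Gaussian around their parent, resampled until inside the nest mask. The
  mask is the union of discs of radius R around the parents, with R solved
  from the Boolean coverage model 1 − exp(−nπR²/A) = tumor_fraction so the
  expected tumor-area fraction equals the archetype's target. The
  immune-exclusion archetype uses more parents (35 vs 20) and tighter
  offspring spread (σ = 0.33·R vs 0.5·R) plus a higher CK density, planting
  the elevated tumor-cell-to-tumor-cell proximity the spatial module must
  detect.
- **Immune populations.** CD8/CD68/FOXP3 cells are homogeneous Poisson per
  compartment, realized by thinning a disc-wide process, so the expected
  whole-core count is density × area. A per-population tumor:stroma intensity
  ratio (default 1) lets the immune-exclusion archetype deplete CD8 inside
  tumor nests (ratio 0.2).
- **Phenotype archetypes.** Five archetypes with whole-core density targets.
  Published overall median densities anchor five of them (immune-desert CD68
  134.32 and CD8 109.63 cells/mm²; TIL-rich CD8 695.45; immune-exclusion CD8
  106.87 and CK⁺PD-L1⁺ 6,445.38, the last pinned via the PD-L1|CK rate at CK
  density 9,000). All other targets and marker rates are the generator's own
  choices, flagged `assumed` in the provenance column of
  `synthetic.archetype_table()`; they were set once to create contrasts of
  the same order as the anchored values (e.g. FOXP3 180 vs 15–60 cells/mm²,
  CD68 900 vs 134–300) — strong enough that a cohort of ~404 cores separates
  into five clusters, which is what the source cohort's printed medians imply.
- **Cohort structure.** 235 patients; a second core with probability 169/235
  (expected 404 cores); core archetypes drawn from the published cluster
  shares (69.1 / 4.5 / 19.3 / 3.5 / 3.7%); the second core repeats the first
  archetype with probability 0.7, mirroring the predominantly "pure"
  desert/exclusion patients.
- **Outcome.** Relapse ~ Bernoulli(invlogit(β₀ + β₁·carrier)) with
  β₀ = logit(0.012) and β₀ + β₁ = logit(0.48): 48% relapse among
  immune-exclusion carriers vs 1.2% background, which reproduces the
  reference margins (~52 carriers, ~27 relapses among 221 evaluable).
  Relapse times are lognormal with median 31 months (log-sd 0.72, matching
  an 18–50 interquartile span); censored follow-up is lognormal capped at
  120 months, with a 6% short-follow-up fraction that exercises the 36-month
  exclusion filter. Clinical covariates (FIGO, grade, LVSI, adjuvant RT,
  molecular statuses) are drawn at the reference cohort's marginal rates but
  carry **no outcome signal**: the generator's relapse model is driven by
  exclusion carriage alone. Consequently the synthetic reference model's AUC
  hovers near 0.5–0.6 rather than the ~0.78 a real cohort shows; passing
  tests demonstrate pipeline correctness and planted-effect recovery, not
  clinical performance.

Everything is driven by one `numpy` Generator seeded from the config, so a
config + seed reproduces byte-identical cohorts. The generator does not
emulate staining intensity, cell morphology, segmentation error, marker
spillover, or spatially correlated immune infiltration beyond the
compartment-level ratios.

## Feature extraction

Densities are counts over area. Per-compartment areas are not part of
per-cell exports, so they are estimated as (compartment cell count / total
cell count) × core area, with a supplied-area override; whole-core density is
therefore always (tumor + stroma count)/area, and the additivity and
area-rescaling invariants hold exactly. The canonical variable list is the
densities of CD8, CD68, FOXP3, CK, CK∧PD-L1, CD8∧PD-1 and CD68∧PD-L1 in
tumor/stroma/whole scopes, the PD-1|CD8 and PD-L1|CD68 fractions per
compartment, the PD-L1|CK fraction, and the two expression gradients.
Fractions with an empty denominator are missing, never zero. Clustering uses
the per-compartment **densities only** (14 variables), which avoids imputing
undefined fractions; the fractions and gradients are reported alongside.

## Clustering and naming

Scaling is column-wise z-scoring with the population SD (ddof = 0);
zero-variance columns (e.g. stromal CK density, structurally zero) map to
zeros with a warning, and scaling is idempotent. Linkage is Ward on Euclidean
distance — the standard pairing for scaled density heatmaps — pinned for
determinism; k is pinned to 5 in the reference configuration, with
`choose_k` (silhouette-maximizing, bootstrap Jaccard as a secondary
diagnostic, "no support for k>1" flagged when all silhouettes are weak)
available for sensitivity analysis. Stability follows the clusterboot recipe:
resample rows with replacement, recluster, match each original cluster to the
bootstrap cluster with maximal Jaccard over the resampled positions; a
cluster absent from a resample scores 0 for that replicate. Naming ranks the
cluster OMD table in a fixed rule order (CD8 → CK∧PD-L1 → CD68 → FOXP3) with
ties broken toward the larger cluster; when k < 5 specialist names are
assigned only while more than one cluster remains, so a two-cluster
desert-vs-TIL split names correctly. The residual cluster must also hold the
minimal total immune OMD to be called immune-desert, otherwise it stays
`unnamed` with a warning.

## Spatial metrics

"Close contact" is Euclidean distance ≤ r (closed ball — pinned so the grid
implementation equals the brute-force oracle exactly), with r = 20 µm by
default; the radius is configurable and stamped into every result record,
since the underlying proximity threshold is a modeling choice rather than a
measured constant. Neighbor search hashes points into a uniform grid with
bin side r and scans the 3×3 bin block. The headline statistic is the mean
target count per source cell, with self excluded whenever a source cell is
itself a target; no source cells gives a missing value, no targets gives 0.
Population self-clustering (e.g. CD8 vs CD8) is the same operation with a
reflexive query. Edge-count conservation (M[a][b]·n_a = M[b][a]·n_b),
translation invariance and radius monotonicity are tested invariants.

## Outcome layer

Patients aggregate their cores into carriage (≥1 core of a phenotype) and
purity (all cores) indicators; purity implies carriage, and single-core
patients have purity = carriage. Covariate encoding: FIGO ordinal
(IA=0, IB=1, II=2), grade binary (G2=1), LVSI binary; carriage indicators
enter the candidate set, purity flags are available but excluded by default.
Non-relapsed patients with <36 months of follow-up are excluded; relapsed
patients are always retained.

Logistic fits use iteratively reweighted least squares, converging when the
largest coefficient change is < 1e-8 (≤100 iterations); fits that fail to
converge or hit a singular information matrix (quasi-separation) are
refitted with a 1e-6 ridge and flagged. Model selection evaluates every
non-empty candidate subset (≤20 candidates) by 20-repeat stratified 2-fold
cross-validated misclassification at the fixed probability cut 0.5; ties go
to fewer features, then lexicographic order. The Youden cut-off is applied
only after selection, for stratification; Youden ties resolve toward higher
specificity, and the candidate cut set includes +∞ (classify none positive).
AUC uses the rank (Mann–Whitney) identity with half credit for ties. The
paired bootstrap resamples patients with replacement (redrawing degenerate
single-class resamples), computes both models' AUCs on each resample, and
counts strict wins — exact AUC ties are excluded from both counts, so with
literally identical score vectors every replicate is a tie. Kaplan–Meier
curves and the two-group log-rank test come from `lifelines`. Fisher tests
are exact for 2×2; larger tables use a seeded Monte-Carlo over fixed-margin
tables (probability-ordering two-sided rule, +1 smoothing), flagged
`monte_carlo` in the result. Subgroup evaluation rescores *fixed* fits per
stratum (no refitting); single-class strata are skipped with a flag and
strata with <5 events are flagged low-power.

A note on the 0.5 classification cut: a binary risk factor whose high-risk
event rate stays below 50% (as carriage does at 48%) is nearly invisible to
misclassification error even when it dominates the AUC; selection on the
synthetic cohort therefore leans on the cross-validated error differences
near the base rate, while the AUC comparison shows the planted effect
unambiguously. This is a property of the selection criterion, preserved
deliberately.

## IHC surrogate tree

The CART screens whether intra-tumoral CD8, CD68, FOXP3 and tumor-cell PD-L1
densities suffice to recover the phenotypes. Splits are grown greedily on
Gini impurity (min leaf 5, max depth 5), then pruned bottom-up: a subtree is
collapsed unless it removes at least cp·R(root) misclassified training
points per additional leaf, with R the resubstitution misclassification risk
and cp = 0.01 — the relative-complexity convention of recursive-partitioning
software. Note that at these defaults pure-noise labels still support a
handful of leaves (depth-5/min-leaf-5 noise splits can beat the threshold);
pruning guarantees leaf count non-increasing in cp and training accuracy
never above the unpruned tree. Per-class precision TP/(TP+FP) is reported on
the fitting data (resubstitution, as in a screening analysis, stamped in the
report); classes never predicted get missing precision, never 0.

## Problem sizes and runtime

The reference configuration (235 patients, ~404 cores, ~2.4M cells, B = 100
stability bootstraps, 255-subset exhaustive search with 40 CV fits each,
10,000 comparison bootstraps) was chosen to match the emulated study's scale
and runs in about a minute on one CPU; the test suite uses the same cohort
once (session-scoped) plus smaller purpose-built simulations.

## Known limitations

- Compartment areas are cell-count proportions of core area, which biases
  per-compartment densities when cell size differs systematically between
  compartments; whole-core densities are unaffected.
- The generator's stromal densities, marker rates and within-patient
  correlation are assumed values; conclusions about real tissue require real
  cohorts.
- The synthetic clinical covariates carry no outcome signal, so the
  reference model's synthetic AUC understates what routine risk factors
  achieve clinically.
- The proximity analysis is a fixed-radius count; Ripley-type statistics and
  permutation enrichment are out of scope.
- Precision of the surrogate tree is resubstitution by design; held-out
  evaluation is available but not the default reporting mode.
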