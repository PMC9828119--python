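# timephen

Tumor immune microenvironment (TIME) phenotyping for multiplex-immunofluorescence
tissue-microarray (TMA) cohorts, aimed at low-grade, early-stage endometrioid
endometrial carcinoma.

Most of these patients are cured by surgery, yet 5–10% relapse, and the routine
risk factors (FIGO stage, tumor grade, lymphovascular space invasion) are weak
predictors in such a clinically homogeneous group. `timephen` implements the
full analysis path from segmented per-cell marker tables (pan-CK, CD8, CD68,
FOXP3, PD-1, PD-L1; tumor vs stroma compartment; x/y in µm) to an
immune-optimized relapse model, together with a seeded synthetic TMA-cohort
generator so the entire pipeline runs and is validated without any patient data.

## What it computes

- **Per-core profiles** — population densities *d = n/A* (cells/mm²) per
  compartment scope, conditional marker fractions such as
  P(PD-1⁺ | CD8⁺, tumor), and tumor-minus-stroma expression gradients
  100·(f_t − f_s) in percentage points.
- **Immune phenotypes** — Ward/Euclidean hierarchical clustering of z-scaled
  density profiles, cut at k = 5; cluster stability as the mean bootstrap
  Jaccard coefficient J(A,B) = |A∩B| / |A∪B| over B = 100 resamplings
  (clusterboot-style best matching); clusters named by ranking overall median
  densities (OMDs): TIL-rich (max CD8), immune-exclusion (max CK⁺PD-L1⁺),
  macrophage-rich (max CD68), FOXP3-rich (max FOXP3), immune-desert (rest,
  lowest total immune OMD).
- **Spatial interactions** — mean number of target-population cells within a
  closed ball of radius r (default 20 µm) of each source cell, computed by
  uniform grid hashing (exactly equal to the O(n²) scan).
- **Outcome layer** — patient-level phenotype *carriage* (≥1 core) and
  *purity* (all cores) indicators; exclusion of non-relapsed patients with
  <36 months of follow-up; logistic regression by IRLS; exhaustive subset
  search over clinicopathological + carriage covariates scored by 20×
  stratified 2-fold cross-validated misclassification; ROC AUC via the
  Mann–Whitney rank identity; Youden-index (J = sens + spec − 1)
  stratification with PPV/NPV; paired patient-level bootstrap AUC comparison
  (10,000 replicates); Kaplan–Meier relapse-free survival with log-rank test;
  Fisher exact enrichment tests.
- **IHC surrogate** — a Gini CART (min leaf 5, depth ≤ 5, rpart-style
  relative pruning cp = 0.01) mapping intra-tumoral CD8/CD68/FOXP3/PD-L1
  densities back to the phenotypes, with per-class precision; plus a
  simplified CD8 + PD-L1 two-marker triage tree.

The synthetic generator plants all of this structure: tumor nests from a
Thomas-type parent–offspring process (nest union = tumor compartment mask),
per-compartment Poisson immune populations, five density archetypes anchored
on published overall median densities, and a patient relapse model in which
carriage of an immune-exclusion core raises relapse probability from 1.2% to
48%.

## Worked example

```python
from timephen import synthetic, features, clustering, outcome

cohort, truth = synthetic.generate_cohort(synthetic.SyntheticConfig(rng_seed=1))
mat, manifest = features.build_feature_matrix(cohort)
assignments, report = clustering.assign_phenotypes(mat, k=5, B=100, rng=7)
print(assignments["semantic_name"].value_counts().to_string())

patients = outcome.aggregate_patients(assignments, cohort)
retained, excluded = outcome.filter_followup(patients)
ref, opt, boot, search = outcome.compare_models(retained, B=10000, rng=3)
print(f"reference AUC {ref.auc:.2f}, optimized AUC {opt.auc:.2f}")
print(f"bootstrap outperformance {boot.a_wins}/{boot.B}")
```

prints

```
immune_desert       277
immune_exclusion     77
foxp3_rich           16
til_rich             16
macrophage_rich      16
reference AUC 0.60, optimized AUC 0.91
bootstrap outperformance 10000/10000
```

Reading: of 402 simulated cores, 277 cluster as immune-desert and 77 as
immune-exclusion (every cluster had bootstrap Jaccard 1.0 here); after the
36-month follow-up filter 223 patients remain; a relapse model optimized over
immune-carriage covariates reaches AUC 0.91 against 0.60 for the FIGO/grade/
LVSI reference, and wins the paired AUC comparison in all 10,000 bootstrap
resamples (the reference covariates are pure noise under the generator, which
drives relapse through immune-exclusion carriage alone).

The same pipeline is scriptable from a shell: `timephen simulate`, `validate`,
`features`, `cluster`, `spatial`, `predict`, `tree` (see `timephen --help`).
Real cohorts enter through three delimiter-separated tables (cells, cores,
patients); heterogeneous export headers are mapped through a YAML *dialect*
(an inForm-like dialect ships built in).

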