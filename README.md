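# imctme

Spatial single-cell analysis of highly multiplexed tumor-tissue images
(imaging mass cytometry, ~1 µm/pixel), aimed at extracting *prognostic
spatial features* of the tumor microenvironment: which cell subtypes sit in
the tumor-enriched part of a sample, which cell pairs are nearest
neighbors there, and whether those quantities separate long-term (LTS,
overall survival ≥ 60 months) from short-term (STS, ≤ 20 months) survivors.

It is written for computational biologists working with IMC or similar
multiplexed imaging of solid tumors who want a transparent, scriptable
pipeline from pixels to survival models, with a synthetic-data module that
makes every stage testable against known ground truth.

## Pipeline

1. **Preprocess** (`imctme.preprocess`) — channel spillover is undone per
   pixel by non-negative least squares against a spillover matrix *S*
   (observed = *Sᵀ·*true); the nuclear channels (histone H3 + DNA
   intercalators) are min-max normalized, max-projected, median-filtered
   (2×2) and Gaussian-blurred (σ = 2 px) into a single segmentation image.
2. **Segment** (`imctme.segmentation`) — seeded watershed on the smoothed
   nuclear projection. Masks can be cut into 4×4 tile grids and exported as
   COCO-style *weak labels* to train an external instance-segmentation
   model; externally produced masks re-enter through the mask reader.
   Segmentations are scored per cell by the Sørensen–Dice coefficient
   2|x∩y|/(|x|+|y|) against a reference, and methods compared by paired
   *t* tests on per-sample Dice means.
3. **Phenotype** (`imctme.phenotype`) — per-cell marker means, z-scored
   within each image (z = (I − μ)/σ over the image's cells), then
   multi-round PhenoGraph-style clustering: Jaccard-weighted kNN graph +
   Louvain, with configurable rounds that keep some clusters and pool and
   re-cluster the rest.
4. **Spatial features** (`imctme.spatial`) — the *tumor-enriched region*
   is the 0.0005 cells/px² level set of the tumor-centroid density map
   (unit-mass Gaussian, σ = 15 px). Per sample: subtype **density** =
   in-region count / total tumor cells, and the **interaction statistic**
   Avg.C&nbsp;ₘʲ = N*ₘⱼ*/N*ₘ* — the average number of subtype-*j* cells
   within 20 µm of each in-region subtype-*m* cell. Features are compared
   between classes by unpaired *t* tests with Benjamini–Hochberg
   correction.
5. **Survival model** (`imctme.survival`) — class-balanced 80/20 split,
   Spearman filter (|r| > 0.2 vs class), decorrelation (keep one of each
   group with pairwise |r| ≥ 0.65), min-max scaling, recursive feature
   elimination under L2 logistic regression, leave-one-out CV to pick the
   model size, held-out accuracy/sensitivity/specificity/AUC.
6. **Omics link** (`imctme.omics`) — collapse probes to the
   highest-variance probe per gene, Spearman-correlate gene expression
   with subtype densities (|r| > 0.4, p < 0.05), filter by cell-type gene
   sets, and scan quantile cutoffs for the best-cutoff Kaplan–Meier
   log-rank test (with an explicit anti-conservatism caveat).
7. **Synthetic data** (`imctme.synth`) — tissues with subtype-specific
   marker profiles and tumor-cell nests, LTS/STS cohorts with planted
   density and co-localization effects, and expression matrices with
   planted Spearman correlations; all deterministic under hierarchical
   seeding.

## Worked example

```python
from imctme import synth, spatial, survival

tissue = synth.default_tissue_spec()
cohort = synth.generate_cohort(tissue, synth.default_cohort_spec(seed=7))
cells = synth.cohort_cell_table(cohort)
surv = synth.cohort_survival_table(cohort).set_index("sample_id")

feats = spatial.sample_feature_matrix(cells, tissue.tumor_subtypes, tissue.image_shape)
comparison = spatial.group_compare(feats, surv["class"])
print(f"{int(comparison['significant'].sum())} of {len(comparison)} features "
      "differ between LTS and STS (BH-adjusted p < 0.05)")

dens = feats[[c for c in feats.columns if c.startswith("density_")]].join(surv["age"])
report, trace = survival.run_cascade(dens, surv["class"], seed=0)
print("chosen features:", report.chosen_features)
print(f"LOOCV accuracy {report.loocv_accuracy[report.chosen_size]:.3f}, "
      f"test accuracy {report.test_accuracy:.3f}, AUC {report.auc:.2f}")
```

prints

```
10 of 42 features differ between LTS and STS (BH-adjusted p < 0.05)
chosen features: ['density_CD8_4']
LOOCV accuracy 0.844, test accuracy 1.000, AUC 1.00
```

The default cohort plants a higher cytotoxic-T-cell (CD8_4) density and a
stronger CD8_4–tumor co-localization in long-term survivors; the group
comparison flags the planted shift (plus its correlated neighbors), and
the feature-selection cascade recovers `density_CD8_4` as the prognostic
feature on held-out samples.

The same stages are available from the shell:

```bash
imctme synth cohort --seed 7 --out cohort/
imctme spatial --cells cohort/cells.csv --survival cohort/survival.csv \
    --tumor-subtypes tu_1,tu_2 --out spatial/
imctme survive --features spatial/features.csv --survival cohort/survival.csv \
    --mode density --out model/
```

## Scope notes

Training the external instance-segmentation network itself (GPU), vendor
MCD file parsing, RMA normalization, and t-SNE visualization are out of
scope: the package exports/ingests their interchange formats instead. See
`docs/methods.md` for the model details, parameter choices, and known
limitations.
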