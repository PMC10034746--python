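# lipidcolony

Single-cell spatial lipidomics of stem-cell colonies: co-registration of
confocal microscopy with MALDI mass-spectrometry imaging (MSI), per-cell
lipid-feature tables, and the multivariate models that read differentiation
state from phospholipid abundances.

## The problem

Induced pluripotent stem cell (iPSC) colonies undergoing spontaneous
differentiation change their phospholipid profiles — phosphatidylinositol
(PI) and phosphatidylethanolamine (PE) species in particular — earlier than
standard pluripotency markers such as Oct4 decline. Measuring this at the
single-cell level requires fusing two modalities that share no landmarks:
confocal fluorescence (Hoechst nuclei + surface markers, ~0.65 μm/px) and
MALDI MSI (negative mode, m/z 200–1600, 10 μm raster). This package
implements that fusion and the downstream analysis for anyone building or
validating such a pipeline:

1. **MSI ingest** — imzML+ibd I/O, iterative-convolution baseline removal,
   peak binning at a 20 mDa minimum interval width (single-linkage
   merging), ion images, and automated screening of colony-associated
   features.
2. **Co-registration** — the Hoechst reference is rotated, shifted, and
   scaled against the mean ion image until the mutual information
   I(A;B) = Σ p(a,b) log₂ [p(a,b)/(p(a)p(b))] of their joint intensity
   histogram is maximal (coarse-to-fine search + simplex polish, with a
   permutation floor for failure detection).
3. **Cell tables** — nuclear segmentation (Otsu + watershed), contour
   mapping into MSI pixel space, mean ion abundance per nucleus and m/z
   feature, colony edge distances, k-means mitosis detection, and a
   neighbor-relative log-abundance metric that cancels smooth
   matrix-deposition background.
4. **Models** — PLS regression of differentiation day (validation R²),
   decision-tree staging with the pluripotent/intermediate/differentiated
   class collapse and predictor importance, PLS-DA phenotype classifiers
   with VIP-based variable trimming, and a 3-population PLS-DA projection
   space in which PC1 reads time and PC2 reads lineage fate.
5. **Synthetic colony phantoms** — paired confocal + MSI data with full
   ground truth (true transform, phenotypes, mitotic flags, edge
   distances, expected abundances), so every stage is testable without any
   instrument data.

Because no raw dataset of this kind is deposited publicly, all quantitative
claims are validated as recovery of planted structure in the phantoms; see
`docs/methods.md` for the model, parameter defaults, and what the phantoms
do and do not emulate.

## Worked example

```bash
python examples/03_staging_models.py
```

generates an 8-day synthetic series (800 cells/day) with an independent
replicate, fits the staging models, and prints:

```
PLSR validation R^2: 0.998
tree 8-class accuracy: 0.909; 3-class (pluripotent/intermediate/differentiated): 0.971
top predictors: m/z 1193.1 31%, m/z 1294.2 15%, m/z 1425.9 13%, m/z 915.8 13%
m/z 885.5 per-day medians vs %Oct4+: R = -0.97
```

Reading: per-cell lipid profiles predict the day of differentiation on the
held-out replicate almost perfectly at these planted effect sizes; the
collapse to three stages can only merge errors away, so 3-class accuracy
exceeds 8-class; predictor importance concentrates on a few informative
ions; and the late-rising PI 38:4 ion anticorrelates with the per-day
percentage of Oct4-positive cells. Likewise,

```bash
python examples/06_bifurcation_projection.py
```

```
Spearman(PC1, day) = 0.979  (PC1 is the time axis)
PC2 sign separates NCAM1+/SSEA1+ arms for 90.8% of day-6/7 cells  (PC2 is the fate axis)
m/z 778.5 NCAM1+ vs SSEA1+: t = 16.6, p = 2.0e-51
```

shows the lineage bifurcation under PI3K inhibition in the projection
space. The other `examples/*.py` scripts cover phantom generation,
registration + extraction, phenotype PLS-DA with trimming, spatial/mitosis
analyses, and the full pipeline (`lipidcolony run --demo` from the shell).

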