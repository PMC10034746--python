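# Methods

`lipidcolony` reconstructs, as a tested pipeline on synthetic data, a
multimodal single-cell lipidomics workflow for stem-cell colonies: confocal
microscopy (Hoechst + three surface-marker live stains at 0.65 um/px) is
co-registered with MALDI mass-spectrometry imaging (negative mode, m/z
200–1600, 10 um raster; 25 um for ultrahigh-resolution-style runs), nuclear
outlines are mapped onto the ion images to produce one lipid profile per
cell, and a suite of latent-variable and tree models reads differentiation
stage, pluripotency phenotype, lineage bifurcation, proliferative state,
and spatial colony organization from those profiles.

Because no raw imaging data of this kind is publicly deposited, the package
ships a colony phantom generator with complete ground truth; every claim
the pipeline makes is validated as *recovery of planted structure*, not as
reproduction of any instrument dataset.

## MSI ingest and feature building

**Containers.** An `MSIDataset` is a rectangular pixel grid of centroid
spectra (strictly increasing m/z, non-negative intensities) with a um/px
calibration. imzML+ibd pairs are read and written through pyimzml;
coordinates are converted between imzML's 1-based (x, y) and the internal
0-based (row, col) with pixel centers at integer coordinates. m/z and
intensity are stored as float64 so a write→read round trip is bit-exact.
The writer accepts a caller-supplied UUID so repeated exports of the same
phantom are byte-identical.

**Baseline removal** (profile spectra) iterates `b ← min(b, smooth(b))`
from `b = intensity` with a moving-average kernel of width `window`
(default 1 Th) until convergence or `max_iter` (default 20) passes, then
subtracts and clips at zero. The iteration drives the envelope down under
broad pedestals while sparing peaks much narrower than the window; a flat
spectrum maps to exactly zero.

**Peak binning.** Centroid peaks pooled over all pixels are merged by
single-linkage with a minimum interval width of 20 mDa: consecutive sorted
centers closer than 20 mDa join one feature, whose center is the member
mean and whose interval is `center ± max(10 mDa, observed spread)`;
overlapping neighbour intervals are cut at the midpoint between centers
(adjacent cluster centers are necessarily ≥ 20 mDa apart, so every feature
keeps at least the minimum width). The 20 mDa figure is read as a *full*
interval width. On 1-D data this merging rule is exactly single-linkage
clustering at threshold 20 mDa, which is what the test suite checks against
an independent hierarchical-clustering oracle. Features present in fewer
than `min_pixel_fraction` (default 1%) of pixels are dropped.

**Ion images** use the SUM of in-window centroid intensities per pixel
(robust to centroid splitting; configurable to MEAN), and the registration
reference is the per-pixel mean over all centroids ("mean ion image").
Optional per-pixel TIC normalization exists but is off everywhere by
default. **Feature screening** automates the selection of
colony-distributed features: a feature is kept when the point-biserial
correlation between its ion image and the colony mask exceeds a threshold
(default 0.3). Matrix cluster ions, present uniformly across the slide,
are rejected by this rule.

## Co-registration

The Hoechst reference is Gaussian-blurred (sigma = half the MSI pitch),
resampled to the MSI pitch, and aligned to the mean ion image by maximizing
the mutual information (MI) of the joint 32-bin histogram of min–max-scaled
intensities, over rotation, (x, y) shift, and residual scale (defaults:
±15°, ±50 MSI px, ±10%; rotation about the image centers). Out-of-overlap
pixels are excluded from the histogram.

The optimizer is coarse-to-fine: (1) a global 4-D grid on 4×-downsampled
images (steps 3°, 8 px, 4%); (2) cyclic per-parameter scans at full
resolution at 1°/1 px/1% then 0.25°/0.25 px/0.25% steps; (3) a Nelder–Mead
polish. A dense fine-stepped 4-D grid over the default box would cost ~10^6
MI evaluations; the scan/polish refinement reaches the same optimum at
~10^4. Grid ties break toward the smallest parameter norm from identity, so
the search is deterministic.

Three estimator safeguards matter in practice and are part of the design:

- **Histogram occupancy.** Bin counts adapt to image size
  (`bins = clip(sqrt(n_px/4), 4, 32)`); with 32² joint bins on a few
  hundred pixels the MI estimate is saturated noise.
- **Minimum overlap.** Candidates retaining less than 30% of the identity
  overlap are rejected — small-overlap MI estimates are biased upward and
  otherwise win the grid.
- **Supersampling** (optional, used for small MSI grids such as the
  phantom's ~60 px frames): the fine levels are scored on a 2× bilinearly
  upsampled grid, which lowers the sampling noise of the joint histogram
  below the MI differences being compared.

A permutation floor (the maximum MI over 20 pixel-shuffled overlaps of the
identity warp) flags registrations whose best score is no better than
chance (`converged=False`). Recovered transforms are reported as an
`AffineTransform2D` (rotation, shift in um, residual scale, pitch, centers,
plus the derived homogeneous matrix) and serialized as JSON. Mapped
nuclear contours keep sub-pixel coordinates; footprint rasterization
happens only at extraction.

On planted same-modality pairs (200² px, 5% noise) recovery is ~0.02°/
0.02 px/0.05%. On the cross-modality phantom (nuclei vs lipid deposits,
~60 px grids) recovery is typically ≤ 1.5°, ≤ 0.3 px, ≤ 2% scale; the scale
axis is weakly identified there because a 1% change moves the colony rim by
only a quarter pixel while the two modalities disagree about the rim at
about that scale.

## Cell-feature tables

Nuclei are segmented from Hoechst by Gaussian smoothing (1.3 um), Otsu
thresholding, and a distance-transform watershed (peak separation 4 um),
filtered to 25–400 um² (an iPSC nucleus is ~10 um across). Per-nucleus
records carry centroid, area, eccentricity, solidity, mean Hoechst, mean
marker fluorescence under the nuclear mask (a proxy for the cell; no
cytoplasmic segmentation), and the contour polygon in um.

**Extraction.** Each contour is mapped through the transform; its footprint
is every MSI pixel whose center falls inside the polygon, or — for
sub-pixel nuclei, the common case at 10 um pitch — the single pixel
containing the mapped centroid. The per-feature abundance is the mean ion
image value over the footprint. This rule is checked *exactly* against an
independent shapely-based point-in-polygon oracle.

**Spatial context.** The colony mask is the morphological closing (disk
radius 30 um, computed via two Euclidean distance transforms, then hole
filling) of the union of nuclear masks; edge distance is the mask's
distance transform at the centroid, in um. Edge-distance summaries use
100 um bins (7 groups, last open-ended) with mean and 25th/75th
percentiles.

**Mitosis detection** is 2-means on standardized {area, eccentricity,
Hoechst mean, solidity}; the cluster scoring higher on standardized
Hoechst-minus-area is the mitotic one (condensed, bright chromatin).
Labels are invariant to affine rescaling of any feature and bit-stable
under a fixed seed.

**Neighbor-relative abundance** of cell *i* is
`log(a_i + eps) − median_j log(a_j + eps)` over its k = 20 nearest cells;
it cancels smooth multiplicative background (matrix-deposition unevenness)
and is invariant to global rescaling. Dividing-vs-non-dividing differences
are tested with a two-sided Mann–Whitney U on these values (the "median
difference" test).

## Model suite

All PLS-family models operate on log-transformed (`log(x + 1e-9)`),
standardized abundances — ion intensities carry multiplicative noise, so
log-space makes class geometry linear; trees are monotone-invariant and
take raw abundances. Validation is always an independent replicate
realization (same expected abundances, fresh noise), never a random
within-sample split.

- **Phenotype labeling**: 2-means (K=2) on the standardized intensities of
  the two competing marker channels; clusters are named by which channel
  they dominate, so the labeling is symmetric under channel swap.
- **PLSR staging**: PLS regression of day on abundances (default 5
  components), reporting validation R².
- **Tree staging**: CART (Gini, max depth 8, min leaf 50), 8-day classes;
  day labels collapse through the fixed partition pluripotent {0–2} /
  intermediate {3–5} / differentiated {6–7}, which can only merge errors
  away, so 3-class accuracy ≥ 8-class accuracy. Predictor importance is
  normalized impurity decrease (sums to 1).
- **PLS-DA**: PLS on a one-hot response with class-balanced column
  scaling; class decision by nearest training-class centroid in predicted-
  response space (argmax is miscalibrated under class weighting).
  **Variable trimming** is VIP-based backward elimination: drop all
  features with VIP < 1, refit, stop when validation accuracy would drop
  (reverting) or nothing is below threshold — so the trimmed model never
  validates worse than the untrimmed one. VIP uses the standard
  weights/explained-response-variance formula (mean square 1).
- **Projection space**: a 3-class PLS-DA (3 components) on day-0
  pluripotent cells and the two late lineage arms. The reported 2-D view
  uses deterministic axes inside the score space: PC1 is the early→late
  centroid direction (time), PC2 the between-arm centroid direction
  orthogonalized against PC1 and centered on the arm midpoint (fate), so a
  late cell's PC2 sign reads its lineage. With 2 components the arm
  contrast is visibly under-resolved, which is why 3 is the default.
- **Trajectories**: per-day median and quartiles per feature, plus Pearson
  R between the per-day medians and an external 8-long covariate (e.g. the
  percentage of Oct4-positive cells from flow cytometry, consumed as a
  given vector). **Lineage comparison** is a Welch two-tailed t test.

## Synthetic colony phantoms

The generator emulates the staggered-seeding design: eight independent
colonies, one per differentiation day 0–7, under one of four conditions
(control, PI3K inhibition at two doses, PEMT inhibition). Per-cell
expected abundance factors as

    base × trajectory(day) × lineage multiplier × edge gradient × background

with lognormal noise (sigma 0.4) on top; fluorescence is Gaussian around
bright/dim levels (180/35 ± 15 a.u.).

- **Geometry**: a smoothed star-convex boundary (harmonics 2–6, 15%
  irregularity) filled by a jittered hexagonal packing at 13 um spacing;
  the colony radius is derived from the requested cell count. True edge
  distances come from a fine-grid distance transform of the boundary.
- **Trajectory shapes** over days 0–7 (multipliers, all positive): stable
  growth 0.5→2.0; rise-then-fall peaking at day 2; flat at 0.8 through day
  4 then rising to 2.0; rapid decline `2 e^{−1.2 d}` (below 1% of its
  day-0 value by day 4); flat. The ~70-feature default panel pins 13
  anchor ions to these shapes with lineage enrichments (×1.8 in the
  enriched phenotype), edge gradients (±0.8 across 300 um), and mitotic
  enrichment (×1.6) matching the planted biology; the rest are filler with
  assorted shapes.
- **Phenotypes**: day 0 all pluripotent; control trades TRA-1-81+ for
  SSEA-1+ along a logistic in day and never expresses NCAM-1; high-dose
  PI3K inhibition yields a pure SSEA-1+/NCAM-1+ bifurcation on days 5–7
  reaching 50/50 at day 7, with the NCAM-1 quota assigned by proximity to
  seeded cluster centers (Matérn-style spatial clustering); PEMT
  inhibition shifts the loss of pluripotency ~2 days later. Mitotic cells
  (5%) are smaller (×0.55 area), brighter (×2.2 Hoechst), more eccentric.
- **Background**: `exp(0.25 × G)` with G a unit-variance Gaussian random
  field of 150 um correlation length, shared across features (it is a
  deposition artifact, not biology).
- **Imaging mode** renders 4-channel confocal stacks (ellipse nuclei,
  1 px PSF blur, additive noise) and deposits cell abundances onto the MSI
  grid (1.1 px spread — the lipid footprint of a cell exceeds its nucleus,
  keeping the colony interior contiguous at 10 um pitch), then emits
  centroid spectra with mass jitter (sigma 3 mDa, clipped at ±8 mDa so
  every peak stays inside its 20 mDa bin), two matrix cluster ions present
  everywhere, and a detection floor of 0.5 intensity units. **Table mode**
  skips rendering and emits the cell table a perfect extraction would
  produce — the fast path for model-level work.
- **Determinism**: all randomness flows from `default_rng([seed, day,
  stream, replicate])`; a replicate differs from its primary only in the
  noise streams (expected abundances identical), which is the
  biological-replicate validation convention used everywhere.

What the phantom does **not** emulate: optics beyond Gaussian blur,
profile-mode peak shapes, isotope envelopes, ion suppression, cell
crowding/overlap pathology, segmentation-hostile staining artifacts, or
day-to-day batch effects beyond the background field. Passing tests
therefore demonstrate correctness of the algorithms and recoverability of
structure at realistic effect sizes — not performance on any real
instrument's data.

## Problem sizes and numerical choices

Test and acceptance runs use the study's design at desk scale, chosen once:
500-cell colonies for imaging-level checks, 600–1,500 cells/day for
model-level series (the generator's default is 2,000), and the full demo
pipeline at 1,000 cells/day over all 8 days with a replicate.
Registration-recovery checks use 200² px same-modality pairs across the
full default search box. The acceptance script reports each quantity with
the problem size it used.

Degenerate inputs are handled explicitly: constant images have zero
entropy (MI 0 with a warning, and near-constant-at-float-epsilon counts as
constant); empty spectra survive imzML round trips; all-equal morphology
yields no mitotic calls; constant fluorescence yields unlabeled cells;
day values outside 0–7 and degenerate (all-true/all-false) colony masks
are contract errors.

## Known limitations

- Cross-modality registration resolves scale only to ~2% on small colony
  frames (see above); shifts and rotation are sub-pixel/degree.
- PLS-DA decision boundaries assume the validation mixture resembles
  training; heavily skewed late-day mixtures (e.g. day-7 control, ~95%
  SSEA-1+) degrade the fluorescence k-means labels themselves, so
  phenotype models are fitted at the last day where both arms are well
  expressed (day 6 in control).
- The pipeline treats days as independent samples (staggered seeding);
  there is no cell tracking, and no batch/normalization model beyond the
  neighbor-relative metric.
- MS/MS identities are carried as optional annotations only; nothing in
  the pipeline depends on them.
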