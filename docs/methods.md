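# Methods

## Landmark schema and geometry

A face is represented by 86 landmarks in pixel coordinates (x rightward,
y downward, origin at the top-left pixel), addressed by 1-based index in
file order.  All ratio features are quotients of Euclidean distances
d(m, n) between landmarks, so they are invariant under translation,
rotation and uniform scaling of the face — the property the test suite
verifies to 1e-9 relative tolerance under random similarity transforms.

Where a ratio definition places the expression "d(23, 37)/2" in a *point*
position, it is read as the **midpoint** of landmarks 23 and 37 (the
inter-brow centre): half a scalar distance cannot be an argument of
d(·,·), so the midpoint is the only reading that type-checks.

Two index maps ship.  The default, `"printed"`, follows the published
ratio table for this schema verbatim, including its internal
inconsistency: the nose-width denominator appears as d(65, 59) in golden
ratios 2 and 5 but as d(65, 69) in ratios 7, 8 and 13.  The alternative
map `"nose-width-corrected"` uses d(65, 69) everywhere.  One repair is
forced in both maps: the published mouth-width entry references landmark
87, which cannot exist in an 86-point schema, so the mouth-corner pair
(74, 80) — the pair the symmetry ratios identify as the mouth corners —
is used.  Golden ratio 8 is parenthesized as d(65,69) / (d(77,84)/2),
matching its "nose width over (half) upper-lip height" description.

The upper-brow symmetry ratio d(23, M)/d(35, M), with M = mid(23, 37),
equals 1 on a symmetric face only when landmark 35 lies at the same
distance from the inter-brow centre as landmark 23.  This is an
anatomical regularity of the schema, not a consequence of mirror symmetry
alone; the synthetic template is constructed to satisfy it exactly, and
the symmetric-set test generator restores it after jittering.

## Score normalization

The two-step normalization z-scores a value set and then maps it linearly
so the fitted minimum and maximum land exactly on configurable bounds,
default (0, 1.618) — the golden ratio as upper bound.  Choices the
formula leaves open:

- **std** is the population form (divide by n), the common z-scoring
  convention; a `ddof` switch gives the sample form.
- Applied to new data the map **extrapolates** beyond the bounds rather
  than clipping, preserving strict monotonicity; `clip=True` is opt-in.
- Normalization parameters are fitted on training rows only and then
  applied to test rows, avoiding leakage.

## Descriptor blocks

**GLCM (T).**  Intensities are quantized uniformly to G = 8 levels
(`level = v * G // 256`); co-occurrence counts are accumulated for four
unit offsets (0°, 45°, 90°, 135°), symmetrized (count + transpose) and
normalized to sum 1.  The four statistics are contrast Σ|i−j|²p(i,j),
homogeneity Σ p(i,j)/(1+|i−j|), correlation
Σ(i−μᵢ)(j−μⱼ)p(i,j)/(σᵢσⱼ) and energy Σ p(i,j)², computed per offset and
averaged — a direction-robust default.  Correlation is undefined on a
constant image (σ = 0) and is reported as NaN; fusion maps it to 0 with
a warning so batch extraction never aborts.  Note the homogeneity
denominator is 1+|i−j| (not 1+(i−j)²), which is why the statistics are
computed in-package rather than delegated to a library with a different
definition.

**Hu moments (S).**  Computed on the grayscale intensity surface (BT.601
luma 0.299/0.587/0.114, not a binary mask), with normalized central
moments η_pq = μ_pq / μ00^(1+(p+q)/2) and the standard seven invariant
combinations; no log transform by default.  Image coordinates are
(x = column, y = row); conventions indexing moments (row, column) differ
by a transpose, which flips the sign of the seventh (reflection-sensitive)
invariant.  A `"verbatim"` variant reproduces a circulating typographically
corrupted transcription of the formulas (h2, h4, h5 differ) for
auditability; it is not used in analysis.

**HSV histograms (C).**  H, S, V each on [0, 1], binned into 16 equal
bins per channel (values of exactly 1.0 in the top bin), each channel
L1-normalized, concatenated H ++ S ++ V (48 values).  Per-channel rather
than joint histograms keep the color block from dwarfing the 19 ratios.

Descriptors are computed on the full 350×350 frame; a region-of-interest
crop can be applied upstream if desired.

## Models

All models are trained on per-column standardized features (scaler fitted
on the training fold, stored with the model — required for KNN distances
to be meaningful across blocks of different scales) and predict on the
raw 1–5 scale.

- **LR**: ordinary least squares.
- **KNN**: inverse-Euclidean-distance weighting of the k nearest
  training rows; a query coinciding with training points receives the
  mean label of its exact matches (the 1/d limit).  When k is left
  unset it is grid-searched over 1..25 by Pearson correlation on a 25%
  validation slice of the training fold — the sweep tables the protocol
  produces imply such a search, and the one bracketed k setting quoted
  for it is unintelligible as printed.
- **RF**: 200 trees, max_features = p/3 (regression convention), seeded.
- **ANN**: one hidden layer of 32 sigmoid units, seeded initialization,
  up to 2000 epochs with early stopping on a 10% validation split
  (disabled below 50 training rows, where the split is degenerate).

Metrics are computed from their defining formulas (PC in product-moment
form); PC and R² are NaN-flagged when a variance term vanishes.  The
train/test split is a seeded 80/20 permutation partition.

## Ablation studies

The FS sweep retrains every model on the first c features of a retained
order, c = 4..19 by default.  The default order lists the 14 golden
ratios before the 5 symmetry ratios, so symmetry ratios are removed
first — the removal schedule under which golden ratios' stronger signal
is visible; the order is fully overridable.  Cardinalities 20..30 extend
the order with the 4 GLCM statistics and then the 7 Hu moments, a
documented reconstruction for sweeps past the FS.  The SFS lattice
evaluates exactly the 8 block subsets (Without, T+C+S, T+C, T+S, C+S, T,
C, S), each fused with the model's best FS cardinality from the sweep.
Every grid cell refits from scratch on the same seeded split, so cells
are comparable and reruns with a fixed seed are byte-identical.
Best-configuration selection breaks ties toward fewer features.

## Synthetic faces

The generator emulates the three artifacts a rated face dataset ships:
86-point landmark files, 350×350 frontal images, and 1–5 scores.

The template is a fixed, bilaterally symmetric 86-point layout (face
outline 1–22, brows 23–42, eyes 43–62, nose 63–70, mouth 71–86) on which
all five symmetry ratios are exactly 1.0 and all 19 ratios are finite and
positive.  `sample_face` can warp named golden ratios to target values by
rescaling the numerator landmark pair about its midpoint (infeasible —
midpoint numerators or shared numerator/denominator landmarks — raises),
and applies mirror-breaking Gaussian jitter anti-symmetrically, so the
symmetric component of the face is preserved.  Rendering is deliberately
schematic: a skin-colored face polygon on a darker same-tone background
with landmark-anchored dark features and seeded Gaussian speckle.  It
carries controllable hue, texture and shape signal into the descriptor
blocks; it does not model lighting, pose, identity or photographic
realism, so passing tests demonstrate that the pipeline recovers signal
it is pointed at, not that these features suffice on photographs.

`make_dataset` plants a named score function, maps the raw values
affinely onto the batch's [1, 5] range, adds Gaussian rater noise on the
latent scale (rater means are roughly continuous and unimodal) and clips
to [1, 5].  The shipped functions:

- `"ratio-linear"` — linear in the g01 and g14 targets; with zero noise
  the score is exactly linear in the extracted features (asymmetry jitter
  off so realized ratios equal their targets).
- `"hue-only"` — linear in hue alone.
- `"fusion"` — the standard study cohort: sd-unit weights 0.35 (g01),
  0.35 (g14), 0.9 (skin tone), 0.2 (texture).  Skin color is modelled as
  a 1-D tone axis (hue and saturation co-vary), so the color effect has a
  footprint in both the H and S histograms; hue stays in [0.05, 0.95] to
  avoid the circular wrap; texture speckle spans sd 9–15 (8-bit units);
  non-planted factors are held fixed so the planted effects are
  identifiable.  These choices make the fused signal recoverable by a
  distance-based learner while the ratio features alone explain only a
  minority of the signal variance — the regime in which the fusion
  comparison is informative.  Generation is bit-exactly reproducible from
  (seed, parameters).

## Problem sizes

The standard synthetic study runs at n = 500 faces with rater noise
sd 0.2; the test suite exercises the grid-shape and determinism contracts
on a 200-face slice with moderate model sizes (60 trees, 300 ANN epochs),
since those contracts do not depend on n.  Examples use n = 150 for
illustration.

## Known limitations

- The published ratio table's landmark-87 reference and d(65,59)/d(65,69)
  inconsistency mean "verbatim" reproduction is approximate by necessity;
  both readings are shipped and switchable.
- KNN's k-selection reconstruction (grid search) is an interpretation of
  an ambiguous protocol description.
- The renderer's schematic faces cannot validate descriptor behavior on
  real skin texture; conclusions about real photographs require the real
  dataset.
- Hu moments h2..h6 of blob-like faces are numerically tiny and carry
  little signal at 8-bit quantization.
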