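# Methods

This note documents the models and numerical choices behind each stage of
the hsibrain pipeline, the assumptions the synthetic phantom makes, and
what the tests do and do not demonstrate about real intraoperative data.

## Data model and conventions

A cube is `data[row, col, band]` with strictly increasing band
wavelengths. All indexing is 0-based `(row, col)`; row is the latitude
axis `h`, column the longitude axis `l` of the KNN feature space. Class
ids are fixed as normal = 1, tumor = 2, vessel/hypervascularized = 3,
background = 4, and probability vectors always use that order — a single
convention removes a whole class of silent-permutation bugs. Cubes track
a processing stage (`raw → calibrated → denoised → cropped → reduced →
normalized`) that can only advance.

On disk, cubes travel either as ENVI header + raw binary (BIL/BIP/BSQ all
supported; the three interleaves of one cube read to identical arrays) or
as a lossless NPZ container that additionally carries the stage and
metadata. The ENVI reader/writer is implemented here directly: the format
is a flat `key = value` text header plus a raw block, and owning it keeps
error reporting precise (a malformed field is named; a binary whose size
contradicts the declared geometry is a dimension error, not a crash).

## Pre-processing

**Calibration.** `reflectance = (raw − dark) / (white − dark)` per
pixel-band. Bands where `white == dark` (dead columns) output 0 and are
counted in the cube metadata rather than raising. Output is clipped to
`[0, 1.5]`: specular pixels can legitimately exceed the white tile, but
unbounded ratios destabilize the noise regression downstream.

**Noise estimation.** Each band is modeled as a linear regression on all
remaining bands across pixels; the residual is the noise estimate and the
fitted value the denoised signal. Rather than fitting B separate
regressions, the residuals are obtained at once through the precision
matrix: with `X` the pixels-by-bands matrix and `G = (XᵀX)⁻¹`, the
residual of regressing band *i* on the others is `X G[:, i] / G[i, i]`
(O(NB² + B³) instead of O(B · NB²)). If `XᵀX` is singular — exactly
linearly dependent bands — the code falls back to per-band least squares,
which correctly yields zero residuals; if there are fewer pixels than
bands a small ridge (`1e-6 · tr(R)/B`) keeps the system solvable. On
synthetic low-rank-plus-Gaussian cubes the estimator recovers the
injected noise sd within 20 % and tracks it monotonically.

**Band crop.** The keep-set is the open interval `(crop_low, crop_high)`
with defaults 50 and 750 on a 0-based axis: the stated limits themselves
are removed, leaving 699 of 826 bands. The arithmetic connecting 826,
the removals, and a "750-band" embedding input cannot be made consistent
under any convention, so the limits are configuration and the open-interval
reading is the documented default.

**Spectral averaging.** Contiguous groups, as equal as possible (sizes
differ by at most one, larger groups first), each output band the group
mean, down to 129 bands by default. 699/129 is non-integral, so the first
54 groups hold 6 bands and the rest 5. Chosen over sliding windows as the
simplest scheme that yields exactly the target count; it commutes with
per-pixel scaling and preserves constants.

**Normalization.** Per-pixel Euclidean norm (zero spectra left at zero).
The purpose of this step is to cancel the multiplicative illumination
differences of the non-flat brain surface, which a per-pixel scale
division does exactly; a property test confirms the whole chain is
invariant to a smooth multiplicative illumination field. `max` and
`minmax` modes are available as options.

The chain emits two cubes: the reduced 129-band cube (classifier input)
and the cropped full-band cube without averaging (embedding input).

## SAM labeling

The spectral angle `arccos(⟨a,b⟩ / (‖a‖‖b‖))` is scale-invariant, so
selection is robust to illumination. The threshold is *strictly* "less
than", in degrees by default with the conventional 0.08° tool default; a
`unit="rad"` switch is provided because angles that tight are unusual and
an operator may reasonably work in radians. Selections are monotone in
the threshold (enforced by a property test). Conflicting assignments
default to keep-first with a reported conflict count; overwrite and error
policies are selectable. `extract_dataset` flattens labeled pixels of any
number of (cube, label map) pairs into a signature table with a
per-patient/per-class count summary.

## Fixed-reference one-band embedding

The KNN filter needs a scalar guidance image `I` that encodes spectral
structure. Re-running a stochastic embedding per cube would give each
cube its own arbitrary coordinate system, so the embedding is trained
once on a fixed reference set and frozen: a 1-D t-SNE (perplexity 30,
capped at (N−1)/3 for small N; PCA initialization; fixed seed) over at
most 2,000 class-balanced labeled spectra, stored as a lookup table of
(spectrum, coordinate) pairs. New pixels get the mean coordinate of their
`lookup_k` (default 1) nearest references by Euclidean distance, and the
image is min–max normalized to [0, 1] (all-zero if constant). An
all-identical reference set short-circuits to coordinate 0. A
deterministic PCA-first-component mode (`method="pca"`) serves as a
closed-form regression check of the lookup machinery.

## Supervised stage

SVM via scikit-learn's `SVC` (libsvm): linear kernel and `C = 1` by
default, RBF/polynomial/sigmoid selectable with library-default kernel
parameters. Probability outputs use the built-in pairwise-coupled Platt
calibration — the filter averages probabilities, not decisions.
(scikit-learn deprecates `probability=True`; the warning is silenced at
the fit site because that calibration is precisely the behaviour wanted
here, and migration to an external calibrator is a contained future
change.) Classes absent from training receive probability zero in the
cube map so the vector layout stays fixed.

Evaluation is one-vs-all: sensitivity `TP/(TP+FN)`, specificity
`TN/(TN+FP)`, accuracy `(TP+TN)/total`, with zero-denominator metrics
flagged `None` instead of raising. Cross-validation is stratified 10-fold
(configurable), deterministic under seed, scored on hard predictions —
per-fold Platt fits would add cost without changing the counted outcomes.

## KNN spatial–spectral filter

Features `F(i) = (I(i), λ·l(i), λ·h(i))` with `l = col/(W−1)`,
`h = row/(H−1)` (0 on a degenerate axis). `λ = 0` removes all spatial
information; `λ` and `K` both act as smoothing knobs. The filtered map is
the mean probability of the K nearest neighbors by Euclidean distance in
feature space, the pixel itself included — which makes `K = 1` exactly
the identity. Neighbor search is an exact KD-tree (3-D features make this
cheap); distance ties at the K-th neighbor break by raster index, and a
brute-force O(n²) implementation is kept as an oracle, with exact
agreement required on images up to 32×32. Output probabilities are
renormalized to the simplex to absorb floating-point drift of the mean.

A note on "oversmoothing, quantified": total variation of the probability
field is *not* monotone in K — neighborhood averaging turns a sharp edge
into a ramp of equal total variation, and feature-space neighbors can
create new local variation — so the trend tests quantify smoothing as the
spatial variance of `O`, which decreases monotonically toward the global
mean as K grows through {5, 10, 20, 40, 60}.

## Hierarchical K-means

Bisecting K-means: all pixels start in one node; the leaf with the
largest within-cluster SSE is repeatedly split by 2-means (k-means++
seeding, 5 restarts, best inertia) until 24 leaves. The largest-SSE
criterion guarantees total SSE is non-increasing at every split (the
recorded `sse_path` asserts it); leaves partition the pixels and every
leaf is nonempty. A leaf of identical points falls back to a 1-vs-rest
split so the requested leaf count is always reached when pixels permit.
Segmentation runs on the 129-band reduced cube by default. With 24
clusters over a 4-class phantom the scene is oversegmented, which the
fusion tolerates (every cluster comes out ≥ 90 % class-pure in tests).

## Fusion and rendering

Per cluster, the class histogram of the filtered classification map is
normalized to fractions (hard-label frequencies; a soft-probability mode
would average `O` instead, but hard frequencies match the majority-vote
definition). MV paints each cluster its winning class's palette color;
exact vote ties go to the lowest class id and are reported, since a
silent tie would be invisible in the rendering. OMD scales the winner's
color by its fraction — except background, which stays pure black. TMD
mixes the colors of the three largest fractions weighted by their
fractions, dropping the smallest fraction without renormalizing (the
output is clipped to [0,1] as a guard); background's black participation
darkens mixed clusters, and tumor+vessel mixtures render purple — the
signature of tumor-infiltrated hypervascularized tissue.

## Synthetic phantom

The phantom emulates the statistical structure of an intraoperative
capture, not tissue optics. Endmembers are built from a shared smooth
positive "tissue envelope" (dim blue end, rising through red/NIR, cubic
spline over 7 control points) rotated along mutually orthogonal smooth
directions: tumor 10° from the envelope, vessel exactly
`tumor_vessel_angle_deg` (default 15°) from tumor — the closest pair, by
design, reproducing the known tumor/vessel confusion mechanism — normal
exactly `min_interclass_angle_deg` (default 20°) from tumor (and farther
from vessel, since orthogonal perturbations compound), background rotated
well beyond the minimum and kept dark (amplitude 0.15 vs 0.5–1.0 for
tissue). A final nonnegativity clip can shift angles by a fraction of a
degree, so tests re-measure them rather than assume them.

The scene is a background border (9 % of the short side), a central tumor
ellipse, two vessel polylines, and normal tissue elsewhere. Illumination
is a Gaussian-smoothed random field rescaled to [0.6, 1.4]. Additive
Gaussian noise has per-band sd `noise_sd · (1 + 3·pos⁸)` (`pos` ∈ [−1,1]
across the band axis), i.e. sd rises steeply at the spectral extremes the
crop step removes; default `noise_sd = 0.01` reflectance units. Raw
counts are synthesized by inverting the calibration equation against a
QTH-lamp-shaped white frame and a flat dark frame of 100 counts, so
`calibrate()` recovers `reflectance · illumination + noise` exactly.
Gold labels are a class-stratified random subset (default 15 % of pixels,
apportioned by largest remainder so the total lands within one pixel of
the target).

What the phantom does *not* model: absorption/scattering tissue optics,
inter-patient spectral variability, specular glints, motion or moisture
changes during acquisition. Passing the end-to-end tests therefore shows
the algorithmic chain is correct and self-consistent under its stated
assumptions — not that the chain reaches clinical accuracy on real
surgical data.

## Problem sizes and determinism

Unit tests run on 40×40×120 phantoms with proportionally scaled crop
limits; the full-scale parameter-recovery test runs the default
128×128×826 phantom once (tumor precision/recall ≥ 0.95 on the MV map,
10-fold CV > 99 %) and shares the run across its assertions. The
confusion-trend test sweeps the tumor–vessel angle through
{2°, 1°, 0.5°, 0.25°} at 48×48×160, where the confusion count rises
monotonically as the angle collapses. Every stochastic component (phantom
synthesis, gold sampling, t-SNE, SVM, 2-means restarts, fold shuffling)
is driven by an explicit seed, and identical inputs reproduce
bit-identical outputs — asserted for the whole pipeline.

## Known limitations

- The embedding approximates the fixed-reference t-SNE deployment
  contract (train once, look up forever); it does not reproduce any
  particular training protocol's coordinates.
- `SVC(probability=True)` is deprecated upstream; see above.
- The KNN filter's tie-break matches the brute-force oracle only for the
  self-distance; ties among distinct neighbors at the K-th rank are
  resolved by the KD-tree's ordering, which on continuous features is a
  measure-zero concern.
- HKM split selection (largest SSE) is one standard choice; spherical
  K-means or NMF-based splitters would slot into the same interface but
  are not provided.
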