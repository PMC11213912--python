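# Methods

## The model

The package implements a concept-bottleneck approach to TIL assessment: the
final score is a deterministic function of intermediate concepts a
pathologist can inspect — tissue-region masks and classified nucleus
instances — produced by a two-resolution panoptic segmentation network.

### Two-branch architecture

Two U-Net encoder–decoders run in parallel. The *region branch* sees a field
of view at 1.0 micron/pixel (10x objective); the *nucleus branch* sees the
central half of that footprint at 0.5 micron/pixel (20x). The geometric
invariant `hpf_px * 0.5 = roi_px * 1.0 / 2` makes the two output grids the
same pixel size, which keeps cropping and upsampling exact (integer factors,
aligned centers). Defaults: depth 5, base 32 channels, 512-px inputs; the toy
profile used in tests and the acceptance script is depth 3, base 8, 64-px
inputs.

Region context reaches the nucleus branch in two places:

1. **Feature hook.** The region decoder's feature map at one decoder level
   (default: level 2 above the bottleneck in the full profile, level 1 in the
   depth-3 toy profile) is center-cropped to the high-power-field footprint,
   2x nearest-neighbor upsampled, and concatenated onto the nucleus decoder
   at the same level. A single mid-decoder hook is the minimal version of
   cross-resolution concatenation; the level is configurable.
2. **Class-specific attention.** Softmaxed region probabilities are cropped
   and nearest-upsampled to the nucleus grid (nearest interpolation preserves
   per-pixel distributions), then mixed with the compatibility kernel K and
   the learned prior P: `A_c(x) ∝ Σ_r p_r(x) K[r,c] P[r,c]`, floored at
   1e-8 and renormalized over classes. The constraint multiplies the nucleus
   softmax foreground channels by A and renormalizes the foreground mass; the
   background probability passes through unchanged, so uniform attention is
   exactly the identity. Attention values still at the floor mark classes the
   kernel prohibits outright; the constraint zeroes them through a constant
   mask (no gradient through the prohibition), so a one-hot region makes the
   prohibition exact rather than merely small.

The soft mixture (rather than the region argmax) is used at inference as well
as training, so partial-volume pixels at region boundaries constrain nuclei
proportionally.

### Compatibility kernel and priors

The kernel encodes hard biological constraints: epithelial regions prohibit
fibroblast and debris nuclei; stromal compartments (stroma, TILs-dense)
prohibit epithelial nuclei; necrosis/debris allows debris plus mononuclear
immune cells; the *empty* region allows every class, because prohibiting
everything would leave the attention map nothing to normalize and there is no
biological evidence to constrain blank glass. Debris is allowed in all
non-epithelial regions since necrotic material accumulates at margins and in
adjacent fibrosis. The full kernel is a documented default, overridable
through the taxonomy config file.

Priors P are a free logits matrix passed through a kernel-masked row softmax,
initialized uniform over allowed classes and updated by the constrained-loss
gradient.

### Loss

Four components with equal weight (the total is their mean): full-field
region prediction vs the 1.0-MPP mask, the cropped/upsampled region
prediction vs the 0.5-MPP mask over the HPF, unconstrained nucleus softmax,
and constrained nucleus probabilities, each scored as categorical
cross-entropy plus `1 − soft-DICE` averaged over classes present in the
target. Region code 0 means unannotated and is ignored. For nuclei the
background *is* a supervised channel (channel 0); a separate boolean
`nucleus_annotated_mask` marks where nucleus annotations exist (emulating
datasets that annotate nuclei only in a central window), and pixels outside
it are ignored. Components whose target is entirely ignored contribute zero
with a warning.

### Training (desk scale)

Everything runs on a NumPy reverse-mode autodiff engine written for this
package (`histotils.autodiff`): 3x3/1x1 convolution, 2x2 max-pool, nearest
upsampling, concatenation, center crop, (log-)softmax, reductions, and the
channel-mixing contraction behind the attention maps; all gradients are
verified against finite differences in the test suite. `train_toy` performs
one-ROI-per-step Adam with a seeded round-robin visit order, global gradient
clipping at norm 5, and a 10x learning-rate drop after 70% of the steps
(default lr 5e-3, 300 steps; the acceptance run uses 500). The round-robin
order and the clipping were chosen to make the tiny-batch optimization stable
across initialization seeds; all randomness (init, visit order) derives from
one explicit seed, and two runs with the same seed are bit-identical.

### Instance extraction

Foreground is where the constrained argmax is not background; 4-connected
components below `min_size_px` (default 10 px at 0.5 MPP) are dropped. An
instance's class probabilities are the mean constrained foreground
probabilities over its pixels, renormalized; argmax ties break toward the
lower class code for reproducibility. The containing region is the region
argmax at the instance centroid.

## Whole-slide pipeline

Tissue is detected on an ~8 micron/px thumbnail (HSV saturation > 0.05,
value < 0.95, closed with a radius-2 disk; the mask is edge-padded first so
closing cannot erode the image border). Marker ink is removed as saturated
single-hue connected components (hue-histogram peak purity > 0.8 over 12 bins
and mean saturation > 0.6); a warning fires if more than half the mask
vanishes. The slide is tiled on a non-overlapping grid (default 512 µm, i.e.
256 px at the 2-MPP scoring resolution — chosen so one tile equals one
network ROI footprint); each tile's informativeness is the product of mean
hematoxylin and mean eosin concentration over tissue pixels after masked
Macenko deconvolution, so mixed cellular/acellular tiles — peritumoral
stroma — rank highest. Ranking sorts by (score desc, row, col); the top 300
tiles are analyzed at full resolution with the five cross-validation models
assigned cyclically (rank mod 5), or with all five averaged when runtime is
no concern. Fixing the ROI count keeps runtime near-constant per slide.

### Stain deconvolution

Optical density is `−log10((rgb+1)/256)`. The masked Macenko estimator uses
pixels that are non-white (mean RGB < 220) with OD norm > 0.05, projects them
onto the top-2 right-singular plane, and takes the 1st/99th percentile
angular extremes as stain directions; tiles with fewer than 100 masked pixels
or near-parallel estimates (< 10° apart) fall back to the reference H&E
vectors (normalized [0.65, 0.70, 0.29] and [0.07, 0.99, 0.11]). Hematoxylin
is identified as the column with the larger red/blue OD ratio (hematoxylin
absorbs strongly in red; eosin barely). Concentrations are per-pixel least
squares, clipped at zero. Tiles under 5% tissue score zero informativeness.
The absolute scale of the informativeness score depends on OD units; only
the ranking is consumed downstream.

## TIL scores

Per ROI: TILs are lymphocyte + plasma-cell instances; the stromal compartment
is the stroma + TILs-dense region codes (excluding TILs-dense would delete
precisely the signal being scored); membership is by instance centroid;
debris instances are excluded from every cell count. Variants: nTSa =
stromal TILs / stromal area (cells/mm², the calibration scale absorbs
units), nTnS = stromal TILs / stromal cells, nTnA = stromal TILs / all
cells. Zero denominators yield missing values, never zero. Saliency is the
fraction of ROI pixels (all pixels, not tissue pixels) that are stroma within
32 µm of the nearest epithelial pixel, from a Euclidean distance transform.
Slide scores aggregate either globally (pool counts, score once) or as the
saliency-weighted mean of per-ROI scores, skipping missing values and
falling back to the unweighted mean (with a warning) if every weight is
zero. Survival-stratification thresholds (10% for stromal scores, 3% for
nTnA) are exposed as constants; survival analysis itself is out of scope.

Calibration z-scores both score lists, standardizes their difference by its
own sample SD, flags |z| > 1.96 as outliers, fits the no-intercept scale
k = Σ vis·comp / Σ comp² on inliers only, and applies k to *all* slides —
outliers are excluded from fitting, never from downstream use.

## Evaluation conventions

Folds are hospital-stratified: hospitals are shuffled (seeded) and assigned
greedily to the lightest fold, so no site appears in both training and
testing and the fold-size spread is bounded by the largest hospital. Fold 1
is reserved for hyperparameter tuning and excluded from summaries, which
report the mean and *sample* (n−1) standard deviation over folds 2–5 rounded
half-away-from-zero to one decimal — the sample convention is the one that
reproduces the published benchmark table from its printed per-fold values
(the population SD does not, e.g. it gives 0.3 instead of 0.4 for the stroma
row). Nucleus metrics are computed per instance on matched pairs:
predictions match the annotation (box or segment) containing their centroid,
nearest annotation centroid breaking ties, greedily one-to-one; detection
misses are reported as unmatched counts. AUROC is one-vs-rest with midrank
ties; micro averages pool binary indicators across classes; macro averages
skip classes absent from the ground truth.

## Synthetic data: what it does and does not emulate

The generator draws a region layout (half-plane, elliptical tumor blobs with
a TILs-dense pocket, or concentric rings), places non-overlapping elliptical
nuclei by dart-throwing (≤ 50 rejections each, ≥ 2 px clearance so instance
extraction is unambiguous), samples nucleus classes per region in accordance
with the default kernel — stromal nuclei are TILs with probability
`til_fraction` (70/30 lymphocyte/plasma) and fibroblasts otherwise — and
renders RGB by base-10 Beer–Lambert color formation from latent hematoxylin
and eosin concentration maps (base 10 so that deconvolution recovers the
generating concentrations in the same units as the OD definition). Slides
are grids of such tiles with exact counts of pure-background tiles; cohorts
pair true computational scores with `scale·true + noise` visual scores and
inject outliers guaranteed (by deterministic search) to be exactly the rows
the 1.96-SD rule flags. Defaults: 0.5 MPP, 1024-px ROIs, stromal cellularity
3000 nuclei/mm² (tests that need ≥ 500 stromal nuclei per ROI raise it to
8000–10000, dense-infiltrate territory), nucleus radius 5 ± 1 px with
class-dependent scaling (carcinoma nuclei large, lymphocytes small and
hematoxylin-dense).

Not modeled: chromatin/stromal texture, overlapping or irregular nuclei,
staining batch effects, scanner artifacts other than constructed marker ink,
and real morphological variability. Passing tests therefore demonstrate
correctness of the *mechanisms* (geometry, counting, constraint, calibration,
ranking) and trainability of the architecture, not clinical-grade accuracy on
real slides; the published benchmark's accuracy on real data is reproduced
only in the form of its summary-statistic conventions.

## Numerical choices and degenerate inputs

- Attention floor 1e-8; hard-prohibited (floor-level) attention is zeroed in
  the constraint so prohibited probabilities are exactly zero under one-hot
  regions. Pixels whose kernel-masked mixture vanishes fall back to uniform
  over the classes the region argmax allows (or all classes, with a warning).
- DICE of a class absent from prediction and truth is missing, not 1 or 0;
  score variants with zero denominators are missing, not zero.
- Ranking ties break row-major; instance class ties break toward the lower
  code; the 10x image is a 2x box-filter downsample (deterministic,
  alias-free); masks downsample by nearest neighbor so codes survive.
- All file formats are plain text or single-channel PNG with integer codes;
  every artifact the CLI writes can be re-read by the package.

## Known limitations

- The NumPy engine is CPU-only and float64; the full-size profile (depth 5,
  512-px inputs) is defined and tested for shape correctness but is not
  practical to train here — training claims are desk-scale by design.
- The pyramidal-image backend reads whole images through tifffile/PIL rather
  than true multi-level WSI pyramids; the tile-directory backend is the
  first-class test path.
- Calibration assumes an approximately linear visual/computational
  relationship; gross nonlinearity would surface as many outliers and an
  error when no inliers remain.
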