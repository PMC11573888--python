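# Methods

This note documents the models, parameters and design choices behind the
package, and what the synthetic test bed does and does not establish about
behaviour on real slides.

## Slide model and I/O

Slides are image pyramids: level 0 at the scanner's base magnification
(nominal objective power, default 20×), coarser levels at strictly
increasing downsample factors. The reader accepts multi-page tiled TIFF
with a JSON `ImageDescription` carrying `base_magnification`; a missing tag
falls back to 20× with a warning. Tile coordinates are 0-based, half-open
and level-local, matching array slicing. When a requested magnification
falls between pyramid levels, the smallest level still at or above the
target is read and the residual scale (≥ 1) is applied by downscaling the
read region — upsampling is refused. Candidate tiles are enumerated on a
non-overlapping row-major grid (stride = tile size = 512 px); the stride is
configurable because nothing in the protocol fixes whether candidates
overlap, and partial edge tiles are dropped.

## Quality control

QC runs on a 32× thumbnail except where a finer scale is physically
required. Tissue is "saturated and not white": Otsu on the HSV saturation
channel, floored at 0.08 for blank or fully covered slides where the
histogram is unimodal, intersected with value < 0.97 to exclude glass;
small holes are filled and specks removed. Artifact detectors:

- **Pen marks** — hue in green/blue ink windows ((0.25–0.45), (0.5–0.72))
  with saturation ≥ 0.5 and G > R + 20. The channel condition separates
  ink (green-dominant) from hematoxylin nuclei, whose blue-violet hue
  overlaps the blue window but always has R ≥ G. Chroma detection runs on a
  4× rendering because a 1 mm pen stroke averages away at 32×, and is
  reduced to the thumbnail grid by block-any.
- **Blood** — red dominance, R > 1.7 × max(G, B) and R > 80.
- **Blur** — local Laplacian variance below 12.0 in a 16-px window at 4×
  downsample, restricted to tissue. Blur is scale-sensitive: a σ≈6 px blur
  at level 0 is invisible at 32× but still suppresses nuclear edges at 4×.
  The thresholded mask is dilated by a quarter window to undo the erosion
  that windowed variance causes at region boundaries.
- **Bubbles** — bright (value > 0.93), low-texture blobs judged at 4×,
  kept only when enclosed by tissue and away from the slide border.

`usable = tissue AND NOT (any artifact)` by construction, asserted on every
mask. A tile is eligible when the usable fraction of its footprint is at
least 0.5; the per-tile threshold is a package default, as are all QC
thresholds — the upstream protocol delegates them to its QC tooling
without printing values, so every one is configuration here.

## Stain model

Optical density is od = −log10((rgb + 1)/256) per channel; the +1 keeps
black finite (od ≈ 2.408). Stain amounts are linear in OD (Beer–Lambert),
so a pixel's OD vector is the density-weighted sum of unit stain vectors.
The default stain matrix uses the standard published H&E OD vectors
(Ruifrok-style constants) with a residual third column; deconvolution is
the matrix inverse applied per pixel with negative densities clipped. The
inverse is exact on unquantized intensities (tested to 1e-6); through
8-bit rendering, quantization alone contributes up to ~0.015 density error
at the darkest mixtures, which bounds what any round-trip test through
uint8 can assert.

Color normalization is Reinhard-style mean/std matching in CIELAB,
restricted to tissue pixels, with glass left untouched and the output
clipped to the RGB gamut. The method was chosen for determinism (no
iterative fitting). The reference defaults to the first accepted patch of
the first training slide, so runs are reproducible without external
reference assets. In the pipeline, normalization is applied when tiles are
assembled for training and prediction; patch-selection features are
computed on the raw tile. Normalization is idempotent up to uint8 rounding.

## Nuclei and patch selection

Nuclei are segmented on the deconvolved hematoxylin map: Otsu threshold
(floored at 0.3; a map with range < 0.1 is treated as empty), hole
filling, then a distance-transform watershed. Seeds are peaks of the
Gaussian-smoothed (σ = 1.5) distance transform with a minimum separation
of 5 px — the smoothing suppresses the plateau ridges that elongated
nuclei produce, which would otherwise over-split them. Components outside
40–3000 px² are dropped; ellipse axes come from second image moments, and
"dimension ratio" is implemented as per-nucleus major/minor axis ratio
(the protocol's phrase is ambiguous; this is the package's reading, not an
asserted fact about the source).

A patch is accepted iff tissue fraction ≥ 0.5, nucleus count ≥ 20, mean
per-nucleus hematoxylin density in [0.15, 1.2], and mean axis ratio ≤ 4.0,
with inclusive boundaries for deterministic tie-breaks. Extraction visits
candidates in scan order and stops at 300 acceptances; keeping the *first*
300 is a determinism choice (the protocol does not say how the cap is
enforced), with seeded random capping available behind `cap_random`.
Per-sample training selection draws min(200, available) patches without
replacement; samples with fewer than 200 accepted patches are kept with
what they have. Each training patch yields 2 of its 8 dihedral variants,
drawn without replacement with the identity eligible (no exclusion is
stated). Validation and test patches are never augmented, asserted on
every manifest. Per-patch RNG streams are derived from (seed, slide id,
coordinates), so per-slide results do not depend on processing order.

## Cohort and split

Dual-mutant samples are excluded; every RAS sample is kept; the BRAF
subset is |RAS| + 1 samples drawn to match the RAS histology distribution
by largest-remainder quotas, borrowing from neighbouring strata (with a
warning) when a stratum is under-populated — unavoidable when the BRAF
pool's follicular-variant rate is far below the RAS one. The 60/20/20
patient split fixes global role totals first — train = floor(0.6 N), the
remainder split as evenly as possible with validation taking the odd
extra — then allocates per-class seats by largest fractional remainder
under those totals. This transportation-style rounding is what makes a
52 + 51 cohort land on exactly 61/21/21 while keeping the split
class-stratified and a partition; plain per-class rounding gives 61/22/20.
Training-plan arithmetic (patches per role, iterations = floor(n/8) × 200)
is validated against brute-force counting of emitted manifests.

## Classifier

The tile classifier is a convolutional network with inception-style
parallel-branch blocks (1×1, 3×3, 5×5 and pooled-1×1 branches,
concatenated), batch normalization after every convolution, and a two-way
softmax head; input is 512×512×3 scaled to [−1, 1] (input scaling is a
package choice). It is implemented directly on numpy with explicit
backward passes — a deliberate choice that keeps training CPU-only, fully
seeded and dependency-light at the package's test scale. Two architecture
scales share the code path: `small` (default; early 8× average-pool, one
inception block, ~12k parameters) trains end-to-end in minutes on one
core, and `full` stacks three inception blocks at higher resolution for a
schematically inception-v3-like topology. Training uses Adam (lr 0.001,
β = 0.9/0.999), batch size 8, softmax cross-entropy. After each epoch the
batch-norm running statistics are replaced by exact activation moments
over the training set (a "precise BN" pass): with batch size 8 and few
steps per epoch the running averages lag the rapidly moving weights, which
otherwise makes eval-mode predictions diverge from train-mode ones.
Validation log-loss and accuracy are recorded per epoch and the returned
model is the checkpoint at the lowest validation loss, first epoch on
ties; single-class training data is rejected before the first epoch.

Activation maps use occlusion saliency — the method is this package's
choice, as no mechanism is specified upstream: a gray (128) square slides
over the tile with a configurable size and stride (grid of
ceil((512 − occ)/stride) + 1 positions per side, with a final position
flush to the edge), and the heat value is the clamped drop in the
predicted-class probability. The map is min–max normalized unless its
range is below 0.05, in which case only the minimum is subtracted so a
flat map is not amplified into noise.

## Aggregation and evaluation

percRAS = (#tiles with p(RAS) ≥ 0.5)/n_tiles, cutoff inclusive; the tumor
call is RAS iff percRAS > 0.75 and BRAF iff percRAS < 0.25, both strict,
else not predicted. These three constants live in one configuration object
and are read literally from the protocol's wording ("50% or higher",
"exceeded", "below"); the sentence about a tumor-level "probability cutoff
of 0.75" is treated as the same band rule, not an extra tile threshold.
Tumor accuracy is reported twice — over called tumors and over all tumors
— because the headline figure's denominator is a reporting choice;
not-predicted counts are always shown alongside. Fisher's exact test runs
on the called-tumors 2×2. AUC uses the Mann–Whitney rank formulation with
ties counted half, and a seeded bootstrap percentile CI (2000 replicates)
over units. Spearman correlation uses mid-ranks; the p-value is an exact
permutation enumeration for n ≤ 9 on tie-free data and the
t-approximation otherwise. The BRS cross-tab classifies brs < 0 as
BRAF-like and brs > 0 as RAS-like; exact zeros are excluded and counted.
The Spearman-vs-BRS correlation pairs the continuous percRAS score with
the continuous BRS value.

## Synthetic data

The generator renders what the pipeline needs to be falsifiable, not
photorealistic histology. Tissue polygons get eosin density 0.35 and
hematoxylin 0.06 with Gaussian texture noise; nuclei are filled ellipses
at hematoxylin density 0.8, placed by dart-throwing with a minimum
separation of 2.2 major semi-axes (spatial hash), arranged in clusters or
rings around seeded anchors; everything is rendered through the same
Beer–Lambert forward model the stain tools invert. Class presets differ
in nucleus density (60 vs 110 per 512² patch), axis ratio (1.1 vs 1.8)
and arrangement (clusters vs rings), standing in for the morphological
contrast between classical-type and follicular-variant tumors; a
separability knob interpolates both the phenotype contrast and the
probability ((1+s)/2) that a sample's BRS sign agrees with its class.
Artifacts are painted with exact masks: Gaussian-blurred tissue, saturated
green/blue ink strokes, red blood blobs, bright flattened bubbles.
Per-slide stain jitter scales the H/E intensities and perturbs the stain
vectors. All outputs are pure functions of (spec, seed); slides are
writable as multi-page tiled TIFF so synthetic and real data share one
reader path.

What passing tests show: the geometry, bookkeeping and statistics of the
workflow are correct, the QC detectors respond to the artifact physics
they target, segmentation recovers non-overlapping nuclei essentially
exactly, and the training loop can learn a real morphological contrast
from images end-to-end. What they do not show: performance on real H&E
slides — real nuclear texture, touching/overlapping nuclei, scanner
compression, stain variability far from the Reinhard model, and the much
weaker true morphology–genotype association are all outside the
generator's scope, and the reported study-scale accuracies are not
reproducible without the original slide set and training budget.

## Problem sizes in the test suite

The suite favours small, seeded instances: 2048² slides (16 tiles) for
recovery tests, a 9216² slide (324 candidates) for the extraction-cap
check, and a 20-sample cohort of 1536² slides with 8 patches per sample
and 25 epochs for the end-to-end learning check, which runs in a few
minutes on one core. These sizes are the package's own test-design
choices; the library itself has no size assumptions beyond memory.

## Known limitations

- No real-SVS backend: reading is tiled-TIFF only (the same interface
  would host an SVS reader).
- The numpy network is not performance-competitive at study scale; the
  `full` architecture is schematic, not a weight-compatible inception v3.
- QC thresholds are defaults tuned on the synthetic test bed; real slides
  will need per-lab calibration through `QcConfig`.
- Fisher and bootstrap statistics assume independent units; tiles from one
  slide are correlated, so the tile-level AUC CI is optimistic — tumor-level
  statistics are the ones to trust.
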