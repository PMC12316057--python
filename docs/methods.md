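# Methods

## The segmentation model

The pipeline treats tissue classification as unsupervised clustering of
pixels in a hand-crafted feature space. Each Z-slice is processed
independently and the per-slice results are then harmonized through depth.

**Normalization.** Raw integer intensities are loaded without rescaling and
linearly mapped so that the 0.5th percentile of the whole volume becomes 0
and the 99.5th becomes 1 (clipped to [0, 1]). Percentile rather than
min–max normalization resists hot-pixel outliers typical of sCMOS cameras;
computing the percentiles over the volume rather than per slice preserves
genuine depth attenuation. A constant volume raises an explicit
degenerate-input error rather than dividing by zero.

**Gabor filter bank.** Texture is measured with 24 complex Gabor filters:
six wavelengths in a geometric (octave) series starting at 4/√2 ≈ 2.83
px/cycle, truncated at one quarter of the image diagonal (with a recorded
warning when fewer than six fit), crossed with the four canonical
orientations 0°, 45°, 90°, 135°. Orientation denotes the wave-normal
direction in image coordinates (x right, y down). Kernels come from the
standard Gabor construction with a one-octave bandwidth; the mean of each
kernel is removed so the bank is DC-free — a constant image yields zero
magnitude response, and responses are invariant to adding a constant.
Convolution uses FFT acceleration with reflected boundaries. Each magnitude
response is then smoothed with an isotropic Gaussian of σ = 0.5 × that
filter's wavelength: raw Gabor magnitudes oscillate within a texture, and
proportional smoothing converts them into locally averaged texture energy,
which is what makes the downstream clusters spatially coherent. The factor
is configurable; 0 disables smoothing.

**Feature stack.** Per pixel: 1 intensity + 24 smoothed texture magnitudes
+ 2 coordinates = 27 features. Every plane is z-scored independently
(constant planes are set to zero and flagged), making intensity, texture
and space commensurate. After z-scoring the two coordinate planes are
multiplied by a spatial weight, default **0.5**. The weight operationalizes
the preference for spatially contiguous clusters; 0 gives appearance-only
clustering. The default is 0.5 rather than 1.0 because at weight 1.0 the
two coordinate planes are strong enough to pull the K = 4 solution toward
compact spatial blocks on some geometries, overriding appearance; 0.5
retains the coherence benefit (see `analysis/04_spatial_weight_experiment.py`)
without that failure mode.

**K-means.** The clustering engine is the textbook Lloyd procedure written
out in full: choose K (default 4, one per tissue class), place initial
centroids, assign every pixel to its nearest centroid (squared Euclidean),
recompute centroids, and repeat until no reassignment occurs, the relative
objective change falls below 10⁻⁶, or 300 iterations elapse. The objective
is the sum of squared point-to-centroid distances and is asserted to be
non-increasing at every iteration. Production defaults use plus-plus (D²)
seeding and 5 restarts scored by final objective; the literal
"random-points" initialization is preserved as an option. Ties go to the
lowest centroid index. An emptied cluster is re-seeded at the point
farthest from its assigned centroid. All randomness flows from a single
seed through a seed sequence, so results are bit-reproducible. An optional
subsampling mode fits the centroids on a random pixel subset and predicts
all pixels, for slices much larger than the defaults; it is off by default.

**Depth harmonization.** Cluster indices are arbitrary per slice. Slice 0
is the reference; each subsequent slice's clusters are matched one-to-one
to the previous slice's by minimizing total centroid distance over the
appearance features only (coordinate planes excluded, since they are
identical in every slice) with the Hungarian algorithm, then relabeled. A
class therefore keeps one index through the volume.

**Validation.** Predicted clusters are matched to ground-truth classes by
the one-to-one assignment maximizing the summed per-pair Dice (optimal
bipartite assignment on the K×K Dice matrix; a greedy variant exists for
comparison only). Dice is 2|A∩B|/(|A|+|B|); when both masks are empty the
value is defined as 1 — a correctly absent class should not be punished —
and each such case is flagged in the report. Aggregation over an image set
reports the mean and the sample SD (n−1 denominator); with a single image
the SD is reported as 0 and flagged.

## The synthetic phantom

Real cleared-muscle light-sheet volumes run to terabytes, so the test bed
is a generative phantom with known per-pixel labels. It emulates a field of
view containing an implanted ECM scaffold in a muscle bed:

- **scaffold** (code 1): a central region bounded by a low-order wobbled
  circle, filled with smooth blobby texture (Gaussian-filtered noise,
  correlation length 45 px, contrast 0.4 about a 0.5 mean);
- **muscle** (code 0): the surrounding field, striated with an oriented
  periodic fiber texture (period 12 px, fiber axis 0.35 rad, contrast
  0.35). The sinusoid is sharpened toward a square wave (tanh squashing,
  "squareness" 8) so the striations carry the odd harmonics real
  sarcomere-scale edges have;
- **interstitium** (code 2): dark gaps (intensity 0.05 × base, i.e. 90%
  contrast) with fine collagen-like speckle (amplitude 0.3), placed as a
  10-px band at the muscle–scaffold border and as seams between muscle
  fiber bundles every 80 px;
- **vessels** (code 3): bright saturated tubes (2× the 0.5 base level,
  clipped at 1.0) built by dilating persistent random-walk centerlines
  (radius 6 px); walks start outside the scaffold and reflect at the image
  borders. Vessels overwrite underlying labels, since a pixel carries one
  ground-truth class.

Each class was deliberately given its own spectral band — scaffold blobs at
the coarse wavelengths, muscle striations at the mid wavelengths (with
harmonics reaching the fine ones), interstitial speckle at the fine
wavelengths, vessels at the intensity extreme — so that most of the 24
texture planes carry class information. This is the regime Gabor K-means
segmentation is designed for; phantoms whose classes differ in only a few
planes leave the remaining z-scored planes as pure within-class variance,
and the minimum-SSE partition then need not coincide with the tissue
classes at all.

Depth is handled by multiplying each slice's contrast about the 0.5 mid
level by `depth_attenuation^z` (default 0.98 per 1-µm plane, a mild
realistic decay); the label geometry itself is depth-stationary. Noise is
applied last: Poisson photon statistics scaled by a gain of 200 expected
photons at unit intensity (SNR ≈ 10 at mid-intensity, the mild sCMOS
regime) followed by additive Gaussian read noise of SD 0.01. Metadata
defaults mirror the instrument class this emulates: 0.254 µm pixels, 1 µm
inter-plane distance.

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: optical point-spread blurring and light-sheet
geometry, tile stitching and deconvolution artifacts, real autofluorescence
spectra (a single synthetic channel stands in), anisotropic or
depth-varying geometry, and the shape statistics of real vasculature.
Results on the phantom bound what the feature set can do when its
assumptions hold; they do not certify performance on microscope data.

## Reference results and their stability

The quantitative reference is a frozen phantom — 5 slices of 256×256 px,
geometry seed 1, all defaults — on which the full pipeline attains
per-class mean Dice of about 0.75 (muscle), 0.91 (scaffold), 0.70
(interstitium) and 0.67 (vessel), stable to ±0.01 across clustering seeds
because the restarted plus-plus K-means converges to the same optimum.

A known limitation: across *geometry* realizations (different phantom
seeds) the outcome varies substantially. The tissue partition and
competing partitions (e.g. splitting muscle along vessel-halo gradients)
can differ in K-means objective by under 1%, and which one is the global
optimum flips with the realized geometry; on unlucky realizations the thin
classes drop well below the reference values. This is a property of the
method itself — K = 4 sum-of-squares clustering has no notion of the
desired classes — and is the reason results are reported on a fixed
reference dataset, as one would report on a fixed benchmark image.

## Problem sizes and numerical choices

Tests and the acceptance script use 48–128 px phantoms for structural
checks and the 256×256×5 reference phantom for end-to-end recovery; the
K-means engine is verified against exhaustive partition enumeration on
instances of up to 10 points, where enumeration is exact. Convolution
boundary handling is reflection everywhere. Percentile defaults 0.5/99.5;
K-means tolerance 10⁻⁶ relative; empty∩empty Dice = 1 (flagged);
cluster-class matching optimal, not greedy. Intensity TIFFs are written as
16-bit (configurable), labels as 8-bit with a plain-text sidecar carrying
the class-name table and, for phantoms, the full generating configuration
including the seed.
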