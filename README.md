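# afseg — label-free tissue classification of autofluorescence Z-stacks

Cleared-tissue light-sheet microscopy of unstained samples produces a single
autofluorescence channel in which different tissues are distinguished only by
their brightness and texture. `afseg` classifies every pixel of such a
Z-stack into four tissue classes — **muscle**, **ECM scaffold**,
**interstitium** and **blood vessel** — without labels or training data,
using unsupervised K-means clustering on a per-pixel feature set, and
validates the segmentation against ground truth with per-class Dice
coefficients. It is aimed at groups studying biomaterial–tissue interfaces
(e.g. decellularized ECM scaffolds implanted in volumetric muscle injuries)
who want a reproducible, fully scriptable alternative to manual annotation.

## Method

For each slice *I(x, y)* of the stack the per-pixel feature vector is

- **intensity**: the normalized autofluorescence value;
- **texture**: magnitude responses of a bank of 24 complex Gabor filters —
  six wavelengths in octave steps, λ ∈ {4/√2·2ᵏ, k = 0…5} px, capped at a
  quarter of the image diagonal, × four orientations θ ∈ {0°, 45°, 90°,
  135°} — each response smoothed with an isotropic Gaussian of σ = 0.5 λ;
- **space**: the pixel coordinates (x, y), so the clustering prefers
  spatially contiguous groupings.

Every feature plane is z-scored; coordinates are multiplied by a spatial
weight (default 0.5). The pixels are clustered by K-means (K = 4) minimizing
the within-cluster sum of squared distances Σᵢ‖pᵢ − c(aᵢ)‖², using
plus-plus seeding, 5 restarts and Lloyd iterations until assignments are
stable. Per-slice cluster indices are harmonized through depth by optimal
matching of appearance centroids, yielding a 3-D classified volume.
Accuracy against a ground-truth label map is scored per class with the Dice
coefficient, dice(A, B) = 2 |A ∩ B| / (|A| + |B|), after a one-to-one
cluster-to-class assignment that maximizes total Dice.

Because raw cleared-tissue data sets run to terabytes, the package ships a
**synthetic phantom generator** that emulates the four tissue classes with
known per-pixel ground truth (oriented striated fibers, smooth scaffold
blobs, dark interstitial gaps, bright curvilinear vessels, depth-dependent
contrast decay and sCMOS-style noise). Every pipeline stage is tested
against it; see `docs/methods.md` for what the phantom does and does not
emulate.

## Worked example

```python
import afseg

cfg = afseg.PipelineConfig(
    phantom=afseg.PhantomConfig(width=256, height=256, n_slices=5, seed=1),
    out_dir="run", seed=1,
)
run_dir = afseg.run_pipeline(cfg)
```

or, from a shell, `afseg all --out run --seed 1`. The run directory
contains the normalized stack, the harmonized label volume (`labels.tif`),
per-slice K-means summaries, and the Dice report. For the 5-slice reference
phantom this prints:

```
per-class Dice over the 5-slice stack (mean ± SD):
  muscle        0.755 ± 0.014
  scaffold      0.909 ± 0.009
  interstitium  0.702 ± 0.019
  vessel        0.670 ± 0.025
```

i.e. the two large textured tissues are recovered at Dice ≈ 0.75–0.91 and
the thin intensity-defined structures at ≈ 0.67–0.70 — entirely without
supervision. The numbered scripts under `analysis/` walk through the same
pipeline step by step (phantom composition, per-feature class profiles,
segmentation + validation, and the effect of the spatial weight) and write
their tables under `results/`.

To segment your own data: `afseg segment --stack stack.tif --out run`
accepts a multi-page grayscale TIFF (or a directory of per-slice TIFFs);
`afseg evaluate --pred run/labels.tif --truth truth.tif --out eval` scores
it against a ground-truth label TIFF.

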