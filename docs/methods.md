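# Methods

## The model

`gridsaccade` implements a saccadic visual-recognition-memory model in which
spatial relations between stimulus features are carried by a grid-cell
population code, and recognition is an active loop of hypothesis, eye
movement and evidence accumulation.

**Training (one-shot Hebbian storage).** Each identity is learned from a
single 440×440 image. Nine salient locations — one per block of an even 3×3
partition, each the peak of smoothed gradient-energy saliency inset so the
fovea fits inside the image — are fixated; at each, a square foveal patch
(default 101×101 px) becomes the template of a *feature-label cell*, and the
grid-cell population activity at that location becomes the cell's grid
weights (a single outer-product association with one stored pattern, so the
weights equal the encoding activity exactly). The nine feature-label cells
link bidirectionally to one *identity cell*.

**Grid code.** Grid cells are idealized rate maps over the image plane: a
sum of three plane-wave cosines at 60° separations, rectified and
peak-normalised to 1, precomputed as 440×440 lookup tables. The default
population has 5 modules with periods in geometric progression (28 px, ratio
≈ 1.42) and 25 random-phase cells per module, 125 cells total — enough
distinct scales that the population activity identifies a map position
uniquely. Encoding a fixation is a per-cell lookup. The displacement between
two encoded locations — the functional role of distance/displace cells — is
decoded by scoring every map position against each activity vector (one
matrix–vector product against the flattened rate-map bank per decode,
minimising summed per-cell squared error) and subtracting the two
maximum-likelihood positions. This makes decode antisymmetry exact and the
round-trip error zero up to integer-pixel effects; attractor dynamics, path
integration and spiking are deliberately out of scope.

**Recognition.** Three loop variants share one skeleton:

- **HG** — the first identity hypothesis comes from a global histogram of
  oriented gradients (HOG): the probe's descriptor is correlated (`corr2`,
  mean-centred normalised cross-correlation) with each gallery descriptor
  and the argmax wins. The loop then saccades, via grid decoding, through
  the hypothesized identity's stored feature locations, correlates each
  foveal patch with the expected template, and adds rectified evidence
  `max(0, corr2)/9` to the identity cell until it reaches the 0.9 decision
  threshold.
- **G** — the original bottom-up variant: the first fixation is a salient
  location, and the best template match there (softmax over similarities
  with a sparsifying threshold, summed per identity) supplies the
  hypothesis. This first fixation forms the hypothesis only and contributes
  no accumulator evidence, so the subsequent evidence path — nine
  grid-guided stored-location matches against the same threshold — is
  identical to HG's; the variants differ only in how reliable the first
  hypothesis is.
- **HG-lesion** — HOG hypothesis retained, but the grid code is
  disconnected from the feature-label cells: saccade targets cannot be
  computed, so every step re-fixates a random salient location and matches
  it against the hypothesis's best unvisited template.

If a hypothesis exhausts its nine features below threshold, it is *reset*:
the identity with the largest cumulative feature-label drive over all
fixations so far (excluding rejected identities, ties to the lowest label)
becomes the new hypothesis with a fresh accumulator; after `max_resets`
(default 3) failed hypotheses the episode ends "unrecognized".

**Occluded features.** A memory-guided fixation whose match falls below a
silent floor (0.45) leaves the feature-label cell silent; the feature is
treated as *unobserved* rather than as counter-evidence, and the decision
threshold is prorated to the features that responded (never deciding on
fewer than 3). This models occlusion: the eye went where the feature should
be and saw nothing. Mediocre matches above the floor still count fully, so
clean-probe behaviour is unchanged. The proration applies only when
fixations are grid-guided — the lesion variant cannot know whether it
looked in the right place, so all its visits count as observed.

**Scale invariance (known gain).** For a probe uniformly downscaled by
ratio *g* and placed centred on the canvas, decoded displacements are
multiplied by *g*, foveal patches are extracted at side `round(f·g)`
(odd-ified) and resampled to the template size before correlation, and the
HOG hypothesis is computed on the probe rescaled back to canonical size.
Estimating an unknown gain is out of scope.

## Descriptors

**HOG** (first-hypothesis front end): gamma contrast normalisation
(`I^gamma`, default gamma 0.5), central-difference gradients with
`[-1, 0, 1]` kernels (no ½ factor; replicate-edge padding so the field
covers every pixel), unsigned orientation folded into [0°, 180°), 9 bins of
20° with hard magnitude-weighted assignment (no bilinear interpolation; an
unweighted-count flag exists), 8×8-px cells, 2×2-cell blocks at stride 1,
plain L2 block normalisation with ε = 1e−5. For a 440×440 image the
descriptor has 54·54·4·9 = 104 976 entries. Cell/block geometry and gamma
follow the classic pedestrian-detection conventions.

**Uniform LBP** (descriptor only, for baseline comparisons): p = 8
neighbours at r = 1 on the 8-connected integer ring (east-first,
counter-clockwise; ties neighbour ≥ centre score 1; no sub-pixel
interpolation at this radius), 5×5 block grid, 59 bins per block (58
uniform codes in ascending order + catch-all), border pixels within r
skipped. The classifier that consumed these features in the comparison
study (a deep belief network) is not reimplemented.

## Synthetic stimuli

The generator emulates the structure of one-training-image-per-identity
face galleries: N identities × (1 training + k probe variants), 440×440.
Each identity is a smooth base texture plus nine oriented (optionally
Gabor-modulated) blobs at face-like landmark positions (four eye corners,
nose tip and wings, two mouth corners). Two properties mimic real face
statistics deliberately:

- identities share most of their global structure: a dataset-wide shared
  texture carries 95% of the base-texture amplitude, and blob shapes are
  population-canonical with moderate per-identity perturbations; identity
  information lives in landmark offsets (±22 px), the residual texture and
  blob-shape deltas. This is what makes a single foveal patch an unreliable
  identity cue (as for real faces) while global descriptors stay reliable.
- probe variants perturb geometry and photometry: landmark jitter
  ("expression"), a smooth warp field, affine illumination change, pixel
  noise, and optional occlusion (texture rectangle covering 1/2, 1/3 or 1/4
  of the area) or uniform downscaling (ratios 1/2, 1/4, 1/5 on a mid-gray
  canvas).

Difficulty presets (easy / medium / hard) set the perturbation magnitudes.
The medium preset (jitter SD 1.5 px, warp 1 px, illumination gain ±12% bias
±0.05, noise SD 0.015) is calibrated so HG accuracy on the default
10-identity set falls strictly between 50% and 100%, leaving visible
headroom in both directions; easy is near-ceiling and hard well below. The
null variant is bit-identical to the training image.

What the generator does **not** emulate: photoreal facial appearance,
semantic occluders (sunglasses/scarves), pose/viewpoint change, and
background clutter. Passing tests therefore demonstrate the mechanics of
the model under controlled geometry/photometry/occlusion/scale, not
performance on real photographs.

## Numerical choices and degenerate inputs

- `corr2` of one or two constant arrays returns 0 with a warning ("no
  evidence"), never NaN.
- Ties in the HOG hypothesis and in reset identity choice break toward the
  lexicographically lowest identity; position-decode ties break toward the
  smallest row-major index. All randomness flows from explicit integer
  seeds; identical inputs and seeds give byte-identical outputs.
- Bin edges are half-open `[k·20°, (k+1)·20°)`; θ = 180° folds to 0°.
- Fovea sides must be odd; near-border fixations are clamped inward and the
  clamped centre recorded.
- Luminance conversion uses ITU-R 601 weights; resampling is bilinear
  (anti-aliased when shrinking); downscaled-canvas background defaults to
  mid-gray 0.5 (configurable).
- The grid population is serialised as a JSON manifest (module specs and
  seed); rate maps are regenerated exactly on load rather than stored as
  ~100 MB of binary.

## Problem sizes

Default experiment sizes keep a full study reproducible on a laptop-class
single core: 10 identities, 5 probe variants per identity per seed, 5 seeds
for the variant/fovea comparison and 2 seeds for the robustness curves.
These are the sizes used by `scripts/acceptance.py` and the test suite; all
counts scale through the public API.

## Known limitations

- Lesion accuracy is near zero under the default evidence rule: without
  grid-guided fixations almost no probe can assemble nine strong matches.
  The variant's qualitative signature — many more fixations, first accuracy
  preserved by HOG — matches expectations, but its absolute accuracy should
  not be compared with studies using different accumulation rules.
- The G variant's bottom-up attention is modeled as the deterministic
  saliency peak per block; real bottom-up saliency is noisier.
- The decision rule is sharp (mean rectified correlation over nine features
  ≥ 0.9), which makes accuracy sensitive to the perturbation magnitudes;
  the calibrated presets place the operating point mid-range.
- Scale handling assumes the gain is supplied; no scale estimation is
  attempted.
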