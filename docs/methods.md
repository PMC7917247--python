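# Methods

This note records the scientific model behind `aphidhsi`, the defaults and
problem sizes the package ships with, and the places where a genuinely open
design choice had to be made.

## The measurement model

A leaf scene is a reflectance field R(v, i, j) ∈ [0, 1.2] over 128 bands
(376–1044 nm, uniform grid) and H×W pixels. The sensor records counts

    I_r = R · 2 · I_g + ε,   ε ~ N(0, noise_sd²),  clipped at 0,

where I_g is the radiance of a 50 %-reflectance gray panel (a smooth
halogen-like spectrum with mild radial vignetting in the simulator).
Calibration inverts this: I_c = I_r / (2 I_g). No dark-current frame enters
the model; the calibration is the two-term gray-panel form only. With zero
noise the render/calibrate round trip is exact, which the tests assert to
machine precision; with noise, the reflectance error has standard deviation
noise_sd / (2 I_g), asserted within 10 % by Monte Carlo.

## The synthetic study

The generator emulates a five-session, two-class leaf study:

* **Geometry** — one elliptical, star-perturbed leaf blob per scene
  (connected by construction), a 2-px erosion edge band, a midrib with 3–5
  lateral veins, and, for infected leaves, 1–5 disk-shaped honeydew
  secretion patches inside the leaf interior (area fraction well below 0.4
  of the leaf; asserted empirically over 50 seeded draws).
* **Spectra** — healthy lamina is a standard vegetation curve (visible
  baseline 0.06, green bump at 550 nm, red trough at 675 nm, logistic red
  edge at ~712 nm, NIR plateau ≈ 0.5). The infected lamina subtracts a
  raised-cosine window supported *exactly* on the discriminative range
  (default 750–950 nm) with peak `effect_size = 0.10`; outside that window
  the two classes' lamina spectra are bit-identical. Secretion is spectrally
  flat at 0.85, veins/edges are scaled lamina. A smooth multiplicative
  texture field (sd 0.05 healthy, ×1.6 infected, emulating the texture
  change infestation causes) and the sensor noise (sd 8 counts against a
  ~2000-count panel) provide within-class variability.
* **Bookkeeping** — per-session counts are uneven (healthy 27/26/25/24/23,
  infected 27/27/27/25/25; sessions otherwise differ only by seed), totalling
  125 + 131 = 256 leaves.

What the generator deliberately does **not** model: radiative-transfer leaf
optics (no PROSPECT-style physics), aphids as objects, temporal infection
dynamics across sessions, multi-leaf scenes, or illumination drift between
sessions. Tests that pass on these data therefore demonstrate that the
pipeline recovers *planted* structure correctly — they do not certify
field performance on real leaves, where class differences are weaker and
confounded.

### Split quotas

The reference bookkeeping pools to healthy 75/26/24 and infected 78/25/28.
No per-cell largest-remainder rounding of a 3:1:1 ratio with a single
symmetric validation/test tie rule can produce both (the healthy pool needs
validation > test, the infected pool the opposite; 125 = 5×25 would even
give 75/25/25 exactly). The default dataset therefore pins explicit
per-(session, class) quotas in `GeneratorConfig.split_quotas`, chosen so
that each cell still honours 3:1:1 up to one sample and the pooled counts
match the reference exactly. `stratified_split` uses quotas when present
and falls back to largest-remainder rounding (training share favoured on
ties, then validation) otherwise; the seed only shuffles which samples land
where, never the counts.

## Preprocessing

* **3-D Savitzky–Golay** — the 5×5×5, order-3 smoother is the exact
  least-squares fit of a trivariate polynomial of total degree ≤ 3 (20 basis
  monomials over 125 voxels), evaluated at the centre; being linear it is
  precomputed once as a stencil whose weights sum to 1 and are symmetric
  under axis reflection. Boundaries use reflect padding (keeps the cube size
  and avoids edge ramps). Oracle: an explicit normal-equations fit at random
  voxels, matched to 1e-8 relative error.
* **First derivative** — finite differences against wavelength via
  `np.gradient` (central interior, second-order one-sided ends), not a
  Savitzky–Golay derivative; this is the simplest defensible reading and is
  exact for linear spectra. Units: reflectance per nm.
* **RGB synthesis** — nearest bands to 698/548/461 nm mapped to R/G/B
  (natural colour order), each channel min–max scaled over the leaf pixels.
  Synthesis runs on the *untrimmed* grid: the nearest band to 461 nm
  (460.2 nm) lies just outside the 461–988 nm trim, and the half-band-spacing
  tolerance would correctly refuse the trimmed cube.
* **Resizing** — bilinear, no anti-aliasing, spectral axis untouched.
* **Set standardization** — per-feature zero-mean/unit-sd transforms with
  training-set statistics only, applied identically to validation and test;
  zero-variance features are floored at sd 1e-8 with a logged warning. This
  reading of "normalizing all sample sets before training" is input
  standardization; the networks additionally contain batch-norm layers.

## Classifiers

The networks run on a small reverse-mode engine (`aphidhsi.nn`): im2col
convolutions (one strided-window copy + one BLAS matmul per layer; large
column matrices are rebuilt in the backward pass to bound memory), windowed
max pooling, batch normalization with running statistics, float32
parameters/activations with a float64 path for float64 inputs (used by the
saliency finite-difference checks). Training is plain SGD, batch 10,
learning rate stepped from 0.1 to 0.01 at half the epoch budget ("gradually
adjusted" is under-specified; the endpoints are fixed, the midpoint step is
recorded in `TrainConfig`), softmax cross-entropy (the universal pairing
with a softmax head), Xavier-uniform initialization, and selection of the
minimum-validation-loss checkpoint. Everything is deterministic for a fixed
seed on a given BLAS.

Architectural decisions in the 3-D network where the layer plan left room:

* Residual block 2 widens 3 → 5 channels *without* a projection; the
  shortcut zero-pads the two extra channels (the classic parameter-free
  "option A"). Block 1 keeps its stated 1×1×1 projection even though its
  input is already 3 channels and stride is 1 — redundant but harmless, and
  retained as specified.
* Max pooling "size 3" is kernel 3, stride 2, padding 1 in all axes (the
  ResNet convention; a stride-1 reading would barely downsample).
* Convolutions inside the residual blocks are 3×3×3 with same padding;
  conv1/conv2 use same padding so the architecture accepts any input with
  ≥ 9 bands and ≥ 3 pixels per axis.

Conventional baselines are scikit-learn estimators (logistic regression
with the default L2 penalty and an effectively unlimited quasi-Newton fit;
SVC with polynomial/sigmoid/RBF kernels; K-nearest neighbours; decision
trees). Hyperparameters are tuned by an in-package Bayesian optimizer:
a Matérn-5/2 Gaussian-process surrogate (scikit-learn) with expected
improvement over log₁₀-scaled C and γ in [1e-5, 1e5] (a uniform prior over
ten decades would waste the search), integer K and depth in [1, 30], and the
SVM kernel as a one-hot categorical optimized jointly with C/γ. One trial in
ten is uniformly random, which keeps the sampled decades spread (asserted:
≥ 8 of 10 decades covered over 200 trials). The trial budget is 200 at the
paper preset, 40 at the desk preset; the full trial log is retained.

## Saliency

S_c is the **pre-softmax** class score: post-softmax gradients saturate once
the network is confident, while the unnormalized score keeps the attribution
informative. Misclassified samples get weights but are flagged invalid and
excluded from every aggregation (exclusion counts are visible in the
profile's sample list). For RGB inputs "band" means channel. Aggregations
(per-sample normalization, cumulative contribution, per-band L1) are all
probability vectors by construction and asserted as such.

The finite-difference validation of the gradients deserves a note: a ReLU
network is piecewise linear, so central differences equal the
backpropagated gradient *exactly* — unless the probe interval straddles a
kink. The tests therefore probe at step 1e-5 in the float64 path and
discard coordinates where the forward and backward one-sided differences
disagree (a kink detector), requiring the remaining majority of probes to
agree within 1 %. At differentiable points the observed agreement is ~1e-9.

Band-subset re-modelling maps closed nm intervals to band indices with the
same centre-inclusion semantics as trimming, restricts every sample,
re-standardizes with the restricted training statistics and retrains the
CNN from scratch.

## Problem sizes

Two presets are recorded in `aphidhsi.pipeline`:

| | desk | paper |
|---|---|---|
| generator frames | 48×64 px | 520×696 px |
| RGB resize | 32 | 160 |
| cube resize | 24 | 160 |
| epochs (1-D / 2-D / 3-D) | 25 / 20 / 12 | 200 / 200 / 200 |
| Bayesian-optimization trials | 40 | 200 |

The desk preset is the package's working scale for CPU experimentation and
for the test suite; the paper preset preserves the full-scale settings. The
generator's library default frame is 96×128 px. Epoch budgets at desk scale
lean on best-validation-checkpoint selection rather than long schedules.

## Known limitations

* Synthetic class separation at desk scale is stronger than in real field
  data; several study cells saturate at 100 % test accuracy, so the grid
  exercises the machinery rather than discriminating among methods.
* The 2-D view's class signal is carried almost entirely by the secretion
  patches; real RGB discrimination also involves subtle colour shifts the
  generator only gestures at via the texture field.
* The engine is CPU-only and single-device; the paper preset exists for
  completeness and is not a practical CPU target for the 2-D/3-D networks.
* Bayesian-optimization determinism holds for a fixed BLAS; across BLAS
  builds, tie-breaking in GP fits could select different but equivalent
  trials.
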