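# aphidhsi

Detection of cotton-aphid (*Aphis gossypii*) infection in single cotton
leaves from Vis/NIR hyperspectral images, as a fully synthetic, testable
pipeline: scene simulation, reflectance calibration and 3-D smoothing,
1-D/2-D/3-D convolutional classifiers alongside Bayesian-optimized classical
baselines, and gradient-saliency attribution of the wavelengths and image
regions that drive the decision.

## Who this is for

Researchers in hyperspectral plant-stress detection who want a reference
implementation of the multi-view analysis pattern — mean-spectrum (1-D),
synthesized RGB (2-D) and full-cube (3-D) classification of the same leaves
— with every stage unit-tested against analytic oracles, and a synthetic
data generator with planted ground truth so that attribution methods can be
validated, not just admired.

## The model

**Acquisition and calibration.** A push-broom camera yields radiance cubes
of 128 bands × H × W pixels spanning 376–1044 nm (≈5 nm resolution). With a
50 %-reflectance gray panel imaged under the same illumination, reflectance
is

> *I*<sub>c</sub> = *I*<sub>r</sub> / (2 *I*<sub>g</sub>)

so a pixel whose counts equal the panel's maps to reflectance 0.5. Cubes are
denoised with a 5×5×5 Savitzky–Golay filter (trivariate polynomial of total
degree ≤ 3, evaluated at the kernel centre) and trimmed to the 100 bands in
461–988 nm.

**Three views, five classifiers.** Per leaf the pipeline derives (i) the
first derivative of the ROI-mean reflectance spectrum, (ii) an RGB frame
from the bands nearest 698/548/461 nm, and (iii) the trimmed cube. Each view
is classified by a CNN — ResNet-18 re-ranked to 1-D for spectra, standard
ResNet-18 for RGB, and a compact 3-D residual network
(conv 9×3×3/5 ch → conv 3×1×1/3 ch → residual blocks of 3 and 5 channels →
global average pooling) for cubes — and by logistic regression, SVM,
K-nearest neighbours and decision trees tuned by Gaussian-process Bayesian
optimization. For image and cube views the classical methods consume the
CNN's global-pooling features. Networks train with SGD (batch 10, learning
rate stepped 0.1 → 0.01, Xavier init) and keep the lowest-validation-loss
checkpoint.

**Saliency.** For a sample *D*₀ of true class *c* with pre-softmax score
*S*<sub>c</sub>, the weight *w* = |∂*S*<sub>c</sub>/∂*D*| at *D*₀ is computed
by backpropagation (valid only when the prediction is correct). Spatial maps
take *M*(i,j) = max<sub>v</sub> *w*(i,j,v); the cumulative band contribution
over a test set is *C* = Σ<sub>j</sub> *M*<sub>j</sub> / ‖Σ<sub>j</sub>
*M*<sub>j</sub>‖₁. A band-subset re-modelling step retrains the CNN on a
wavelength interval alone to confirm that high-contribution ranges carry the
class signal.

**Synthetic ground truth.** The generator draws leaf blobs with veins and
edge bands, gives the infected class a NIR-plateau depression confined to
750–950 nm plus small bright honeydew-secretion patches, renders radiance
through the gray-panel model with sensor noise, and emits 125 healthy + 131
infected leaves over 5 sessions so that the built-in 3:1:1 session-stratified
split reproduces the reference bookkeeping (75/78, 26/25, 24/28). Because
the discriminative bands are planted, saliency recovery is checkable.

## Worked example

```python
from aphidhsi import GeneratorConfig, generate_dataset
from aphidhsi.pipeline import DESK, extract_views, run_full_study

cfg = GeneratorConfig(height=48, width=64, seed=0)   # desk-scale frames
views = extract_views(generate_dataset(cfg), DESK, split_seed=0)
record = run_full_study(views, DESK, seed=1)
print(record.results[["view", "method", "test_accuracy"]])
```

prints the 15-cell study grid (test accuracies in percent):

```
       view method  test_accuracy
0   spectra    CNN         100.00
1   spectra     LR         100.00
2   spectra    SVM         100.00
3   spectra     NN         100.00
4   spectra     DT         100.00
5       rgb    CNN         100.00
...
10      hsi    CNN          90.38
11      hsi     LR          94.23
...
```

The spectra view is the easiest (the planted NIR signal survives averaging
and differentiation almost noise-free), the cube view the hardest at desk
scale. Attribution recovers the construction: the 1-D CNN's cumulative
contribution places ~63 % of its mass inside the planted 750–950 nm window,
and retraining on 750–950 nm alone keeps test accuracy at 100 % while the
460–600 nm control range reaches only ~67 %:

```python
from aphidhsi.saliency import band_subset_remodel
band_subset_remodel(views, (750, 950), "spectra", seed=1)   # -> 100.0
band_subset_remodel(views, (460, 600), "spectra", seed=1)   # -> 69.23
```

The same pipeline is scriptable from the shell:

```bash
aphidhsi simulate --out data/ --seed 0          # ENVI cubes + masks + manifest
aphidhsi run-all  --out results/ --seed 1       # the full study grid
aphidhsi remodel  --range 750:950 --view spectra --seed 1
```

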