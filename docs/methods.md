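# Methods

This note defines the statistical and numerical machinery implemented in
`pgan`: the generative model, the phantom data it is demonstrated on, the
three certification axes, and the main numerical choices with their
rationale.

## 1. The generative model

### ac-GAN

The generator `G` maps a latent `z ∈ R^100` drawn from a standard normal,
concatenated with a length-3 region condition `c` (reshaped to a
`(103, 1, 1)` input), through a stack of transposed convolutions to a
multi-slice grayscale image stack in `[-1, 1]` (tanh output). The reference
architecture produces a 9-slice 64×64 stack:

| layer | out channels | kernel | stride | pad | output |
| ----- | ------------ | ------ | ------ | --- | ------ |
| deconv 1 | 512 | 4 | 1 | 0 | 4×4 |
| deconv 2 | 256 | 4 | 2 | 1 | 8×8 |
| deconv 3 | 128 | 4 | 2 | 1 | 16×16 |
| deconv 4 | 64  | 4 | 2 | 1 | 32×32 |
| deconv 5 | 9   | 4 | 2 | 1 | 64×64 |

Hidden deconv layers use batch normalization + ReLU. The discriminator `D`
mirrors this with strided convolutions (64/128/256/512 channels, leaky-ReLU
slope 0.2, final 4×4 stride-1 layer to a 64-feature 1×1 map) and two heads
on the shared trunk: a sigmoid real/fake head and a softmax 3-class region
head. `D` never receives `c`; the class is predicted, not given.

The training objective, from the discriminator's point of view, is

```
L  = L_D + α·L_C,          α = 1
L_D = E[log P(real | X_real)] + E[log P(fake | X_fake)]
L_C = E[log P(ĉ = c | X)]
```

ascended for `D`; the generator follows the non-saturating heuristic
(maximize `log P(real | X_fake) + α·log P(ĉ = c | X_fake)`). Both networks
use Adam with learning rate 1e-4 and betas (0.5, 0.999). Fake-batch labels
are drawn from the empirical training label distribution.

**Desk scale.** `GeneratorSpec.desk(size, n_slices, base_channels)` and
`DiscriminatorSpec.desk(...)` produce truncated stacks of the same form for
any power-of-two size ≥ 8, so the full workflow runs on one CPU. The
reference 64×64 stacks remain the constructors' defaults.

**Batch-norm placement in `D`.** Batch normalization is applied only to
interior trunk layers — not to the pixel input and not to the final trunk
layer. Real and fake images are forwarded as separate batches; per-batch
normalization of the final features would remove exactly the batch-level
statistic that distinguishes real from fake, and empirically freezes
adversarial learning at D(real) ≈ D(fake) ≈ 0.5.

### Conditioning and morphing

Class `k ∈ {1, 2, 3}` (cervical, thoracic, lumbar) is encoded one-hot. A
morph from `k` to `k'` in `n` steps uses condition

```
c_i = ((n - i)/n) · e_k + (i/n) · e_k',   i = 0 … n
```

so weights stay on the 2-simplex with at most two non-zero components, and
the two-step midpoint is a 50 %/50 % mixture. `ACGANResults.morph` freezes
one latent `z` and sweeps the schedule; its endpoints are bit-consistent
with the one-hot generations for the same `z`.

### Synthetic release

`build_synthetic_dataset` draws labels i.i.d. from a stated categorical
distribution — default `(0.25, 0.55, 0.20)` — then generates one image per
label with a fresh latent. The release records its provenance (checkpoint
id, seed, label distribution, n) and carries no patient identifiers. The
default release size is 1.25× the training split.

## 2. Phantom data

Real vertebral-unit MRI cannot ship with the code, so the package
generates a parametric stand-in that preserves the statistical structure
the workflow depends on:

* **class-dependent geometry** — each sample is a 9-slice stack of a soft
  superellipse "body" whose aspect ratio, corner exponent, and texture
  frequency depend on the region label (cervical: small and round;
  thoracic: intermediate; lumbar: large, square, high-frequency texture);
  slices narrow elliptically away from the central slice;
* **patient random effects** — per-patient intensity offset and log-size
  factor (SD 0.15 by default), shared by all of a patient's samples, so
  same-patient images correlate the way repeated scans do;
* **pixel noise and sub-pixel jitter** (SD 0.10 by default);
* **patient-disjoint splits** — patients (never samples) are partitioned
  train/validation/test (default 0.67/0.19/0.14, largest-remainder
  rounding), and the container's `validate()` rejects any patient spanning
  two splits.

With both SDs at zero, two same-class samples are pixel-identical; the
random number stream does not depend on the SD values, so datasets with
different noise levels stay comparable draw-by-draw. Bodies whose sampled
size would leave the canvas raise a descriptive `PhantomGeometryError`
rather than silently clipping anatomy.

The phantom is an emulation target for *pipeline behaviour*, not for MRI
realism: it gives the GAN a learnable class-conditional distribution, the
classifiers a non-trivial task (small CNNs reach macro AUC > 0.9 on
held-out patients), and the privacy attacks a realistic patient-clustered
candidate pool.

## 3. Certification axes

### Fidelity / utility transfer

Two classifiers with byte-identical configuration are trained — `F_real` on
the real training split, `F_synthetic` solely on the synthetic release —
and both are evaluated on the same real test split. The desk classifier is
a compact conv-batchnorm-ReLU CNN (halving blocks to 4×4, then a softmax
head) trained with SGD (momentum 0.9, lr 1e-4, 20 epochs, batch 32,
cross-entropy) — the reference protocol's optimizer and loss at a
CPU-trainable width. Performance is summarized by the confusion matrix and
the macro-average one-vs-rest ROC; the real-minus-synthetic AUC gap gets a
joint-bootstrap BCa interval (both arms' posteriors resampled on the same
test indices). The pipeline's fidelity verdict requires the synthetic arm
to beat chance (macro AUC > 0.5) on real held-out data.

### Diversity

A 2-D UMAP embedding is fitted on real data only; synthetic samples are
projected through the frozen transform. Coverage = median real-to-nearest-
synthetic distance divided by the median real-to-real nearest-neighbour
spacing (must be ≤ 3); collapse = synthetic spacing over real spacing (must
be ≥ 0.1, guarding against a generator that repeats a few modes); all three
labels must be present.

### Privacy

An attacker holds a candidate image and the released synthetic dataset.
Candidates are drawn in equal thirds from train/validation/test (the
reference protocol's 1000-candidate set uses 334/333/333). Two attacks are
simulated, in pixel space and in a 64-feature UMAP embedding fitted on real
data (reference counts 3000/1000/1000 per split):

* **pairwise** — score = minimum Euclidean distance to any synthetic
  sample (small ⇒ suspicious);
* **distribution** — score = number of synthetic samples within the 1st
  percentile of the pooled candidate-to-synthetic distance distribution
  (large ⇒ suspicious).

Attack strength is the ROC AUC of separating train-origin from
validation-origin candidates (test-origin AUCs and top-k origin
compositions are reported as supporting evidence). The release **fails**
if any train-vs-validation AUC reaches 0.6. Validation, not test, drives
the verdict: validation members share the acquisition context of training
members, so distinguishing them isolates *membership* leakage from
distribution shift.

## 4. Statistical machinery

* **Macro ROC** — per-class one-vs-rest ROC curves (scikit-learn),
  interpolated onto a common 512-point FPR grid and averaged with equal
  weights; the macro AUC is the trapezoidal area under the averaged curve.
  Classes absent from the truth are excluded with a warning.
* **BCa bootstrap** — bias-corrected and accelerated intervals, 2000
  resamples by default. The resampling unit is the test-set index, so
  (posterior, label) pairs — and in arm comparisons, both arms' posterior
  rows — stay paired. Bias `z0` comes from the fraction of bootstrap
  statistics below the observed value (ties counted half), acceleration
  `a` from jackknife skewness. At n ≈ 30 the empirical coverage of a 95 %
  interval is ≈ 0.91; scipy's BCa reproduces the same value, i.e. this is
  a property of the estimator, not of the implementation.
* **Label simulation** — `numpy.random.default_rng(seed).choice`, exposed
  as `sample_labels`; 10,000 draws from the generation distribution land
  within 3 binomial SEs (±0.015) of the thoracic mass 0.55.

## 5. Numerical choices

* **Hand-written NumPy networks.** No deep-learning framework is assumed.
  `pgan.nn` implements Conv2d / ConvTranspose2d (einsum over kernel
  offsets on strided views), BatchNorm2d (train/eval modes, running
  stats), Linear, ReLU/LeakyReLU/Tanh, Adam and SGD. Every backward pass
  is verified against central finite differences in the test suite
  (agreement to ~1e-8).
* **Determinism.** Every stochastic component takes an explicit seed;
  stage seeds in the pipeline are derived from the global seed via CRC-32
  of the stage name through `SeedSequence`, so reruns reproduce every
  number. The UMAP transform is wrapped in a content-hash cache so it
  behaves as a pure function of the pixels.
* **Probability clamping.** Log-probabilities clamp their arguments to
  `[1e-7, 1 - 1e-7]` before logs, so perfect discriminators and degenerate
  posteriors give finite losses.
* **Resumable artifacts.** Every pipeline stage persists to HDF5 / zip /
  JSON / pickle and reloads instead of recomputing; `--force` overrides.

## 6. Limitations

* The phantom's geometry is a deliberate caricature of vertebral anatomy;
  absolute AUC values on phantom data do not transfer to clinical images.
* The desk-scale GAN (32×32, truncated stacks, minutes of CPU training)
  demonstrates the workflow end to end but does not reach the sample
  quality of the reference 64×64 configuration trained at length.
* The classifier arm is a compact CNN; a ResNet-18 arm would require a
  deep-learning framework and is out of scope (`ClassifierConfig`
  validates `architecture="cnn"` only).
* BCa intervals undercover slightly at small test-set sizes (see §4);
  reported intervals at n ≲ 30 should be read accordingly.
* The privacy verdict is a *simulation* of two specific attacks; passing
  it is evidence, not proof, that no membership inference is possible.
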