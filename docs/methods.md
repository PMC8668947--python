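# Methods

## Problem and model

The package addresses three-class classification of skin-tissue Raman
spectra (basal cell carcinoma BCC, squamous cell carcinoma SCC, and NORMAL
tissue) in the small-sample regime, where each measured spectrum is a vector
of d intensity values on a shared wavenumber axis (default 600.237–1699.39
cm⁻¹ sampled at d = 1608 positions). Two components interact:

1. **Per-class GAN augmentation.** One vanilla generative adversarial
   network is trained per tissue class on min-max-scaled intensities. The
   generator maps a 100-dimensional standard-normal latent vector through
   fully connected layers of 100, 64, 64, 64 units (each followed by batch
   normalization, ReLU activations) to a sigmoid output of width d. The
   discriminator maps a spectrum through fully connected layers — the first
   as wide as the input (1608 at the default d), then 64, 64, leaky-ReLU
   (slope 0.2) — to a single probability unit. Training alternates k
   discriminator ascent steps with one generator descent step on

       V(G, D) = E_x[log D(x)] + E_z[log(1 − D(G(z)))],

   the generator minimizing E_z[log(1 − D(G(z)))] (the saturating form; a
   non-saturating option is available but off by default). Both nets use
   Adam at learning rate 2e-4, default 500 epochs, batch size min(32, class
   size), k = 1.

2. **1-D CNN classification.** r = 120 rectified filters of width k = 5 are
   slid over the spectrum (valid convolution, output length d − k + 1), the
   feature-map matrix is max-pooled, and a dense softmax layer predicts the
   class, trained by cross-entropy with Adam at learning rate 1e-3.
   Rival families with the same training regime: softmax (logistic)
   regression, PCA(100)+LR, linear SVM capped at 500 iterations (with
   held-in Platt calibration for probability output), PCA(100)+SVM, an MLP
   with hidden layers (100, 32), and an LSTM with 100 hidden units followed
   by dense layers (10, 500).

Augmentation strategies: **balanced** adds the same number n′ of synthetic
samples to every class (class sizes c_k + n′, total n + K·n′); **stratified**
adds m·c_k to each class, preserving class priors exactly. Either count
scheme can be served by the per-class GANs or by SMOTE (each synthetic point
is x + u·(x_nn − x) for a uniformly drawn class sample x, one of its k = 5
Euclidean nearest class neighbours x_nn, and u ~ Uniform[0,1]).

## Evaluation protocol

Leave-one-out cross-validation over the measured samples. By default,
augmentation is performed **inside each fold** on the training fold only:
the per-class GANs are retrained per fold, synthetic samples are never test
items, and the held-out spectrum cannot leak into the generators or the
classifier. A `global_augment` switch reproduces the alternative reading in
which the generators are trained once on all data before cross-validation;
it is clearly labelled in every report because it is potentially leaky.
Metrics: accuracy, macro-F1 (unweighted per-class F1, 0/0 → 0), and macro
one-vs-rest AUC computed in the rank-based (Mann–Whitney) form with ties
counted 1/2; AUC for a subgroup skips classes lacking positives or
negatives. Metrics are reported for all samples and for the treated /
untreated subgroups (laser-ablation flag); empty subgroups report missing
values, never 0. Argmax ties break toward the lowest class index under the
fixed alphabetical class ordering (BCC, NORMAL, SCC).

## Synthetic benchmark generator

The measured clinical dataset is not public, so the package ships a
parametric generator that emulates its statistical structure. Each class is
a `ClassSignature`: Lorentzian bands (standard line shape for Raman bands;
the kernel equals 1 at its center so a band contributes exactly its
amplitude there) at literature tissue-Raman positions (phenylalanine 1004
cm⁻¹, CH₂ deformation 1445 cm⁻¹, amide I 1655 cm⁻¹, plus class-specific
marker bands), a broad polynomial fluorescence baseline over the normalized
axis, and signal-dependent Gaussian noise with sd = noise_scale ·
sqrt(max(signal, 0)) — a continuous proxy that preserves the defining
property of photon shot noise. The laser-treatment covariate multiplies the
baseline by 0.8 for treated samples and is deliberately almost
label-irrelevant; it is metadata for subgroup reporting, never a feature.

The default benchmark reproduces the reference dataset's shape exactly:
d = 1608 on 600.237–1699.39 cm⁻¹, class sizes 36/63/50 (total 149),
treated/untreated splits NORMAL 28/35, SCC 20/30, and BCC 2/34 — the BCC
split is configurable; 2/34 is the default as the only split summing to 36
consistent with the reported per-class totals.

What the generator does **not** emulate: instrument response functions,
cosmic-ray spikes, wavelength calibration drift, patient-level correlation
between spectra, and real biochemical variability within a class (within-
class variation here is only noise plus the treatment baseline factor).
Passing tests on this benchmark therefore demonstrate that the pipeline's
machinery is correct and directionally consistent, not that the clinical
accuracy figures transfer.

## Fixture sizes used by the acceptance checks

Chosen once for single-CPU tractability and an informative difficulty
regime:

- *Benchmark reconstruction and augmentation arithmetic*: the full default
  benchmark (149 × 1608).
- *Classifier sanity*: a noiseless, well-separated benchmark of 10 samples
  per class at d = 384 (same axis range); the default CNN configuration
  (r = 120, k = 5) trained 100 epochs should reach leave-one-out accuracy
  ≥ 0.9 — it reaches 1.0 in practice.
- *GAN fidelity*: 16 noiseless single-class spectra at d = 400, 300 epochs;
  the mean generated spectrum should correlate ≥ 0.9 (Pearson) with the
  class mean in ≥ 4 of 5 seeds.
- *Augmentation benefit*: a scarce noisy benchmark (8 samples per class,
  d = 192, shot-noise scale 1.2 — calibrated so the unaugmented CNN sits
  near 0.75–0.79 accuracy, below ceiling), balanced GAN augmentation with
  n′ = 64, per-fold GAN epochs 300, CNN epochs 40, 5 seeds. The comparison
  is directional (augmented mean ≥ baseline mean): with only 24 LOO folds
  per seed the per-seed difference is a small-count statistic.

## Numerical choices

- Probabilities inside log terms of the GAN objectives are clamped to
  [1e-7, 1 − 1e-7] when the values are *reported*; training gradients are
  taken at the discriminator's logit (the standard stable form,
  mathematically identical), because clamping with a masked gradient can
  freeze the generator permanently once the discriminator saturates.
- Batch normalization uses batch statistics during training and exponential
  running averages (momentum 0.9) at sampling time, so generation is
  deterministic given the seed.
- Scaling is fitted on the training fold only; features constant on the
  training fold map to 0 under both min-max and standardization (unit
  divisor), which keeps the transform finite and invertible.
- The pooled feature of the CNN defaults to the max across the *filter* axis
  (output length d − k + 1); the conventional global max over positions
  (output length r) is available as `pooling="global"`. Both readings of the
  max-pooling step are defensible for 1-D spectra, so both are implemented
  and the choice is logged in every config snapshot.
- The LSTM consumes the spectrum chunked into windows of 8 adjacent
  wavenumbers (sequence length ⌈d/8⌉) to keep backpropagation through time
  affordable on CPU; the window is configurable.
- Per-cell experiment seeds are master_seed + a stable hash of the cell
  descriptor, so extending a grid never changes existing cells.
- All randomness flows through seeded `numpy.random.Generator` streams;
  training, sampling, and evaluation are bit-reproducible given a seed.

## Known limitations

- Neural models are plain NumPy implementations; they are exact and
  reproducible but not GPU-accelerated, so full-scale grids (500 epochs,
  n′ up to 1024, 149 LOO folds) are hours of CPU time. Defaults in the
  evaluation harness (per-fold GAN epochs) are therefore configurable.
- The saturating generator loss (the default, matching the stated
  objective) learns slowly when the discriminator dominates; the
  non-saturating flag is provided for practical use.
- SVM probabilities come from held-in Platt scaling of decision values,
  which is optimistic relative to cross-validated calibration; it is used
  only to rank classes for AUC.
- The clinical tables' absolute metric values are not reproducible without
  the private dataset; the package reproduces structural counts exactly and
  the qualitative augmentation effect directionally.
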