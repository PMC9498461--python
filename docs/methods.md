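# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `teamoist`.

## Problem setting

During green-tea fixation, leaves are heated in a roller and their moisture
content falls from roughly 68 % to 16 % over ~225 s.  Moisture is the
operational indicator of fixation degree, so the task is regression: predict
the per-sample moisture fraction from a 900–1700 nm NIR reflectance spectrum
and/or a colour image of the leaf bed.  NIR responds directly to the O–H
overtones of water (absorption bands near 1180 nm and 1440 nm); the image
responds indirectly, through colour and texture changes as the leaf dries.

## Data model and preprocessing

Spectra live in a `SpectraTable` (samples × wavelengths, moisture stored as
a fraction in [0, 1]; RMSEP values around 0.01 are therefore percentage
points ÷ 100).  Analysis crops to 980–1670 nm, where the instrument is
quiet.  Preprocessing options:

* **SNV** — per-spectrum centring and scaling by the sample standard
  deviation (n−1 throughout the package).  Removes multiplicative scatter
  and additive offsets exactly (it is invariant to `a + b·x`, b > 0).
* **MSC** — least-squares fit of each spectrum on a reference (the mean of
  the *training* spectra, stored at fit time and reused on prediction data
  so no test information enters the reference), then inversion of the
  fitted offset and slope.
* **max–min** — row-wise rescaling onto [0, 1].  Applied per spectrum by
  default; the per-wavelength variant exists for the fusion stage.

SNV and max–min are applied per spectrum (the chemometrics convention);
min–max inside mid-level fusion is per column, to put PCA score columns of
different blocks on one scale.

## Image features

A fixed square ROI (1080 × 1080 in production, scalable for tests) yields
17 variables.  Colour: per-pixel sRGB→HSV and sRGB→CIELAB (D65) conversion,
then spatial means; hue is an angle and is averaged on the unit circle
(the arithmetic mean of 350° and 10° would be 180°; the circular mean is
0°).  Texture: BT.601 luma quantized uniformly to 64 grey levels; the
histogram gives average grey level m, uniformity U = Σp², entropy
e = −Σp·log₂p (bits) and variance v; a symmetric grey-level co-occurrence
matrix at distance 1, averaged over the four standard angles
(0°/45°/90°/135°), gives energy en = ΣP², inertia i = Σ(i−j)²P, inverse
difference moment IDM = ΣP/(1+(i−j)²) and correlation c.  Splitting the
statistics across the histogram (m, U, e, v) and the co-occurrence matrix
(c, i, IDM, en) avoids U and en being duplicate definitions.  Averaging
over the four angles makes the texture block invariant to 90° image
rotation, which the tests exploit as an oracle.  A constant image has
U = en = IDM = 1 and e = i = v = 0; its correlation is undefined (zero
marginal variance) and is reported as 0 with a warning.

## Fusion

* **LDF** concatenates the preprocessed spectral block and the 17 image
  features column-wise.
* **MDF** fits a mean-centred, unstandardized PCA per block on training
  rows only, min–max scales each score column with training statistics
  (prediction rows may leave [0, 1]), and concatenates.

PCA loadings carry a deterministic sign convention (largest-magnitude
element of each loading positive).  Component counts come from a cumulative
explained-variance threshold (0.99) or fixed overrides.  The *pipeline*
default is fixed counts — 5 spectral and 2 image components, the
configuration of the original acquisition design: under the generator's
isotropic white noise the threshold rule retains ~180 spectral components
whose pure-noise score columns are then amplified by min–max scaling, which
measurably degrades the downstream model (median Rp 0.991 vs 0.994).  A
validation scan over k ∈ {5…40} found no clearly better choice than 5/2.

## Elman network

Hidden width 10, tanh hidden transfer, identity output.  Inputs are static,
so the context state is reset to zero for every sample and the recurrence
is run K = 2 steps on the same input: predictions are then independent of
sample presentation order while the context weights w₁ remain active.
Inputs and target are min–max scaled to [0, 1] with training statistics and
predictions inverse-transformed.

Training is full-batch gradient descent on MSE with the gradient truncated
at the context copy (one-step truncated backpropagation through time).
Three stabilization choices matter in practice:

* **fan-in initialization** — the input-to-hidden block is drawn
  U(−0.5, 0.5)/√n_in.  Without the √n_in factor, tanh saturates and
  training diverges on wide inputs such as the 346-channel spectral block.
* **best-iterate return** — the trainer returns the weights with the lowest
  observed training MSE, not the last ones.  A fixed-step descent started
  near a sharp minimum can overshoot; the best-iterate rule guarantees
  training never ends worse than its own starting point.
* **learning-rate backoff** — on divergence (non-finite or exploding loss)
  the rate is divided by 5, up to three retries.

Defaults (600 epochs, rate 0.1) were chosen by validation on the synthetic
campaign across input widths from 7 (fused) to 363 (LDF) features.

## Whale optimization algorithm

Standard WOA over a box, minimization convention: per iteration and whale,
draw element-wise coefficient vectors A = 2a·r₁ − a and C = 2r₂ with the
control parameter a decaying linearly 2 → 0; with probability ½ follow the
logarithmic spiral around the best solution (shape constant b = 1,
l ~ U(−1, 1)), otherwise encircle the best solution where |A| < 1 and
search around a random whale where |A| ≥ 1 — the exploitation/exploration
choice is made **per dimension** from the element-wise A, following the
original reference implementation.  Positions are clamped to the bounds;
the incumbent best is replaced only by a strictly better candidate, so the
best-fitness history is non-increasing.  Candidates with non-finite
objective values are rejected (treated as +∞) with a warning.

## WOA-ENN coupling

The optimizer searches θ ∈ [−1, 1]^d, d = n_h² + n_h·n_in + n_h + n_h + 1
(191 for 7 inputs, 10 hidden), decoded in the same parametrization family
as the random initializer (input block fan-in scaled) — searching raw
weights in [−1, 1] produces saturated networks that gradient descent cannot
improve.  Fitness is the training MSE **after a 20-epoch gradient burst**
from the candidate.  The cheaper untrained-MSE fitness is available
(`burst_epochs=0`) but is not the default: across 10 paired seeds it
selects basins whose fully trained MSE is systematically worse than plain
random initialization (median 6.7e-4 vs 4.8e-4), i.e. it defeats the
purpose of the search, whereas the burst fitness wins the paired comparison
10/10 (median 3.0e-4 vs 1.2e-3) and lifts the fused-model median RMSEP to
≈ 0.009 moisture fraction.  Population 30, 100 iterations by default;
`woa_iters=0` skips the search and reduces exactly to the plain estimator,
which the tests use as an ablation identity.

## Baselines and evaluation

PLSR selects its latent-variable count by 5-fold cross-validated RMSE;
ε-SVR uses an RBF kernel with (C, γ, ε) chosen by grid search over a
declared grid, after standardization.  Evaluation on the prediction set:
Rp (Pearson), RMSEP = √(Σ(ŷ−y)²/n) in moisture fraction, and
RPD = SD(y_true; n−1)/RMSEP, so RPD·RMSEP = SD(y) holds to machine
precision.  RPD bands are reported as qualitative labels only
(>1.4 applicable, 1.8–2 good, >2 excellent).  RPD is +∞ when RMSEP = 0.

## Synthetic campaign

The generator emulates the acquisition design: 10 time points at 25 s
spacing, 34 replicates each (340 records).  Mean moisture follows an
exponential drying curve through 68.17 % at 0 s and 15.97 % at 225 s
(first-order drying kinetics); replicates jitter with sd 0.8 percentage
points, enough for adjacent time points to overlap slightly.  Reflectance
is exp(−absorbance) on a 2 nm grid, with a gently tilted baseline and two
Gaussian bands (1180 nm/width 40 nm, 1440 nm/width 60 nm) whose depths are
affine in the moisture fraction; each record is the average of three scans,
each distorted by a multiplicative scatter factor N(1, 0.05), an additive
offset N(0, 0.02) and white noise sd 0.005.  Images: mean leaf colour
interpolates linearly from bright green (wet) to darker yellow-green (dry)
with band-limited noise texture whose amplitude grows as the leaf dries;
`fast_mode` (default) skips rendering and emits the 17 features directly
through affine moisture maps plus noise, with noise levels set so the
vision modality is informative but clearly weaker than NIR, as colour and
texture only track moisture indirectly.

What the generator does **not** emulate — and therefore what passing tests
cannot show about real data: it contains no irrelevant structured
variation (no interfering chemical constituents, illumination drift or
instrument artefacts beyond scatter/offset/white noise).  All spectral
variation is moisture-driven, so the full spectral block is nearly
sufficient and concatenation-style fusion is not penalized for carrying
"useless information" the way real campaigns penalize it.  One directional
consequence, reported honestly by the test suite: the plain Elman model on
mid-level-fused features does not beat its low-level counterpart here
(median Rp 0.994 vs 0.999 over 10 seeds), although the whale-optimized
model on the same fused features does reach parity (0.9987), showing the
fused representation loses essentially nothing and the gap is training
variance of the plain network.  Transfer of the numeric results to real
instruments is out of scope.

## Reproducibility and sizes

Every stochastic element (generation, split, initialization, the whale
search) is driven by an explicit seed; repeated runs are bit-identical.
Comparison suites repeat the grid across seeds and compare medians, because
single recurrent-network runs can be unstable.  The acceptance script uses
10 repetitions of the 340-record campaign with a 272/68 split — the full
protocol size — and completes in about two minutes on one CPU.

## Known limitations

* The recurrent loop adds representational richness but the package makes
  no claim about genuine temporal modelling; K is a fixed replication of a
  static input.
* MSC can fail per spectrum when the fitted slope is near zero; this raises
  rather than silently passing data through.
* The SVR grid is deliberately small and declared; it is a baseline, not a
  tuned competitor.
* Rendered-image mode is exercised at small ROI sizes in tests; the
  1080 × 1080 production path is the same code but is not routinely run.
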