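# Methods

This note documents the models, algorithms and design decisions behind
`fruitspec`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

A push-broom VNIR hyperspectral camera images fruit at 462 spectral
channels over 386–1,004 nm (≈1.3 nm resolution). From each fruit one mean
reflectance spectrum is extracted, and two quality metrics are regressed
from it: soluble solids content (SSC, °Brix — a refractometric sweetness
proxy) and firmness (N/cm² at fixed probe depth — a maturity proxy). The
pipeline has four stages: reflectance calibration, ROI spectrum extraction,
chemometric pre-treatment, and regression.

## Reflectance calibration and ROI extraction

Calibration is the standard two-point correction
`R_c = (R_ori − R_dark)/(R_white − R_dark)` with a white ≈100 %-reflectance
standard and a lens-capped dark capture. Reference captures are per-band
vectors by default (an averaged reference image); full reference images are
accepted. Values are **not** clipped to [0, 1]: clipping is not part of the
correction and would bias band means; MSC and all downstream models
tolerate slightly out-of-range values. A white band equal to the dark band
raises an error naming the band rather than dividing by zero.

ROI selection on real fruit images is traditionally manual. Here it is a
deterministic two-threshold mask for reproducibility: pixels whose
broadband mean reflectance lies strictly above the lower
`1 − highlight_percentile` quantile (the specular highlight on the convex
fruit surface) or below `background_threshold` (background) are excluded,
and the rest are averaged per band. The quantile uses the "lower"
interpolation rule so that a cohort of inflated pixels occupying exactly
the top fraction is excluded exactly. Both parameters are exposed; an
empty mask is an error reporting both thresholds. This mask is a stand-in
for manual ROI workflows, not a reconstruction of any particular one.

The ENVI reader supports BIL/BIP/BSQ interleaves, uint16 and float32
samples and both byte orders, and honors header wavelength lists (absent a
list, a uniform 386–1,004 nm grid is synthesized). Anything else is
rejected loudly with the offending header field named, rather than guessed.
It is checked against an independent triple-loop byte decoder in the tests.

## Pre-treatments

**MSC.** The ideal spectrum is the per-band mean over samples. Each sample
is regressed on it by closed-form OLS (`b = cov(x, m)/var(m)`,
`a = x̄ − b·m̄`) and corrected as `(x − a)/b`. A slope below 1e-8 (a flat
sample; far below float noise for reflectance-scale data) is an error
naming the sample. The reference scope defaults to `all_samples` — the
ideal spectrum is the average of *all* spectra — with `train_only` offered
to avoid leakage; the evaluation metadata records which was used.

**Second-order differentiation.** The default is the plain three-point
second difference on interior bands (output lives on the grid trimmed by
one channel per end). It is exactly linear, zero on affine spectra and
constant 2 on unit-spaced quadratics, which the tests assert. Because raw
differences at ~1.3 nm resolution amplify noise, a Savitzky–Golay
local-polynomial mode (default window 11, order 3) is available with the
same interior-trim contract. Output is not rescaled by 1/Δλ² by default —
every downstream model here is scale-invariant — but physical scaling is a
flag.

The two treatments are composable (`msc_then_derivative`) but treated as
alternatives by default, matching the usual side-by-side comparison layout.
Fitted state (reference spectrum + config echo) serializes to plain JSON
and re-applies bit-for-bit.

## Synthetic data generator

No public dataset exists for this design, so the generator is first-class,
tested code that defines the study conditions. It emulates, per sample:

* a sigmoidal continuum rising from ~0.12 below 550 nm to ~0.82 in the
  NIR (the carotenoid/chlorophyll absorption edge of ripe tomato);
* Beer–Lambert-style multiplicative Gaussian absorption bands
  (`r = continuum · exp(−Σ depth_k · G_k)`), keeping spectra positive and
  making depths interpretable. The default band table holds the broad
  400–550 nm pigment absorption plus bands at 585, 685 and 975 nm, so the
  clean spectrum's second derivative shows extrema inside the 580–590,
  680–690 and 970–980 nm windows reported for real tomato;
* label-linked band depths: `depth_k = base_k + load_SSC,k·z(ssc) +
  load_firm,k·z(firm)`, floored at 0. SSC loads on the 585 and 975 nm
  bands; firmness loads on the 685 nm band, weakly on the broad pigment
  band, and on a continuum tilt — deliberately the weaker, more diffuse
  signal, so firmness is harder to regress than SSC, as on real fruit;
* labels from truncated normals matched to a 200-fruit field sample:
  SSC ~ N(8.719, 0.662²) on [7.2, 11.1] °Brix, firmness
  ~ N(8.853, 1.229²) on [5.978, 12.936] N/cm²;
* measurement effects: per-sample gain ~ N(1, 0.08) and offset ~ N(0, 0.01)
  (multiplicative scatter, which MSC removes), i.i.d. per-band noise
  (SD 0.002), and smooth broadband interference — random low-order
  Legendre baseline wiggles (orders 1–4, weights 1/j, coefficient SD 0.05,
  i.e. a few percent of reflectance). The interference models
  sample-to-sample "unwanted reflectance" (surface color and curvature
  residuals, stray light) that a single gain/offset correction cannot
  remove. It is what makes naive all-band distance and kernel methods
  (k-NN, RBF-SVR) degrade on these spectra while structured learners
  (PLS projections, convolutional features) see through it — the
  qualitative regime observed on real fruit data.

One global seed drives labels, scatter, noise and interference through
independent spawned sub-streams; identical seeds give bit-identical
datasets.

What the generator does **not** emulate: radiative transfer, skin/flesh
layered optics, wavelength-dependent instrument response, label
measurement error, or the exact spectra of any real cultivar. Passing
tests on synthetic data therefore demonstrate that the pipeline recovers
known signal under realistic nuisance structure — not field performance.

## The deep regression network

The network is a ResNet-34-style architecture with all convolutions
one-dimensional and the classifier replaced by a single-output linear
head:

* stem: conv(k=3, stride 2) → batch norm → ReLU → max-pool(k=3, stride 2)
  → dropout 0.5;
* stage 2: 3 residual units at 32 filters;
* stage 3: 1 downsampling unit + 3 residual units at 64 filters;
* stage 4: 1 downsampling unit + 5 residual units, dropout 0.5, then 3
  residual units, at 128 filters;
* head: global average pool → linear → 1 value.

A residual unit computes `ReLU(x + BN(conv(ReLU(BN(conv(x))))))`; a
downsampling unit strides its first convolution by 2 and projects the skip
path with a kernel-1 stride-2 convolution + batch norm. All strided layers
use ceil-mode "same" padding, so odd input lengths survive. Batch norm
follows every convolution (standard ResNet-34 behavior). Inputs shorter
than 16 channels cannot support the stem + two downsampling stages and are
rejected with that minimum stated.

**Stride reading.** A literal stride of 3 in *every* convolution would
collapse a 462-channel input long before 16 units of depth; the package
therefore uses the conventional ResNet striding (1 inside residual units,
2 in the stem and downsampling units) as the default and keeps a
`literal_stride3` switch for the literal reading, which errors if the
signal collapses.

**Engine.** The network is implemented directly in numpy: im2col
convolutions backed by BLAS matmuls, manual backpropagation (verified
against numerical gradients in development), float32 throughout, Adam
(β₁ 0.9, β₂ 0.999, ε 1e-8). Training is exactly `epochs` epochs of seeded
shuffled minibatches of MSE loss; everything is deterministic given the
seeds. A non-finite loss raises a divergence error naming the epoch and
learning rate. Default learning rate 1e-3 (configurable).

**Dropout.** Two choices matter and are deliberate:

1. *Channel-wise masks.* Positions within a 1-D conv feature map are
   strongly correlated, so i.i.d. per-position masks mostly inject local
   sum noise instead of removing features, and — with batch norm
   downstream — produce a severe train/eval distribution shift. Dropout
   here removes whole feature maps per sample (the `Dropout1d` /
   `SpatialDropout1D` reading), the standard convolutional form.
2. *Annealed schedule.* Even channel-wise dropout at rate 0.5 ahead of a
   deep BN stack leaves the trained function mis-calibrated when masks are
   removed at inference. The default training schedule linearly anneals
   the dropout rate to zero over the epochs (early-phase regularization,
   mask-free final network); `dropout_anneal="constant"` restores a fixed
   rate. After training, batch-norm running statistics are re-estimated in
   one dropout-free pass over the training spectra (cumulative mean of
   batch statistics), so deterministic inference matches the converged
   training-mode function. Inference never uses dropout.

**Checkpoints.** Weights go to `.npz` with a JSON sidecar (architecture
echo, band count, target, train config), so inputs can be validated at
predict time without loading the weights.

## Baselines

SVR, k-NN regression, AdaBoost regression and PLS regression are thin
adapters over scikit-learn behind the same fit/predict contract — they are
the yardstick, not the contribution. Hyperparameters default to the library
defaults, fully exposed; PLSR defaults to 10 components (latent-projection
models on spectra typically use on the order of 5–20). AdaBoost gets a
fixed `random_state` and training rows are fed in canonical (sample-id)
order so that resampling-based fits do not depend on incidental row order.
The deep network consumes raw spectra; baselines consume the configured
pre-treatment — the comparison runner enforces this pairing.

## Evaluation protocol

Split sizes are `floor(0.7·n) / floor(0.1·n) /` remainder, assigned by one
seeded uniform shuffle; this reproduces the canonical 140/20/40 and
35/5/10 partitions. No stratification by default (a stratified option is
not provided; labels are near-normal and splits are seeded). Metrics are
computed on the test split; per-epoch validation loss is logged but never
drives early stopping — training runs a fixed number of epochs. Negative
R² is reported as-is, never clamped. Per-cell model failures are captured
in the report (an `error` field) without aborting the run, and the report
serializes to CSV and JSON with a full config/seed echo.

## Problem sizes used in the shipped checks

The unit suite runs the generator at n ≤ 300 and trains the network for 1–8
epochs except for two deeper checks: an 8-sample/500-epoch memorization
test, and one full recovery experiment at n = 1,000 with the default
50-epoch protocol, in which the network must reach test R² ≥ 0.7 on SSC
and beat SVR and k-NN in the same run. `scripts/acceptance.py` runs the
complete comparison at the 200-sample field scale. The loss-decrease
repeatability check runs 5 seeds at 8 epochs; the 50-epoch regime is
covered by the recovery experiment.

## Known limitations

* The synthetic generator is a fixture with interpretable knobs, not a
  biophysical model; absolute R² values on it do not predict field
  performance.
* The dropout schedule departs from a fixed-rate reading of the
  architecture description (see above); the fixed-rate variant remains
  available but is not eval-consistent at rate 0.5.
* The ENVI reader covers the two sample types and three interleaves used
  in practice here; it is not a general ENVI implementation.
* Single-split evaluation (no cross-validation) by design, to match the
  reference protocol.
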