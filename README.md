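# fruitspec

Non-destructive estimation of fruit quality from hyperspectral reflectance.
`fruitspec` implements the full chain from a push-broom camera's raw output
to a model-comparison table: reflectance calibration, highlight-free ROI
spectrum extraction, chemometric pre-treatments, a one-dimensional
convolutional residual regression network with four classical baselines,
and a reproducible split/evaluation protocol. Because no public
cherry-tomato dataset at this design exists, the package ships a
first-class synthetic generator that emulates tomato VNIR reflectance
(462 channels, 386–1,004 nm) with latent soluble-solids-content (SSC,
°Brix) and firmness (N/cm²) signal, so every stage is testable end to end.

It is aimed at chemometrics / plant-phenotyping researchers who want a
tested, scriptable reference implementation of this pipeline rather than a
GUI workflow.

## The methods in brief

**Calibration.** Raw counts become relative reflectance via the two-point
correction against a white (≈100 % reflectance) and a dark (lens-capped)
reference:

```
R_c = (R_ori − R_dark) / (R_white − R_dark)
```

**ROI extraction.** Glossy fruit produce a specular highlight; the mask
excludes the brightest fraction of pixels (by broadband mean) and the dark
background, and the surviving pixels are averaged into one spectrum per
fruit.

**Pre-treatments.** Multiplicative scatter correction (MSC) regresses each
spectrum `x_i` on the "ideal" (mean) spectrum `m` by ordinary least squares,
`x_i ≈ a_i + b_i·m`, and corrects `(x_i − a_i)/b_i`; second-order
differentiation applies the three-point second difference
`x[k−1] − 2x[k] + x[k+1]` (a Savitzky–Golay smoothed mode is available).

**Models.** The deep model is a ResNet-34-style network with 1-D
convolutions (all kernels size 3): a conv/max-pool stem, 16
residual/downsampling units in three stages of 32/64/128 filters with
dropout 0.5 after the stem and inside the last stage, and a global-average-
pool + linear head emitting one value. It trains with Adam on an MSE loss,
50 epochs of batch-16 minibatches by default, and consumes **raw** spectra.
The baselines — SVR, k-NN regression, AdaBoost, PLS regression — consume
pre-treated spectra through one fit/predict contract.

**Evaluation.** Samples split 7:1:2 (train/validation/test) by seeded
shuffle with a floor/floor/remainder rule (200 → 140/20/40, 50 → 35/5/10);
models are scored on the test split with

```
R² = 1 − Σ(ŷᵢ−yᵢ)² / Σ(ȳ−yᵢ)²        MSE = (1/m)·Σ(yᵢ−ŷᵢ)²
```

Negative R² is reported as-is.

## Worked example

`examples/04_train_and_compare_models.py` generates a 200-fruit synthetic
dataset, splits it 7:1:2, and compares all five models on SSC (10 epochs
for speed):

```
split sizes: {'train': 140, 'val': 20, 'test': 40}
model        preprocessing            R2      MSE
svr          second_derivative     0.182    0.336
knnr         second_derivative    -0.024    0.420
adaboost     second_derivative     0.157    0.346
plsr         second_derivative     0.376    0.256
svr          msc                   0.601    0.164
knnr         msc                   0.863    0.056
adaboost     msc                   0.911    0.037
plsr         msc                   0.990    0.004
con1dresnet  none                  0.643    0.146
deep vs best PLSR: -35.0 %
```

Each row is a (model × pre-treatment) cell scored on the 40-sample test
split; the deep network uses raw spectra (`none`). At this sample size the
latent-projection baseline leads and the network trails — it is data
hungry. On a 1,000-sample draw under identical default conditions the
ordering flips: the network reaches test R² ≈ 0.97 for SSC and overtakes
the distance/kernel baselines (this is asserted by
`tests/test_acceptance.py::test_deep_network_recovers_ssc_and_beats_distance_baselines`).

The other examples show the generator (01), calibration + ROI extraction on
a constructed cube (02), and MSC/derivative behavior (03); each prints the
quantities it computes and a line on what they mean.

There is also a thin CLI mirroring the library
(`fruitspec simulate|calibrate|preprocess|train|predict|compare`); every
run writes a resolved-config echo next to its outputs.

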