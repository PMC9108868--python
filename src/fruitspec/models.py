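"""Regression models: the 1-D convolutional residual network and four
classical chemometric baselines behind one fit/predict contract.

The deep model ("Con1dResNet") is a ResNet-34-style network with every
convolution made one-dimensional and the classification head replaced by a
single linear output, so the network regresses a quality value (SSC in
°Brix, or firmness in N/cm^2) directly from a raw reflectance spectrum:

* stem: conv(k=3, stride 2) - BN - ReLU - maxpool(k=3, stride 2) - dropout 0.5
* stage 2: 3 residual units, 32 filters
* stage 3: 1 downsampling unit + 3 residual units, 64 filters
* stage 4: 1 downsampling unit + 5 residual units, dropout 0.5,
  then 3 residual units, 128 filters
* head: global average pool + linear -> 1 value

That is the classic 3/4/6/3 ResNet-34 layout with the deepest stage merged
into stage 4 (16 residual/downsampling units in total).  All kernels are
size 3.  A written description of the architecture could be read as giving
every convolution a stride of 3; a literal stride-3 everywhere collapses a
462-channel spectrum to nothing long before 16 units, so the conventional
ResNet striding (1 inside residual units, 2 in the stem and the downsampling
units) is the default, and ``literal_stride3=True`` keeps the literal
reading reachable for comparison.

Training uses Adam on a mean-squared-error loss, 50 epochs of minibatches of
16 by default.  Baselines (SVR, k-NN, AdaBoost, PLS regression) are thin
adapters over scikit-learn — they are the comparison yardstick, not the
contribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import AdaBoostRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from ._net import (
    Adam,
    BatchNorm1d,
    Conv1d,
    Dropout,
    GlobalAvgPool,
    Linear,
    MaxPool1d,
    ReLU,
    ResidualUnit,
    flatten_layers,
)
from .preprocessing import PreprocessConfig
from .spectral_io import SpectrumSet
from .synthetic import LabeledDataset

__all__ = [
    "Con1dResNetSpec",
    "TrainConfig",
    "TrainingHistory",
    "BaselineSpec",
    "ModelHandle",
    "ArchitectureError",
    "DivergenceError",
    "GridMismatchError",
    "Con1dResNet",
    "build_con1dresnet",
    "train_model",
    "predict",
    "build_baseline",
    "BASELINE_NAMES",
]

MIN_INPUT_LENGTH = 16  # four stride-2 halvings need >= 2^4 channels
BASELINE_NAMES = ("svr", "knnr", "adaboost", "plsr")


class ArchitectureError(ValueError):
    """Input length cannot survive the pooling/downsampling chain."""


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


class GridMismatchError(ValueError):
    """Prediction input has a different band count than the fitted model."""


@dataclass
class Con1dResNetSpec:
    input_length: int = 462
    stem_filters: int = 32
    stage_units: tuple[int, int, int] = (3, 4, 9)  # incl. downsampling units
    stage_filters: tuple[int, int, int] = (32, 64, 128)
    dropout: float = 0.5
    stem_stride: int = 2
    literal_stride3: bool = False
    init_seed: int = 0


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "mse"
    # dropout-rate schedule across epochs: "linear" anneals the configured
    # rate to zero by the final epoch (keeps early-phase regularization while
    # leaving a mask-free network whose batch-norm statistics match
    # deterministic inference); "constant" keeps the rate fixed.
    dropout_anneal: str = "linear"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam" or self.loss != "mse":
            raise ValueError("only Adam + MSE are supported")
        if self.dropout_anneal not in ("linear", "constant"):
            raise ValueError("dropout_anneal must be 'linear' or 'constant'")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)


@dataclass
class BaselineSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in BASELINE_NAMES:
            raise ValueError(
                f"unknown baseline {self.name!r}; supported: {BASELINE_NAMES}"
            )


class Con1dResNet:
    """The 1-D residual regression network (numpy implementation)."""

    def __init__(self, spec: Con1dResNetSpec):
        if spec.input_length < MIN_INPUT_LENGTH:
            raise ArchitectureError(
                f"input length {spec.input_length} too short for the "
                f"stem + 2 downsampling stages; minimum is {MIN_INPUT_LENGTH}"
            )
        self.spec = spec
        rng = np.random.default_rng(spec.init_seed)
        res_stride = 3 if spec.literal_stride3 else 1
        down_stride = 3 if spec.literal_stride3 else 2
        sf = spec.stem_filters
        self.stem = [
            Conv1d(1, sf, 3, spec.stem_stride, rng=rng),
            BatchNorm1d(sf),
            ReLU(),
            MaxPool1d(3, 2),
            Dropout(spec.dropout),
        ]
        self.units: list[ResidualUnit] = []
        layers: list = list(self.stem)
        in_ch = sf
        for stage_idx, (n_units, filters) in enumerate(
            zip(spec.stage_units, spec.stage_filters)
        ):
            for u in range(n_units):
                downsample = stage_idx > 0 and u == 0
                unit = ResidualUnit(
                    in_ch,
                    filters,
                    stride=down_stride if downsample else res_stride,
                    rng=rng,
                )
                self.units.append(unit)
                layers.append(unit)
                in_ch = filters
                # stage 4: dropout between the 5-unit and 3-unit groups
                if stage_idx == 2 and u == 5:
                    layers.append(Dropout(spec.dropout))
        self.head_pool = GlobalAvgPool()
        self.head_linear = Linear(in_ch, 1, rng=rng)
        layers += [self.head_pool, self.head_linear]
        self.layers = layers
        self._param_layers = flatten_layers(layers)
        if spec.literal_stride3:
            length = spec.input_length
            for _ in range(len(self.units)):
                length = -(-length // 3)
            if length < 1:
                raise ArchitectureError(
                    "literal stride-3 collapses the signal below 1 channel"
                )

    def refresh_bn_stats(self, x: np.ndarray, batch_size: int = 64):
        """Re-estimate batch-norm running statistics with dropout disabled.

        Dropout layers sit upstream of later convolution + batch-norm
        stages, so activation variances seen during training are inflated
        by 1/keep relative to inference; running statistics averaged during
        training therefore mis-scale eval-mode activations.  One forward
        pass over the training spectra with dropout off, averaging batch
        statistics cumulatively, restores calibrated inference.
        """
        x = np.asarray(x, dtype=np.float32)
        dropouts = [l for l in self.layers if isinstance(l, Dropout)]
        rates = [d.rate for d in dropouts]
        bns = [l for l in self._param_layers if isinstance(l, BatchNorm1d)]
        saved_momentum = [bn.momentum for bn in bns]
        try:
            for d in dropouts:
                d.rate = 0.0
            for bn in bns:
                bn.running_mean[...] = 0.0
                bn.running_var[...] = 0.0
            starts = range(0, x.shape[0], batch_size)
            for t, start in enumerate(starts, start=1):
                for bn in bns:
                    bn.momentum = 1.0 / t  # cumulative mean of batch stats
                self.forward(x[start : start + batch_size], training=True)
        finally:
            for d, r in zip(dropouts, rates):
                d.rate = r
            for bn, mom in zip(bns, saved_momentum):
                bn.momentum = mom

    def seed_dropout(self, seed: int):
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng((seed, i))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (batch, input_length) spectra to (batch, 1) predictions."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 2:
            raise ValueError("expected a (batch, length) array")
        if x.shape[1] != self.spec.input_length:
            raise GridMismatchError(
                f"expected {self.spec.input_length} bands, got {x.shape[1]}"
            )
        h = x[:, None, :]
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def backward(self, dout: np.ndarray):
        d = dout.astype(np.float32)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    # --- audit helpers -----------------------------------------------------

    def unit_census(self) -> dict:
        """Counts used to audit the architecture against its description."""
        per_stage, filters = [], []
        i = 0
        for n_units, f in zip(self.spec.stage_units, self.spec.stage_filters):
            per_stage.append(n_units)
            filters.append(f)
            i += n_units
        return {
            "total_units": len(self.units),
            "units_per_stage": tuple(
                sum(
                    1
                    for u in self.units
                    if u.out_ch == f
                )
                for f in dict.fromkeys(filters)
            ),
            "downsample_units": sum(
                1 for u in self.units if u.kind == "downsample"
            ),
            "filters_per_stage": tuple(dict.fromkeys(filters)),
            "kernel_sizes": sorted(
                {u.conv1.kernel for u in self.units}
                | {u.conv2.kernel for u in self.units}
            ),
            "head_outputs": self.head_linear.params["w"].shape[0],
        }

    # --- checkpointing -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self._param_layers):
            for name, arr in layer.params.items():
                state[f"{i}.{name}"] = arr
            if isinstance(layer, BatchNorm1d):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]):
        for i, layer in enumerate(self._param_layers):
            for name in layer.params:
                layer.params[name][...] = state[f"{i}.{name}"]
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]


def build_con1dresnet(
    spec: Con1dResNetSpec | None = None,
) -> Con1dResNet:
    return Con1dResNet(spec or Con1dResNetSpec())


@dataclass
class ModelHandle:
    """A trained regressor plus the provenance needed to validate inputs."""

    kind: str  # {"deep", "baseline"}
    model: object
    band_count: int
    target: str
    preprocess: PreprocessConfig | None = None
    meta: dict = field(default_factory=dict)


def _dataset_matrix(data: LabeledDataset, target: str):
    if target not in ("ssc", "firmness"):
        raise ValueError("target must be 'ssc' or 'firmness'")
    y = data.ssc if target == "ssc" else data.firmness
    return data.spectra.spectra, np.asarray(y, dtype=float)


def train_model(
    model: Con1dResNet,
    train: LabeledDataset,
    val: LabeledDataset | None,
    target: str,
    config: TrainConfig | None = None,
) -> tuple[ModelHandle, TrainingHistory]:
    """Minibatch Adam/MSE training for exactly ``config.epochs`` epochs."""
    config = config or TrainConfig()
    x_train, y_train = _dataset_matrix(train, target)
    if x_train.shape[0] == 0:
        raise ValueError("training set is empty")
    x_train = x_train.astype(np.float32)
    y_train = y_train.astype(np.float32)
    rng = np.random.default_rng(config.seed)
    model.seed_dropout(config.seed)
    optimizer = Adam(model._param_layers, lr=config.learning_rate)
    history = TrainingHistory()
    n = x_train.shape[0]
    dropouts = [l for l in model.layers if isinstance(l, Dropout)]
    base_rates = [d.rate for d in dropouts]
    for epoch in range(config.epochs):
        if config.dropout_anneal == "linear":
            frac = 1.0 - epoch / max(config.epochs - 1, 1)
            for d, r in zip(dropouts, base_rates):
                d.rate = r * frac
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            pred = model.forward(xb, training=True)[:, 0]
            resid = pred - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch + 1} "
                    f"(learning rate {config.learning_rate})"
                )
            losses.append(loss)
            model.backward((2.0 * resid / resid.size)[:, None])
            optimizer.step()
        history.train_loss.append(float(np.mean(losses)))
        if val is not None and val.n_samples:
            model.refresh_bn_stats(x_train, config.batch_size)
            x_val, y_val = _dataset_matrix(val, target)
            pred = model.forward(x_val.astype(np.float32))[:, 0]
            history.val_loss.append(float(np.mean((pred - y_val) ** 2)))
    for d, r in zip(dropouts, base_rates):
        d.rate = r
    model.refresh_bn_stats(x_train, config.batch_size)
    handle = ModelHandle(
        kind="deep",
        model=model,
        band_count=model.spec.input_length,
        target=target,
        preprocess=None,
        meta={"config": asdict(config)},
    )
    return handle, history


def predict(handle: ModelHandle, spectra: SpectrumSet) -> np.ndarray:
    """One finite prediction per sample; dropout disabled."""
    if spectra.grid.count != handle.band_count:
        raise GridMismatchError(
            f"model fitted on {handle.band_count} bands, "
            f"received {spectra.grid.count}"
        )
    if handle.kind == "deep":
        out = handle.model.forward(
            spectra.spectra.astype(np.float32), training=False
        )[:, 0]
    else:
        out = np.asarray(handle.model.predict(spectra.spectra)).ravel()
    return out.astype(float)


class BaselineModel:
    """Uniform fit/predict adapter over a scikit-learn regressor."""

    def __init__(self, spec: BaselineSpec):
        self.spec = spec
        hp = dict(spec.hyperparameters)
        try:
            if spec.name == "svr":
                self.estimator = SVR(**hp)
            elif spec.name == "knnr":
                self.estimator = KNeighborsRegressor(**hp)
            elif spec.name == "adaboost":
                hp.setdefault("random_state", 0)
                self.estimator = AdaBoostRegressor(**hp)
            else:  # plsr
                hp.setdefault("n_components", 10)
                self.estimator = PLSRegression(**hp)
        except TypeError as exc:
            raise ValueError(
                f"invalid hyperparameters for {spec.name}: {exc}"
            ) from exc

    def fit(self, x: np.ndarray, y: np.ndarray) -> "BaselineModel":
        self.estimator.fit(x, y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(x)).ravel()


def build_baseline(spec: BaselineSpec) -> BaselineModel:
    return BaselineModel(spec)


def fit_baseline(
    spec: BaselineSpec,
    train: LabeledDataset,
    target: str,
    preprocess: PreprocessConfig | None = None,
) -> ModelHandle:
    model = build_baseline(spec)
    x, y = _dataset_matrix(train, target)
    # canonical row order: resampling-based fits (AdaBoost) would otherwise
    # depend on the incidental ordering of the training rows
    order = np.argsort(np.asarray(train.spectra.sample_ids))
    model.fit(x[order], y[order])
    return ModelHandle(
        kind="baseline",
        model=model,
        band_count=train.spectra.grid.count,
        target=target,
        preprocess=preprocess,
        meta={"baseline": spec.name, "hyperparameters": spec.hyperparameters},
    )


# --- checkpoint I/O --------------------------------------------------------


def save_checkpoint(handle: ModelHandle, path: str | Path):
    """Weights (.npz) plus a JSON sidecar describing the architecture."""
    if handle.kind != "deep":
        raise ValueError("checkpointing applies to the deep model")
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **handle.model.state_arrays())
    sidecar = {
        "architecture": asdict(handle.model.spec),
        "band_count": handle.band_count,
        "target": handle.target,
        "meta": handle.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> ModelHandle:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    arch = sidecar["architecture"]
    arch["stage_units"] = tuple(arch["stage_units"])
    arch["stage_filters"] = tuple(arch["stage_filters"])
    model = Con1dResNet(Con1dResNetSpec(**arch))
    with np.load(path.with_suffix(".npz")) as blob:
        model.load_state_arrays(dict(blob))
    return ModelHandle(
        kind="deep",
        model=model,
        band_count=sidecar["band_count"],
        target=sidecar["target"],
        meta=sidecar.get("meta", {}),
    )
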