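"""Experimental protocol: 7:1:2 splitting, R²/MSE metrics and the
multi-model comparison table.

The split rule is floor(n·train) / floor(n·val) / remainder-to-test under a
seeded uniform shuffle, which reproduces the canonical partitions
140/20/40 (n=200) and 35/5/10 (n=50).  Metrics are the coefficient of
determination

    R² = 1 - Σ(ŷᵢ - yᵢ)² / Σ(ȳ - yᵢ)²

(reported as-is, which may be negative when a model underperforms the mean
predictor) and the mean squared error.  The comparison runner fits every
requested (model × preprocessing × target) cell: the deep network consumes
raw spectra, the classical baselines consume the configured pre-treatment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .models import (
    BaselineSpec,
    Con1dResNetSpec,
    TrainConfig,
    build_con1dresnet,
    fit_baseline,
    predict,
    train_model,
)
from .preprocessing import PreprocessConfig, preprocess_pipeline
from .synthetic import LabeledDataset

__all__ = [
    "SplitRatios",
    "MetricPair",
    "ComparisonReport",
    "split_dataset",
    "split_sizes",
    "r_squared",
    "mse",
    "relative_improvement",
    "run_comparison",
]


@dataclass(frozen=True)
class SplitRatios:
    train: float = 0.7
    val: float = 0.1
    test: float = 0.2

    def __post_init__(self):
        if min(self.train, self.val, self.test) <= 0:
            raise ValueError("split fractions must be positive")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class MetricPair:
    r_squared: float
    mse: float

    def __post_init__(self):
        if self.r_squared > 1 + 1e-12:
            raise ValueError("R² cannot exceed 1")
        if self.mse < 0:
            raise ValueError("MSE cannot be negative")


def split_sizes(n: int, ratios: SplitRatios = SplitRatios()) -> tuple[int, int, int]:
    """floor/floor/remainder partition sizes."""
    n_train = int(np.floor(n * ratios.train))
    n_val = int(np.floor(n * ratios.val))
    return n_train, n_val, n - n_train - n_val


def split_dataset(
    data: LabeledDataset,
    ratios: SplitRatios = SplitRatios(),
    seed: int = 0,
) -> LabeledDataset:
    """Tag every sample train/val/test by a seeded uniform shuffle."""
    n = data.n_samples
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    n_train, n_val, n_test = split_sizes(n, ratios)
    perm = np.random.default_rng(seed).permutation(n)
    tags = np.empty(n, dtype=object)
    tags[perm[:n_train]] = "train"
    tags[perm[n_train : n_train + n_val]] = "val"
    tags[perm[n_train + n_val :]] = "test"
    return LabeledDataset(
        spectra=data.spectra, ssc=data.ssc, firmness=data.firmness,
        split=tags.astype(str),
    )


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination; 1 is perfect, negative is sub-mean."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("inputs must be equal-length nonempty vectors")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² undefined: y_true is constant")
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    return 1.0 - ss_res / ss_tot


def mse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("inputs must be equal-length nonempty vectors")
    return float(np.mean((y_true - y_pred) ** 2))


def relative_improvement(candidate: float, reference: float) -> float:
    """Percent improvement of candidate over reference, one decimal."""
    if reference == 0:
        raise ValueError("reference score is zero")
    return round(100.0 * (candidate - reference) / reference, 1)


@dataclass
class ComparisonReport:
    """One row per (model, preprocessing, target) cell on the test split."""

    rows: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self) -> str:
        return json.dumps(
            {"metadata": self.metadata, "rows": self.rows}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        doc = json.loads(text)
        return cls(rows=doc["rows"], metadata=doc["metadata"])

    def cell(self, model: str, target: str, preprocessing: str | None = None):
        for row in self.rows:
            if row["model"] == model and row["target"] == target and (
                preprocessing is None or row["preprocessing"] == preprocessing
            ):
                return row
        raise KeyError((model, target, preprocessing))


def run_comparison(
    data: LabeledDataset,
    baselines: list[BaselineSpec] | None = None,
    preprocess_configs: list[PreprocessConfig] | None = None,
    targets: tuple[str, ...] = ("ssc", "firmness"),
    deep_spec: Con1dResNetSpec | None = None,
    train_config: TrainConfig | None = None,
    split_seed: int = 0,
    include_deep: bool = True,
) -> ComparisonReport:
    """Fit every requested cell on the train split, score on the test split.

    Per-cell failures are captured in the report (``error`` field) rather
    than aborting the whole run.
    """
    baselines = baselines if baselines is not None else [
        BaselineSpec(name) for name in ("svr", "knnr", "adaboost", "plsr")
    ]
    preprocess_configs = preprocess_configs or [
        PreprocessConfig(method="second_derivative"),
        PreprocessConfig(method="msc"),
    ]
    train_config = train_config or TrainConfig()
    if data.split is None:
        data = split_dataset(data, seed=split_seed)
    train, val, test = (data.split_part(t) for t in ("train", "val", "test"))

    report = ComparisonReport(
        metadata={
            "n_samples": data.n_samples,
            "split_sizes": {
                "train": train.n_samples,
                "val": val.n_samples,
                "test": test.n_samples,
            },
            "split_seed": split_seed,
            "train_config": asdict(train_config),
            "targets": list(targets),
            "msc_scope": {
                cfg.method: cfg.msc_scope for cfg in preprocess_configs
            },
        }
    )

    for target in targets:
        y_test = test.ssc if target == "ssc" else test.firmness
        # classical baselines on each pre-treatment
        for cfg in preprocess_configs:
            sets, _ = preprocess_pipeline(
                train.spectra, {"val": val.spectra, "test": test.spectra}, cfg
            )
            pre_train = LabeledDataset(
                sets["train"], train.ssc, train.firmness
            )
            for spec in baselines:
                row = {
                    "model": spec.name,
                    "preprocessing": cfg.method,
                    "target": target,
                }
                try:
                    handle = fit_baseline(spec, pre_train, target, cfg)
                    y_hat = predict(handle, sets["test"])
                    row["r_squared"] = r_squared(y_test, y_hat)
                    row["mse"] = mse(y_test, y_hat)
                except Exception as exc:  # captured per cell
                    row["error"] = f"{type(exc).__name__}: {exc}"
                report.rows.append(row)
        if include_deep:
            row = {
                "model": "con1dresnet",
                "preprocessing": "none",
                "target": target,
            }
            try:
                spec = deep_spec or Con1dResNetSpec(
                    input_length=data.spectra.grid.count
                )
                model = build_con1dresnet(spec)
                handle, history = train_model(
                    model, train, val, target, train_config
                )
                y_hat = predict(handle, test.spectra)
                row["r_squared"] = r_squared(y_test, y_hat)
                row["mse"] = mse(y_test, y_hat)
                row["final_train_loss"] = history.train_loss[-1]
            except Exception as exc:
                row["error"] = f"{type(exc).__name__}: {exc}"
            report.rows.append(row)
    return report
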