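"""Chemometric pre-treatments: multiplicative scatter correction and
second-order differentiation, with fit/apply separation.

MSC regresses every sample spectrum on an "ideal" (mean) spectrum by ordinary
least squares and removes the fitted baseline shift ``a`` and multiplicative
skew ``b``:

    x_i = a_i + b_i * m + e_i        (OLS fit per sample)
    x_i_corrected = (x_i - a_i) / b_i

so that samples differing only by scattering-induced affine distortion
collapse onto the ideal spectrum.

The second-order differential accentuates absorption-band inflection points.
The default scheme is the plain three-point second difference
``x[b-1] - 2 x[b] + x[b+1]`` on interior bands (output loses one channel at
each end); a Savitzky-Golay smoothed mode is available because raw
differences at ~1.3 nm resolution amplify noise.  Output is not rescaled by
1/dl^2 by default — every downstream model here is scale-invariant — but
physical scaling can be switched on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import savgol_filter

from .spectral_io import SpectrumSet, WavelengthGrid

__all__ = [
    "MSCReference",
    "MSCCoefficients",
    "PreprocessConfig",
    "FittedPreprocess",
    "fit_msc_reference",
    "apply_msc",
    "second_derivative",
    "preprocess_pipeline",
]

METHODS = ("none", "msc", "second_derivative", "msc_then_derivative")
DERIVATIVE_MODES = ("finite_difference", "smoothed")
MSC_SCOPES = ("train_only", "all_samples")


@dataclass
class MSCReference:
    """The per-band mean spectrum used as the scatter-correction ideal."""

    ideal_spectrum: np.ndarray

    def __post_init__(self):
        self.ideal_spectrum = np.asarray(self.ideal_spectrum, dtype=float)
        if not np.all(np.isfinite(self.ideal_spectrum)):
            raise ValueError("ideal spectrum contains non-finite values")
        if np.var(self.ideal_spectrum) == 0:
            raise ValueError(
                "degenerate MSC reference: ideal spectrum is constant"
            )


@dataclass
class MSCCoefficients:
    """Per-sample baseline shift (intercept) and skew (slope)."""

    shift: np.ndarray
    skew: np.ndarray


@dataclass
class PreprocessConfig:
    method: str = "none"
    derivative_mode: str = "finite_difference"
    window: int = 11
    polyorder: int = 3
    msc_scope: str = "all_samples"
    scale_by_spacing: bool = False
    slope_tol: float = 1e-8

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.derivative_mode not in DERIVATIVE_MODES:
            raise ValueError(f"unknown derivative mode {self.derivative_mode!r}")
        if self.msc_scope not in MSC_SCOPES:
            raise ValueError(f"unknown msc scope {self.msc_scope!r}")
        if self.derivative_mode == "smoothed":
            if self.window % 2 == 0 or self.window <= self.polyorder:
                raise ValueError(
                    "smoothing window must be odd and exceed the polynomial "
                    f"order (window={self.window}, polyorder={self.polyorder})"
                )


def fit_msc_reference(spectra: SpectrumSet) -> MSCReference:
    """Average all samples into the ideal spectrum."""
    if spectra.n_samples < 2:
        raise ValueError("MSC reference needs at least 2 samples")
    return MSCReference(spectra.spectra.mean(axis=0))


def apply_msc(
    spectra: SpectrumSet, ref: MSCReference, slope_tol: float = 1e-8
) -> tuple[SpectrumSet, MSCCoefficients]:
    """Regress each sample on the ideal spectrum and undo shift and skew."""
    m = ref.ideal_spectrum
    if m.size != spectra.grid.count:
        raise ValueError("reference grid does not match spectra grid")
    x = spectra.spectra
    m_c = m - m.mean()
    var_m = np.dot(m_c, m_c) / m.size
    # closed-form per-sample OLS: b = cov(x, m)/var(m), a = mean(x) - b*mean(m)
    skew = (x - x.mean(axis=1, keepdims=True)) @ m_c / m.size / var_m
    flat = np.nonzero(np.abs(skew) < slope_tol)[0]
    if flat.size:
        sid = spectra.sample_ids[int(flat[0])]
        raise ValueError(
            f"flat sample {sid!r}: regression slope {skew[int(flat[0])]:.3g} "
            f"below tolerance {slope_tol}"
        )
    shift = x.mean(axis=1) - skew * m.mean()
    corrected = (x - shift[:, None]) / skew[:, None]
    return (
        SpectrumSet(corrected, spectra.grid, list(spectra.sample_ids)),
        MSCCoefficients(shift=shift, skew=skew),
    )


def _interior_grid(grid: WavelengthGrid) -> WavelengthGrid:
    return WavelengthGrid(grid.values[1:-1])


def second_derivative(
    spectra: SpectrumSet, config: PreprocessConfig | None = None
) -> SpectrumSet:
    """Discrete second derivative along the wavelength axis.

    Both modes trim one channel at each end so the output lives on the
    interior grid (count - 2 channels).
    """
    config = config or PreprocessConfig(method="second_derivative")
    x = spectra.spectra
    n_bands = x.shape[1]
    if n_bands < 3:
        raise ValueError("second derivative needs at least 3 bands")
    if config.derivative_mode == "finite_difference":
        out = x[:, :-2] - 2.0 * x[:, 1:-1] + x[:, 2:]
    else:
        if config.window > n_bands:
            raise ValueError(
                f"smoothing window {config.window} exceeds band count {n_bands}"
            )
        out = savgol_filter(
            x, config.window, config.polyorder, deriv=2, delta=1.0, axis=1
        )[:, 1:-1]
    if config.scale_by_spacing:
        dl = np.diff(spectra.grid.values).mean()
        out = out / dl**2
    return SpectrumSet(out, _interior_grid(spectra.grid), list(spectra.sample_ids))


@dataclass
class FittedPreprocess:
    """Serializable fitted preprocessing state (reference + config echo)."""

    config: PreprocessConfig
    reference: MSCReference | None = None

    def apply(self, spectra: SpectrumSet) -> SpectrumSet:
        out = spectra
        if self.config.method in ("msc", "msc_then_derivative"):
            if self.reference is None:
                raise ValueError("MSC selected but no fitted reference")
            out, _ = apply_msc(out, self.reference, self.config.slope_tol)
        if self.config.method in ("second_derivative", "msc_then_derivative"):
            out = second_derivative(out, self.config)
        return out

    def to_json(self) -> str:
        doc = {"config": asdict(self.config)}
        if self.reference is not None:
            doc["reference"] = self.reference.ideal_spectrum.tolist()
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "FittedPreprocess":
        doc = json.loads(text)
        ref = (
            MSCReference(np.asarray(doc["reference"]))
            if "reference" in doc
            else None
        )
        return cls(config=PreprocessConfig(**doc["config"]), reference=ref)


def preprocess_pipeline(
    train: SpectrumSet,
    others: dict[str, SpectrumSet] | None = None,
    config: PreprocessConfig | None = None,
) -> tuple[dict[str, SpectrumSet], FittedPreprocess]:
    """Fit the configured treatment and apply it to every split.

    The MSC reference is fitted from the training split alone
    (``msc_scope='train_only'``) or from all splits pooled
    (``'all_samples'``, the default — the ideal spectrum is the average of
    *all* spectra).  The derivative, when combined, follows MSC.
    """
    others = others or {}
    config = config or PreprocessConfig()
    fitted = FittedPreprocess(config=config)
    if config.method in ("msc", "msc_then_derivative"):
        if config.msc_scope == "train_only" or not others:
            pool = train
        else:
            all_sets = [train] + list(others.values())
            ids = []
            for i, s in enumerate(all_sets):
                ids += [f"{i}:{sid}" for sid in s.sample_ids]
            pool = SpectrumSet(
                np.vstack([s.spectra for s in all_sets]), train.grid, ids
            )
        fitted.reference = fit_msc_reference(pool)
    out = {"train": fitted.apply(train)}
    for name, s in others.items():
        out[name] = fitted.apply(s)
    return out, fitted
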