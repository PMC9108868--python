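"""Synthetic cherry-tomato reflectance spectra with known SSC/firmness signal.

The generator emulates the structure a VNIR (386-1,004 nm) push-broom camera
sees on ripe cherry tomato: a sigmoidal continuum rising from strong
carotenoid/chlorophyll absorption below ~550 nm toward a high NIR plateau,
multiplied by Beer-Lambert-style Gaussian absorption bands whose depths carry
the chemistry.  Second-derivative spectra of the clean signal show extrema in
the 580-590, 680-690 and 970-980 nm windows (pigment edge, chlorophyll-a
tail, and the water/sugar OH second overtone).

Soluble solids content (SSC, °Brix) loads mainly on the 580-590 and 970-980
nm band depths; firmness (N/cm^2) loads on the 680-690 nm band and on a
continuum tilt.  Firmness is deliberately the weaker, more diffuse signal so
that it is harder to regress than SSC, as is observed on real fruit.

Measured spectra add per-sample multiplicative scatter (gain), an additive
baseline offset, smooth broadband interference and i.i.d. per-band sensor
noise:

    observed = gain * clean(lambda) + offset + drift(lambda) + noise(lambda)

Label distributions are truncated normals matched to a 200-fruit field
sample: SSC ~ N(8.719, 0.662^2) on [7.2, 11.1] °Brix, firmness
~ N(8.853, 1.229^2) on [5.978, 12.936] N/cm^2.

One global seed drives labels, scatter, noise and interference through
independent spawned sub-streams, so the same seed always reproduces the
same dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectral_io import SpectrumSet, WavelengthGrid

__all__ = [
    "AbsorptionBand",
    "GeneratorParams",
    "LabeledDataset",
    "default_params",
    "generate_dataset",
    "scatter_replicates",
]


@dataclass(frozen=True)
class AbsorptionBand:
    """Gaussian absorption band: depth = base + loadings on z-scored labels."""

    center_nm: float
    width_nm: float
    base_depth: float
    ssc_loading: float = 0.0
    firmness_loading: float = 0.0

    def __post_init__(self):
        if self.width_nm <= 0:
            raise ValueError("band width must be positive")


@dataclass
class GeneratorParams:
    n_samples: int = 200
    seed: int = 0
    grid_range_nm: tuple[float, float] = (386.0, 1004.0)
    n_channels: int = 462
    # sigmoidal continuum rising with wavelength
    continuum_midpoint_nm: float = 560.0
    continuum_steepness: float = 0.035  # 1/nm
    continuum_low: float = 0.12
    continuum_high: float = 0.82
    continuum_firmness_tilt: float = 0.04  # fractional tilt per firmness SD
    bands: tuple[AbsorptionBand, ...] = ()
    gain_mean: float = 1.0
    gain_sd: float = 0.08
    offset_sd: float = 0.01
    noise_sd: float = 0.002
    # smooth broadband interference ("unwanted reflectance"): per-sample
    # random low-order Legendre baseline wiggles that a single gain/offset
    # correction cannot remove.  They swamp naive all-band distances while
    # leaving local absorption-band contrasts intact.
    drift_sd: float = 0.05
    drift_orders: int = 4
    ssc_mean: float = 8.719
    ssc_sd: float = 0.662
    ssc_bounds: tuple[float, float] = (7.2, 11.1)
    firmness_mean: float = 8.853
    firmness_sd: float = 1.229
    firmness_bounds: tuple[float, float] = (5.978, 12.936)

    def __post_init__(self):
        if self.n_channels < 3:
            raise ValueError("need at least 3 channels")
        if self.gain_sd >= self.gain_mean:
            raise ValueError("gain SD must be below gain mean")
        if self.ssc_sd <= 0 or self.firmness_sd <= 0:
            raise ValueError("label SDs must be positive")

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid.uniform(*self.grid_range_nm, self.n_channels)


@dataclass
class LabeledDataset:
    """Spectra plus per-sample SSC (°Brix) and firmness (N/cm^2) labels."""

    spectra: SpectrumSet
    ssc: np.ndarray
    firmness: np.ndarray
    split: np.ndarray | None = None  # per-sample {train, val, test} tags

    def __post_init__(self):
        self.ssc = np.asarray(self.ssc, dtype=float)
        self.firmness = np.asarray(self.firmness, dtype=float)
        n = self.spectra.n_samples
        if self.ssc.size != n or self.firmness.size != n:
            raise ValueError("label vectors must match the sample count")
        if not (np.all(np.isfinite(self.ssc)) and np.all(np.isfinite(self.firmness))):
            raise ValueError("labels must be finite")
        if self.split is not None:
            self.split = np.asarray(self.split)
            if self.split.size != n:
                raise ValueError("split tags must match the sample count")

    @property
    def n_samples(self) -> int:
        return self.spectra.n_samples

    def subset(self, index: np.ndarray) -> "LabeledDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.nonzero(index)[0]
        return LabeledDataset(
            spectra=SpectrumSet(
                self.spectra.spectra[index],
                self.spectra.grid,
                [self.spectra.sample_ids[i] for i in index],
            ),
            ssc=self.ssc[index],
            firmness=self.firmness[index],
            split=None if self.split is None else self.split[index],
        )

    def split_part(self, tag: str) -> "LabeledDataset":
        if self.split is None:
            raise ValueError("dataset carries no split tags")
        return self.subset(self.split == tag)


def default_params(n_samples: int = 200, seed: int = 0) -> GeneratorParams:
    """Default tomato-like generator: 462 channels over 386-1,004 nm.

    The band table holds the broad 400-550 nm pigment absorption plus the
    three windows where real second-derivative tomato spectra show peaks.
    """
    bands = (
        # broad carotenoid/chlorophyll absorption over 400-550 nm
        AbsorptionBand(475.0, 60.0, base_depth=1.1, ssc_loading=0.0,
                       firmness_loading=0.05),
        # pigment edge feature; SSC-linked
        AbsorptionBand(585.0, 7.0, base_depth=0.30, ssc_loading=0.10),
        # chlorophyll-a tail; firmness-linked (maturity)
        AbsorptionBand(685.0, 7.0, base_depth=0.25, firmness_loading=0.05),
        # OH second overtone (water/sugar); SSC-linked
        AbsorptionBand(975.0, 9.0, base_depth=0.35, ssc_loading=0.12),
    )
    return GeneratorParams(n_samples=n_samples, seed=seed, bands=bands)


def _continuum(params: GeneratorParams, wl: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-params.continuum_steepness
                            * (wl - params.continuum_midpoint_nm)))
    return params.continuum_low + (params.continuum_high - params.continuum_low) * s


def clean_spectrum(
    params: GeneratorParams, ssc: float, firmness: float
) -> np.ndarray:
    """Noise-free reflectance for one sample given its labels."""
    wl = params.grid.values
    z_ssc = (ssc - params.ssc_mean) / params.ssc_sd
    z_firm = (firmness - params.firmness_mean) / params.firmness_sd
    lo, hi = params.grid_range_nm
    tilt = 1.0 + params.continuum_firmness_tilt * z_firm \
        * (wl - 0.5 * (lo + hi)) / (hi - lo)
    absorbance = np.zeros_like(wl)
    for band in params.bands:
        depth = max(
            band.base_depth + band.ssc_loading * z_ssc
            + band.firmness_loading * z_firm,
            0.0,
        )
        absorbance += depth * np.exp(
            -0.5 * ((wl - band.center_nm) / band.width_nm) ** 2
        )
    return _continuum(params, wl) * tilt * np.exp(-absorbance)


def _truncnorm(mean, sd, bounds, n, rng):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=rng)


def generate_dataset(params: GeneratorParams) -> LabeledDataset:
    """Draw labels, synthesise clean spectra, apply scatter and noise."""
    if not params.bands:
        raise ValueError("generator needs at least one absorption band")
    label_rng, scatter_rng, noise_rng, drift_rng = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(params.seed).spawn(4)
    )
    n = params.n_samples
    if n <= 0:
        raise ValueError("n_samples must be positive")
    ssc = _truncnorm(params.ssc_mean, params.ssc_sd, params.ssc_bounds, n,
                     label_rng)
    firmness = _truncnorm(params.firmness_mean, params.firmness_sd,
                          params.firmness_bounds, n, label_rng)

    any_depth = False
    clean = np.empty((n, params.n_channels))
    for i in range(n):
        clean[i] = clean_spectrum(params, ssc[i], firmness[i])
    for band in params.bands:
        z_ssc = (ssc - params.ssc_mean) / params.ssc_sd
        z_firm = (firmness - params.firmness_mean) / params.firmness_sd
        depths = (band.base_depth + band.ssc_loading * z_ssc
                  + band.firmness_loading * z_firm)
        if np.any(depths > 0):
            any_depth = True
    if not any_depth:
        import warnings

        warnings.warn("degenerate signal: all band depths are zero",
                      stacklevel=2)

    gain = scatter_rng.normal(params.gain_mean, params.gain_sd, size=n)
    offset = scatter_rng.normal(0.0, params.offset_sd, size=n)
    noise = noise_rng.normal(0.0, params.noise_sd,
                             size=(n, params.n_channels))
    drift = np.zeros((n, params.n_channels))
    if params.drift_sd > 0 and params.drift_orders > 0:
        t = np.linspace(-1.0, 1.0, params.n_channels)
        basis = np.polynomial.legendre.legvander(t, params.drift_orders)[:, 1:]
        weights = 1.0 / np.arange(1, params.drift_orders + 1)
        coeffs = drift_rng.normal(
            0.0, params.drift_sd, size=(n, params.drift_orders)
        ) * weights
        drift = coeffs @ basis.T
    observed = gain[:, None] * clean + offset[:, None] + drift + noise
    ids = [f"s{i:04d}" for i in range(n)]
    return LabeledDataset(
        spectra=SpectrumSet(observed, params.grid, ids),
        ssc=ssc,
        firmness=firmness,
    )


def mean_clean_spectrum(params: GeneratorParams) -> np.ndarray:
    """Clean spectrum at the label means (noise- and scatter-free)."""
    return clean_spectrum(params, params.ssc_mean, params.firmness_mean)


def scatter_replicates(
    base: np.ndarray,
    grid: WavelengthGrid,
    k: int,
    gain_mean: float = 1.0,
    gain_sd: float = 0.08,
    offset_sd: float = 0.01,
    seed: int = 0,
) -> tuple[SpectrumSet, np.ndarray, np.ndarray]:
    """k affine-distorted copies of one spectrum (no band noise).

    Returns the replicate set together with the sampled per-replicate gains
    and offsets, for checking that scatter correction recovers them.
    """
    if k < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    gain = rng.normal(gain_mean, gain_sd, size=k)
    offset = rng.normal(0.0, offset_sd, size=k)
    spectra = gain[:, None] * np.asarray(base, dtype=float) + offset[:, None]
    ids = [f"rep{i:03d}" for i in range(k)]
    return SpectrumSet(spectra, grid, ids), gain, offset
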