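"""Hyperspectral cube I/O, reflectance calibration and ROI spectrum extraction.

This module handles the plumbing between a push-broom hyperspectral camera's
output (an ENVI header + band-interleaved binary cube, plus white/dark
reference captures) and the per-sample 1-D spectra that the chemometric and
learning stages consume.

Reflectance calibration follows the standard two-point correction

    R_c = (R_ori - R_dark) / (R_white - R_dark)

where the white reference is a ~100 %-reflectance standard (e.g. a Teflon
tile) and the dark reference is captured with the lens capped.  Values are
deliberately *not* clipped to [0, 1]: downstream scatter correction tolerates
slight out-of-range values and clipping would bias band means.

Because the surface of a glossy fruit produces a specular highlight, ROI
selection excludes the brightest pixels (a configurable top percentile of the
broadband mean image) as well as dark background pixels below a floor
threshold, and the remaining pixels are averaged into one spectrum per fruit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "HyperspectralCube",
    "ReferenceCaptures",
    "ROIMask",
    "SpectrumSet",
    "EnviFormatError",
    "CalibrationError",
    "EmptyROIError",
    "SpectraTableError",
    "read_envi_cube",
    "write_envi_cube",
    "calibrate_reflectance",
    "extract_roi_mask",
    "mean_spectrum",
    "read_spectra_table",
    "write_spectra_table",
]

DEFAULT_RANGE_NM = (386.0, 1004.0)
DEFAULT_N_CHANNELS = 462


class EnviFormatError(ValueError):
    """Malformed or unsupported ENVI header/binary pair."""


class CalibrationError(ValueError):
    """Degenerate reference captures (white == dark at some band)."""


class EmptyROIError(ValueError):
    """ROI parameters excluded every pixel."""


class SpectraTableError(ValueError):
    """Malformed delimited spectra table."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 3:
            raise ValueError("wavelength grid needs at least 3 channels")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def count(self) -> int:
        return int(self.values.size)

    @classmethod
    def uniform(cls, lo: float, hi: float, n: int) -> "WavelengthGrid":
        return cls(np.linspace(lo, hi, n))

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """462 channels spanning 386-1,004 nm (VNIR push-broom camera)."""
        return cls.uniform(*DEFAULT_RANGE_NM, DEFAULT_N_CHANNELS)

    def __eq__(self, other):
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.values, other.values
        )


@dataclass
class HyperspectralCube:
    """3-D intensity or reflectance array (rows x cols x bands) on a grid."""

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"  # {"raw", "reflectance"}

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, bands)")
        if self.data.shape[2] != self.grid.count:
            raise ValueError(
                f"band dimension {self.data.shape[2]} does not match "
                f"grid with {self.grid.count} channels"
            )
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.data)):
            raise ValueError("reflectance cube contains non-finite values")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ReferenceCaptures:
    """White (100 %-standard) and dark (lens-capped) reference intensities.

    Each may be a per-band vector (averaged reference image, the default
    contract) or a full image matching the cube's spatial shape.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self):
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)


@dataclass
class ROIMask:
    """Boolean pixel mask plus the parameters that produced it."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise EmptyROIError("ROI mask has no selected pixels")


@dataclass
class SpectrumSet:
    """Matrix of per-sample spectra (samples x bands) on a shared grid."""

    spectra: np.ndarray
    grid: WavelengthGrid
    sample_ids: list[str]

    def __post_init__(self):
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.spectra.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match number of sample ids")
        if self.spectra.shape[1] != self.grid.count:
            raise ValueError(
                f"column count {self.spectra.shape[1]} does not match "
                f"grid with {self.grid.count} channels"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]


# ---------------------------------------------------------------------------
# ENVI cube I/O
# ---------------------------------------------------------------------------

# ENVI numeric data-type codes we accept: 12 = uint16, 4 = float32.
_ENVI_DTYPES = {4: np.dtype("float32"), 12: np.dtype("uint16")}
_ENVI_CODES = {v: k for k, v in _ENVI_DTYPES.items()}
_INTERLEAVES = ("bil", "bip", "bsq")


def _parse_envi_header(text: str) -> dict:
    """Parse key = value pairs; braces may span lines (wavelength lists)."""
    body = re.sub(r"^ENVI\s*", "", text.strip(), flags=re.IGNORECASE)
    fields: dict[str, str] = {}
    # join brace-delimited values onto one line before splitting
    buf = []
    depth = 0
    for ch in body:
        if ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
        if ch == "\n" and depth > 0:
            buf.append(" ")
        else:
            buf.append(ch)
    for line in "".join(buf).splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi_cube(header_path: str | Path) -> HyperspectralCube:
    """Read an ENVI header + raw binary companion into a raw cube.

    Supports BIL/BIP/BSQ interleaves, uint16 and float32 samples, and both
    byte orders.  Wavelengths from the header win; absent a wavelength list,
    a uniform default grid is synthesised over 386-1,004 nm.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_envi_header(header_path.read_text())

    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in fields:
            raise EnviFormatError(f"ENVI header missing required field {key!r}")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(
            f"unsupported interleave {fields['interleave']!r}; "
            f"expected one of {_INTERLEAVES}"
        )
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise EnviFormatError(
            f"unsupported data type {code!r}; supported codes: "
            f"{sorted(_ENVI_DTYPES)} (uint16, float32)"
        )
    dtype = _ENVI_DTYPES[code]
    byte_order = int(fields.get("byte order", 0))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    binary = _companion_path(header_path)
    if binary is None:
        raise EnviFormatError(
            f"missing binary companion file for header {header_path.name}"
        )
    raw = np.fromfile(binary, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"binary file holds {raw.size} values but header declares "
            f"interleave={interleave} with {expected} "
            f"(samples={samples} x lines={lines} x bands={bands})"
        )
    if interleave == "bil":  # (lines, bands, samples)
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":  # (lines, samples, bands)
        cube = raw.reshape(lines, samples, bands)
    else:  # bsq: (bands, lines, samples)
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)

    if "wavelength" in fields:
        wl_text = fields["wavelength"].strip().strip("{}")
        wl = np.array([float(w) for w in wl_text.split(",") if w.strip()])
        if wl.size != bands:
            raise EnviFormatError(
                f"wavelength list has {wl.size} entries for bands={bands}"
            )
        grid = WavelengthGrid(wl)
    else:
        grid = WavelengthGrid.uniform(*DEFAULT_RANGE_NM, bands)

    return HyperspectralCube(
        cube.astype(np.float64), grid=grid, kind="raw"
    )


def _companion_path(header_path: Path) -> Path | None:
    stem = header_path.with_suffix("")
    for cand in (stem, stem.with_suffix(".img"), stem.with_suffix(".dat"),
                 stem.with_suffix(".raw"), stem.with_suffix(".bil"),
                 stem.with_suffix(".bip"), stem.with_suffix(".bsq")):
        if cand.exists() and cand != header_path:
            return cand
    return None


def write_envi_cube(
    header_path: str | Path,
    cube: HyperspectralCube,
    interleave: str = "bil",
    dtype: str = "float32",
    byte_order: int = 0,
) -> None:
    """Write a cube as an ENVI header + binary pair (test/CLI fixture aid)."""
    header_path = Path(header_path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    np_dtype = np.dtype(dtype).newbyteorder("<" if byte_order == 0 else ">")
    if np_dtype.newbyteorder("=") not in _ENVI_CODES:
        raise EnviFormatError(f"unsupported data type {dtype!r}")
    lines, samples, bands = cube.shape
    data = cube.data
    if interleave == "bil":
        arr = data.transpose(0, 2, 1)
    elif interleave == "bip":
        arr = data
    else:
        arr = data.transpose(2, 0, 1)
    binary = header_path.with_suffix(".img")
    arr.astype(np_dtype).tofile(binary)
    wl = ", ".join(f"{w:.6g}" for w in cube.grid.values)
    header_path.write_text(
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        f"interleave = {interleave}\n"
        f"data type = {_ENVI_CODES[np_dtype.newbyteorder('=')]}\n"
        f"byte order = {byte_order}\n"
        f"wavelength = {{ {wl} }}\n"
    )


# ---------------------------------------------------------------------------
# Calibration and ROI extraction
# ---------------------------------------------------------------------------


def calibrate_reflectance(
    raw: HyperspectralCube, refs: ReferenceCaptures
) -> HyperspectralCube:
    """Two-point reflectance correction (raw - dark) / (white - dark)."""
    if raw.kind != "raw":
        raise ValueError("cube is already calibrated (kind != 'raw')")
    white = np.broadcast_to(refs.white, raw.shape) if refs.white.ndim == 1 \
        else refs.white
    dark = np.broadcast_to(refs.dark, raw.shape) if refs.dark.ndim == 1 \
        else refs.dark
    if white.shape != raw.shape or dark.shape != raw.shape:
        raise ValueError("reference captures do not align with the cube grid")
    denom = white - dark
    bad = np.nonzero(np.any(denom == 0, axis=(0, 1)))[0]
    if bad.size:
        raise CalibrationError(
            f"white equals dark at band index {int(bad[0])} "
            f"({raw.grid.values[int(bad[0])]:.1f} nm); cannot divide"
        )
    refl = (raw.data - dark) / denom
    return HyperspectralCube(refl, grid=raw.grid, kind="reflectance")


def extract_roi_mask(
    cube: HyperspectralCube,
    highlight_percentile: float = 0.05,
    background_threshold: float = 0.05,
) -> ROIMask:
    """Deterministic two-threshold fruit-surface mask.

    Excludes (a) specular-highlight pixels, i.e. those whose broadband mean
    reflectance lies strictly above the (1 - highlight_percentile) lower
    quantile of all pixel means, and (b) background pixels whose mean falls
    below ``background_threshold``.
    """
    if cube.kind != "reflectance":
        raise ValueError("ROI extraction expects a reflectance cube")
    if not 0 <= highlight_percentile < 1:
        raise ValueError("highlight_percentile must be in [0, 1)")
    means = cube.data.mean(axis=2)
    keep = means >= background_threshold
    if highlight_percentile > 0:
        cutoff = np.quantile(means, 1.0 - highlight_percentile, method="lower")
        keep &= means <= cutoff
    if not keep.any():
        raise EmptyROIError(
            "ROI empty: no pixel survives highlight_percentile="
            f"{highlight_percentile} and background_threshold="
            f"{background_threshold}"
        )
    return ROIMask(
        mask=keep,
        provenance={
            "highlight_percentile": highlight_percentile,
            "background_threshold": background_threshold,
        },
    )


def mean_spectrum(cube: HyperspectralCube, mask: ROIMask) -> np.ndarray:
    """Per-band arithmetic mean over the masked pixels."""
    if mask.mask.shape != cube.shape[:2]:
        raise ValueError("mask spatial shape does not match cube")
    return cube.data[mask.mask].mean(axis=0)


# ---------------------------------------------------------------------------
# Delimited spectra tables
# ---------------------------------------------------------------------------

_LABEL_COLUMNS = ("ssc", "firmness")


def write_spectra_table(
    path: str | Path,
    spectra: SpectrumSet,
    ssc: np.ndarray | None = None,
    firmness: np.ndarray | None = None,
    float_format: str = "%.17g",
) -> None:
    """Write samples x wavelengths CSV with optional ssc/firmness columns."""
    cols = [f"{w:.6g}" for w in spectra.grid.values]
    df = pd.DataFrame(spectra.spectra, columns=cols)
    df.insert(0, "sample_id", spectra.sample_ids)
    for name, vals in (("ssc", ssc), ("firmness", firmness)):
        if vals is not None:
            if len(vals) != spectra.n_samples:
                raise ValueError(f"{name} labels do not match sample count")
            df[name] = np.asarray(vals, dtype=float)
    df.to_csv(path, index=False, float_format=float_format)


def read_spectra_table(path: str | Path) -> tuple[SpectrumSet, dict]:
    """Read a spectra table; returns the set and any label columns found."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(",")
        if not header or header[0] != "sample_id":
            raise SpectraTableError("first header cell must be 'sample_id'")
        n_cols = len(header)
        label_names = []
        while header and header[-1].strip().lower() in _LABEL_COLUMNS:
            label_names.insert(0, header.pop().strip().lower())
        try:
            wl = np.array([float(w) for w in header[1:]])
        except ValueError as exc:
            raise SpectraTableError(f"non-numeric wavelength header: {exc}")
        if wl.size < 3 or not np.all(np.diff(wl) > 0):
            raise SpectraTableError("wavelength header not strictly increasing")
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(",")
            if len(parts) != n_cols:
                raise SpectraTableError(
                    f"ragged row at line {lineno}: {len(parts)} fields, "
                    f"expected {n_cols}"
                )
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    values = np.asarray(rows, dtype=float)
    labels = {}
    for i, name in enumerate(label_names):
        labels[name] = values[:, values.shape[1] - len(label_names) + i]
    if label_names:
        values = values[:, : values.shape[1] - len(label_names)]
    return SpectrumSet(values, WavelengthGrid(wl), ids), labels
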