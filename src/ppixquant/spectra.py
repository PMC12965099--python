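"""Wavelength-grid data model, spectra table I/O, and emission pre-processing.

Fluorescence emission scans are acquired as photon counts on a uniform
wavelength grid (by default 450-800 nm with a 1 nm step, i.e. 351 samples).
This module provides the shared containers used throughout the package:

* :class:`WavelengthGrid` -- a strictly increasing, uniformly spaced grid;
* :class:`SpectraMatrix` -- ``n`` samples x ``m`` wavelengths of non-negative
  intensities (the matrix ``V`` consumed by the unmixing);
* :class:`ReflectanceRecord` -- a per-sample diffuse (or total) reflectance
  spectrum with values in ``[0, 1]``;
* :class:`AcquisitionMeta` -- exposure metadata used to normalise raw counts.

Tables are plain delimited text.  Two dialects are accepted: wavelengths as
the header row (one row per sample, first column the sample id) or
wavelengths as the first column (one column per sample).  The dialect is
auto-detected and can be forced.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraMatrix",
    "ReflectanceRecord",
    "AcquisitionMeta",
    "SpectraFormatError",
    "load_spectra",
    "write_spectra",
    "reflectance_records",
    "load_concentrations",
    "write_concentrations",
    "preprocess_emission",
    "resample_linear",
]

DEFAULT_START = 450.0
DEFAULT_STOP = 800.0
DEFAULT_STEP = 1.0

#: relative tolerance used when checking grid uniformity
_GRID_RTOL = 1e-6


class SpectraFormatError(ValueError):
    """Raised for malformed spectra tables (bad grid, negative counts, ...)."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing, uniformly spaced wavelength grid in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise SpectraFormatError("wavelength grid needs at least two points")
        diffs = np.diff(vals)
        if np.any(diffs <= 0):
            bad = vals[1:][diffs <= 0]
            raise SpectraFormatError(
                f"wavelengths not strictly increasing at {bad[:5].tolist()}"
            )
        step = diffs[0]
        off = np.abs(diffs - step) > _GRID_RTOL * max(step, 1.0)
        if np.any(off):
            bad = vals[1:][off]
            raise SpectraFormatError(
                f"non-uniform wavelength spacing near {bad[:5].tolist()} "
                f"(expected step {step:g} nm)"
            )
        object.__setattr__(self, "values", vals)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """The 450-800 nm, 1 nm acquisition grid (351 points)."""
        return cls.from_range(DEFAULT_START, DEFAULT_STOP, DEFAULT_STEP)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "WavelengthGrid":
        """Inclusive-of-both-endpoints uniform grid."""
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    @property
    def start(self) -> float:
        return float(self.values[0])

    @property
    def stop(self) -> float:
        return float(self.values[-1])

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values, rtol=0, atol=1e-9)
        )

    __hash__ = None  # type: ignore[assignment]

    def index_of(self, wavelength: float) -> int:
        """Index of the grid node closest to ``wavelength``."""
        return int(np.argmin(np.abs(self.values - wavelength)))

    def contains(self, wavelength: float) -> bool:
        return self.start <= wavelength <= self.stop


@dataclass
class SpectraMatrix:
    """``n`` emission spectra on a shared grid; the non-negative matrix V."""

    grid: WavelengthGrid
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        if vals.shape[1] != len(self.grid):
            raise SpectraFormatError(
                f"{vals.shape[1]} intensity columns but grid has {len(self.grid)} points"
            )
        if np.any(~np.isfinite(vals)):
            raise SpectraFormatError("non-finite intensity values")
        if np.any(vals < 0):
            raise SpectraFormatError("negative intensity values")
        self.values = vals
        if not self.sample_ids:
            self.sample_ids = [f"s{i:03d}" for i in range(vals.shape[0])]
        elif len(self.sample_ids) != vals.shape[0]:
            raise SpectraFormatError("sample_ids length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "SpectraMatrix":
        return SpectraMatrix(self.grid, np.asarray(values, float), list(self.sample_ids))


@dataclass
class ReflectanceRecord:
    """Diffuse (or total) reflectance fraction per wavelength, in [0, 1]."""

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "diffuse"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        if vals.size != len(self.grid):
            raise SpectraFormatError("reflectance length does not match grid")
        if np.any(vals < 0) or np.any(vals > 1):
            raise SpectraFormatError("reflectance values outside [0, 1]")
        if self.kind not in ("total", "diffuse"):
            raise ValueError(f"unknown reflectance kind {self.kind!r}")
        self.values = vals

    def resampled(self, target: WavelengthGrid, extrapolate: bool = False) -> "ReflectanceRecord":
        vals = resample_linear(self.values, self.grid, target, extrapolate=extrapolate)
        return ReflectanceRecord(target, np.clip(vals, 0.0, 1.0), self.kind)


@dataclass
class AcquisitionMeta:
    """Exposure metadata: dwell time (s), scan repeats, filter transmission."""

    dwell_time: float = 0.2
    scan_repeats: int = 1
    filter_transmission: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        if self.scan_repeats < 1:
            raise ValueError("scan_repeats must be >= 1")
        t = np.asarray(self.filter_transmission, dtype=float)
        if np.any(t <= 0) or np.any(t > 1):
            raise ValueError("filter transmission must lie in (0, 1]")


# ---------------------------------------------------------------------------
# table I/O


def _detect_dialect(df: pd.DataFrame) -> str:
    header = list(df.columns)
    if len(header) < 2:
        raise SpectraFormatError("table needs at least two columns")
    try:
        [float(h) for h in header[1:]]
        return "row"
    except (TypeError, ValueError):
        return "column"


def load_spectra(path, dialect: str = "auto", sep: str = ",") -> SpectraMatrix:
    """Read a delimited spectra table.

    ``dialect='row'``: wavelengths in the header, one row per sample, first
    column the sample id.  ``dialect='column'``: wavelengths in the first
    column, one column per sample.  ``'auto'`` sniffs the header.
    """
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise SpectraFormatError(f"no samples in {path}") from None
    if df.empty:
        raise SpectraFormatError(f"no samples in {path}")
    if dialect == "auto":
        dialect = _detect_dialect(df)
    if dialect == "column":
        df = df.set_index(df.columns[0]).T.reset_index()
        df = df.rename(columns={"index": "sample_id"})
    elif dialect != "row":
        raise ValueError(f"unknown dialect {dialect!r}")
    ids = [str(v) for v in df.iloc[:, 0]]
    try:
        grid_vals = np.array([float(c) for c in df.columns[1:]])
    except (TypeError, ValueError) as exc:
        raise SpectraFormatError(f"non-numeric wavelength header in {path}: {exc}") from None
    body = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = body.columns[body.isna().any()][:5].tolist()
        raise SpectraFormatError(f"non-numeric intensity cells in columns {bad}")
    return SpectraMatrix(WavelengthGrid(grid_vals), body.to_numpy(float), ids)


def write_spectra(spectra: SpectraMatrix, path, dialect: str = "row", sep: str = ",") -> None:
    """Write a spectra table; round-trips through :func:`load_spectra`."""
    cols = [f"{w:.10g}" for w in spectra.grid.values]
    df = pd.DataFrame(spectra.values, columns=cols)
    df.insert(0, "sample_id", spectra.sample_ids)
    if dialect == "column":
        df = df.set_index("sample_id").T
        df.index.name = "wavelength"
        df.to_csv(path, sep=sep, float_format="%.12g")
    elif dialect == "row":
        df.to_csv(path, sep=sep, index=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def reflectance_records(spectra: SpectraMatrix, kind: str = "diffuse") -> list[ReflectanceRecord]:
    """View each row of a spectra table as a per-sample reflectance record."""
    return [ReflectanceRecord(spectra.grid, row, kind) for row in spectra.values]


def load_concentrations(path, sep: str = ",") -> pd.Series:
    """Read a two-column (sample_id, concentration) ground-truth table."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise SpectraFormatError("concentration table needs sample_id and value columns")
    s = pd.Series(pd.to_numeric(df.iloc[:, 1]).to_numpy(float),
                  index=[str(v) for v in df.iloc[:, 0]])
    s.index.name = "sample_id"
    return s


def write_concentrations(y: pd.Series, path, name: str = "ppix_ug_ml", sep: str = ",") -> None:
    df = pd.DataFrame({"sample_id": y.index, name: y.to_numpy(float)})
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# processing


def preprocess_emission(raw: SpectraMatrix, meta: AcquisitionMeta) -> SpectraMatrix:
    """Normalise raw counts for exposure and emission-filter transmission.

    Output units are counts/s:
    ``V <- raw / (dwell_time * scan_repeats * T(lambda))`` with the filter
    transmission applied per emission wavelength.
    """
    t = np.asarray(meta.filter_transmission, dtype=float)
    if t.ndim == 1 and t.size != raw.n_wavelengths:
        raise ValueError("filter transmission not defined on the spectra grid")
    if np.any(t == 0):
        raise ValueError("filter transmission contains zeros; division undefined")
    scale = meta.dwell_time * meta.scan_repeats * t
    return raw.copy_with(raw.values / scale)


def resample_linear(
    values: np.ndarray,
    source: WavelengthGrid,
    target: WavelengthGrid,
    extrapolate: bool = False,
) -> np.ndarray:
    """Piecewise-linear resampling between wavelength grids.

    Exact at shared nodes.  Target wavelengths outside the source span raise
    unless ``extrapolate=True``, in which case values clamp to the endpoints.
    """
    vals = np.asarray(values, dtype=float)
    if vals.shape[-1] != len(source):
        raise ValueError("values do not match the source grid")
    if not extrapolate and (target.start < source.start - 1e-9 or target.stop > source.stop + 1e-9):
        raise ValueError(
            f"target grid {target.start:g}-{target.stop:g} nm outside source span "
            f"{source.start:g}-{source.stop:g} nm (set extrapolate=True to clamp)"
        )
    if vals.ndim == 1:
        return np.interp(target.values, source.values, vals)
    return np.vstack([np.interp(target.values, source.values, row) for row in vals])
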