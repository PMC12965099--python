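"""Reflectance-based correction of tissue optical distortion.

Fluorescence detected at a tissue surface is attenuated by absorption and
scattering at both the excitation and emission wavelengths.  Diffuse
reflectance, measured with broadband illumination, is an empirical surrogate
for those optical properties, and a family of dual-band corrections divides
the raw signal by reflectance integrals raised to a calibrated exponent
``alpha``:

* ``valdes`` -- constant dual-band factor ``V' = V / (R_ex * R_em**alpha)``
  with ``R_ex`` and ``R_em`` band-mean reflectances over the excitation
  (430-450 nm) and primary-emission (625-645 nm) bands;
* ``spectral`` -- wavelength-dependent factor ``V'(lam) = V(lam) /
  (R_ex * R(lam)**alpha)`` applied before unmixing;
* ``abundance`` -- per-endmember factor applied after unmixing,
  ``W'_i = W_i / (R_ex * Rbar_em_i**alpha)`` where ``Rbar_em_i`` is the
  reflectance averaged with the endmember spectrum as weight, matching each
  fluorophore's emission shape.

"Integration" over a band is implemented as the band mean (integral divided
by width) so both factors stay in [0, 1] and ``alpha`` is comparable across
bands.  The exponent is calibrated by sweeping alpha over [-2, 2] and
scoring goodness-of-fit against ground-truth concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import ReflectanceRecord, SpectraMatrix, WavelengthGrid, resample_linear

__all__ = [
    "CorrectionConfig",
    "AlphaSweepResult",
    "band_average_reflectance",
    "correct_valdes",
    "correct_spectral",
    "correct_abundance",
    "apply_correction",
    "sweep_alpha",
    "default_alpha_grid",
]

METHODS = ("none", "valdes", "spectral", "abundance")

DEFAULT_EX_BAND = (430.0, 450.0)
DEFAULT_EM_BAND = (625.0, 645.0)

#: reflectance floor applied before exponentiation, guarding deep
#: absorption bands against numerical blow-up
R_FLOOR = 1e-4


@dataclass
class CorrectionConfig:
    method: str = "none"
    alpha: float = -1.0
    ex_band: tuple[float, float] = DEFAULT_EX_BAND
    em_band: tuple[float, float] = DEFAULT_EM_BAND

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown correction method {self.method!r}")
        for band in (self.ex_band, self.em_band):
            if band[1] < band[0]:
                raise ValueError(f"band {band} is reversed")


@dataclass
class AlphaSweepResult:
    alphas: np.ndarray
    scores: np.ndarray
    best_alpha: float
    method: str = ""

    def as_table(self):
        import pandas as pd

        return pd.DataFrame({"alpha": self.alphas, "r2": self.scores})


def default_alpha_grid(step: float = 0.1) -> np.ndarray:
    """The calibration grid for alpha: [-2, 2] at the given step."""
    n = int(round(4.0 / step))
    return np.round(-2.0 + step * np.arange(n + 1), 10)


def band_average_reflectance(R: ReflectanceRecord, band: tuple[float, float]) -> float:
    """Mean reflectance over a wavelength band (trapezoidal integral / width)."""
    lo, hi = band
    mask = (R.grid.values >= lo - 1e-9) & (R.grid.values <= hi + 1e-9)
    if not np.any(mask):
        raise ValueError(f"band {band} contains no reflectance grid points")
    lam = R.grid.values[mask]
    vals = R.values[mask]
    if lam.size == 1:
        return float(vals[0])
    return float(np.trapezoid(vals, lam) / (lam[-1] - lam[0]))


def _ex_factor(R: ReflectanceRecord, cfg: CorrectionConfig) -> float:
    r_ex = band_average_reflectance(R, cfg.ex_band)
    if r_ex <= 0:
        raise ValueError("excitation-band reflectance is non-positive")
    return max(r_ex, R_FLOOR)


def correct_valdes(values: np.ndarray, R: ReflectanceRecord, cfg: CorrectionConfig) -> np.ndarray:
    """Constant dual-band correction of a single emission spectrum."""
    r_ex = _ex_factor(R, cfg)
    r_em = band_average_reflectance(R, cfg.em_band)
    if r_em <= 0:
        raise ValueError("emission-band reflectance is non-positive")
    r_em = max(r_em, R_FLOOR)
    return np.asarray(values, float) / (r_ex * r_em ** cfg.alpha)


def correct_spectral(
    values: np.ndarray,
    R: ReflectanceRecord,
    cfg: CorrectionConfig,
    grid: WavelengthGrid,
) -> np.ndarray:
    """Wavelength-dependent correction of a single emission spectrum."""
    r_ex = _ex_factor(R, cfg)
    r_lam = R.values if R.grid == grid else resample_linear(R.values, R.grid, grid)
    values = np.asarray(values, float)
    if np.any((r_lam <= 0) & (values > 0)):
        raise ValueError("reflectance non-positive within the spectrum support")
    r_lam = np.maximum(r_lam, R_FLOOR)
    return values / (r_ex * r_lam ** cfg.alpha)


def correct_abundance(
    W: np.ndarray,
    H: np.ndarray,
    reflectances: list[ReflectanceRecord],
    cfg: CorrectionConfig,
    grid: WavelengthGrid,
) -> np.ndarray:
    """Per-endmember post-unmixing correction of the abundance matrix.

    For sample j and endmember i the emission factor is the
    endmember-weighted average reflectance
    ``Rbar_ij = int R_j(lam) H_i(lam) dlam / int H_i(lam) dlam``.
    """
    W = np.atleast_2d(np.asarray(W, float))
    H = np.atleast_2d(np.asarray(H, float))
    if len(reflectances) != W.shape[0]:
        raise ValueError("need one reflectance record per sample")
    lam = grid.values
    h_areas = np.trapezoid(H, lam, axis=1)
    if np.any(h_areas <= 0):
        raise ValueError("endmember with zero integral; weighted reflectance undefined")
    out = np.empty_like(W)
    for j, R in enumerate(reflectances):
        r_ex = _ex_factor(R, cfg)
        r_lam = R.values if R.grid == grid else resample_linear(R.values, R.grid, grid)
        rbar = np.trapezoid(H * r_lam[None, :], lam, axis=1) / h_areas
        rbar = np.maximum(rbar, R_FLOOR)
        out[j] = W[j] / (r_ex * rbar ** cfg.alpha)
    return out


def apply_correction(
    spectra: SpectraMatrix,
    reflectances: list[ReflectanceRecord],
    cfg: CorrectionConfig,
) -> SpectraMatrix:
    """Apply a pre-unmixing correction (valdes/spectral) to a spectra batch."""
    if cfg.method == "none" or cfg.method == "abundance":
        return spectra
    if len(reflectances) != spectra.n_samples:
        raise ValueError("need one reflectance record per sample")
    out = np.empty_like(spectra.values)
    for j, (row, R) in enumerate(zip(spectra.values, reflectances)):
        if cfg.method == "valdes":
            out[j] = correct_valdes(row, R, cfg)
        else:
            out[j] = correct_spectral(row, R, cfg, spectra.grid)
    return spectra.copy_with(out)


def sweep_alpha(
    dataset,
    method: str,
    alpha_grid: np.ndarray | None = None,
    **pipeline_kwargs,
) -> AlphaSweepResult:
    """Calibrate the correction exponent against ground truth.

    For each alpha the full correction -> unmixing -> calibration ->
    evaluation chain is scored by R^2 against the known concentrations.
    For the ``abundance`` method the unmixing of uncorrected spectra is
    computed once and reused (the correction is post hoc); pre-unmixing
    methods re-run the unmixing per alpha.  Ties break toward smaller |alpha|.
    """
    from .pipeline import score_alpha_grid  # local import avoids a cycle

    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alphas = np.asarray(alpha_grid, float)
    if alphas.size == 0:
        raise ValueError("alpha grid is empty")
    y = np.asarray(dataset.y, float)
    if np.allclose(y, y[0]):
        raise ValueError("ground truth is constant; R^2 undefined")
    scores = score_alpha_grid(dataset, method, alphas, **pipeline_kwargs)
    best_i = min(range(alphas.size),
                 key=lambda i: (-scores[i], abs(alphas[i]), alphas[i]))
    return AlphaSweepResult(alphas=alphas, scores=np.asarray(scores, float),
                            best_alpha=float(alphas[best_i]), method=method)
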