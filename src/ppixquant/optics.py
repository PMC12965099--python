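"""Optical-property utilities: specular subtraction and scattering fits.

Integrating-sphere measurements yield *total* reflectance, the sum of the
diffuse (subsurface) component used by the distortion correction and a
specular (surface Fresnel) component.  At normal incidence on a smooth
interface the specular fraction is ``((n1-n2)/(n1+n2))**2``; for a typical
air/glass interface (n = 1.0 / 1.5) this is exactly 0.04, and it is
subtracted as a constant.

Reduced scattering spectra are summarised with a mixed Rayleigh-Mie power
law,

    mu_s'(lam) = a' * ( f_ray * (lam/lam0)**-4 + (1 - f_ray) * (lam/lam0)**-b_mie )

where ``a' = mu_s'(lam0)`` at the reference wavelength ``lam0`` (500 nm by
convention), ``f_ray`` is the Rayleigh fraction and ``b_mie`` the Mie
scattering power.  The inversion of sphere measurements to mu_a/mu_s' is
performed by external adding-doubling tooling; this module only consumes its
tabulated output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .spectra import ReflectanceRecord

__all__ = [
    "ScatteringFitParams",
    "OpticalProperties",
    "fresnel_normal_incidence",
    "subtract_specular",
    "eval_rayleigh_mie",
    "fit_rayleigh_mie",
    "ScatteringFitError",
]

DEFAULT_LAMBDA0 = 500.0
DEFAULT_FIT_RANGE = (450.0, 1000.0)

#: physical ordering of exponents: the Mie power stays below the Rayleigh 4
B_MIE_MAX = 4.0


class ScatteringFitError(RuntimeError):
    """Raised when the Rayleigh-Mie fit cannot be performed or fails."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class ScatteringFitParams:
    """Mixed Rayleigh-Mie parameters; ``a_prime`` is mu_s'(lambda0) in 1/mm."""

    a_prime: float
    f_ray: float
    b_mie: float
    lambda0: float = DEFAULT_LAMBDA0
    residual_norm: float = 0.0

    def __post_init__(self):
        if self.a_prime <= 0:
            raise ValueError("a_prime must be > 0")
        if not 0.0 <= self.f_ray <= 1.0:
            raise ValueError("f_ray must lie in [0, 1]")

    @property
    def f_mie(self) -> float:
        """Mie fraction 1 - f_ray, reported explicitly to avoid ambiguity."""
        return 1.0 - self.f_ray


@dataclass
class OpticalProperties:
    """Per-wavelength absorption and reduced scattering coefficients (1/mm)."""

    grid: "np.ndarray"
    mu_a: np.ndarray
    mu_s_prime: np.ndarray

    def __post_init__(self):
        self.mu_a = np.asarray(self.mu_a, float)
        self.mu_s_prime = np.asarray(self.mu_s_prime, float)
        if np.any(self.mu_a < 0) or np.any(self.mu_s_prime < 0):
            raise ValueError("optical coefficients must be non-negative")


def fresnel_normal_incidence(n1: float, n2: float) -> float:
    """Specular reflectance fraction at normal incidence between two media."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("refractive indices must be positive")
    return ((n1 - n2) / (n1 + n2)) ** 2


def subtract_specular(total: ReflectanceRecord, specular: float) -> ReflectanceRecord:
    """Total minus a constant specular fraction, clamped below at zero."""
    if total.kind != "total":
        raise ValueError("subtract_specular expects a total-reflectance record")
    if not 0.0 <= specular < 1.0:
        raise ValueError("specular fraction must lie in [0, 1)")
    vals = np.maximum(total.values - specular, 0.0)
    return ReflectanceRecord(total.grid, vals, kind="diffuse")


def eval_rayleigh_mie(params: ScatteringFitParams, lam) -> np.ndarray | float:
    """Evaluate the mixed Rayleigh-Mie model at wavelength(s) ``lam`` (nm)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelengths must be positive")
    x = lam / params.lambda0
    out = params.a_prime * (
        params.f_ray * x ** -4.0 + (1.0 - params.f_ray) * x ** -params.b_mie
    )
    return float(out) if out.ndim == 0 else out


def fit_rayleigh_mie(
    wavelengths: np.ndarray,
    musp: np.ndarray,
    lambda0: float = DEFAULT_LAMBDA0,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
) -> ScatteringFitParams:
    """Bounded least-squares fit of the Rayleigh-Mie model to mu_s' data.

    Data points outside ``fit_range`` are excluded.  Bounds: a' > 0,
    f_ray in [0, 1], b_mie in [0, 4].  Initialised at a' = mu_s'(lambda0)
    (nearest sample), f_ray = 0.1, b_mie = 1.0.
    """
    lam = np.asarray(wavelengths, float)
    mu = np.asarray(musp, float)
    if lam.shape != mu.shape:
        raise ValueError("wavelengths and musp must have the same shape")
    mask = (lam >= fit_range[0]) & (lam <= fit_range[1])
    lam, mu = lam[mask], mu[mask]
    if lam.size < 4:
        raise ScatteringFitError(
            f"need at least 4 points inside {fit_range[0]:g}-{fit_range[1]:g} nm, got {lam.size}"
        )
    if np.any(mu <= 0):
        raise ScatteringFitError("mu_s' values must be positive")

    x = lam / lambda0

    def resid(p):
        a, f, b = p
        return a * (f * x ** -4.0 + (1.0 - f) * x ** -b) - mu

    a0 = float(mu[np.argmin(np.abs(lam - lambda0))])
    res = least_squares(
        resid,
        x0=[a0, 0.1, 1.0],
        bounds=([1e-12, 0.0, 0.0], [np.inf, 1.0, B_MIE_MAX]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise ScatteringFitError(f"Rayleigh-Mie fit did not converge: {res.message}",
                                 last_iterate=res.x)
    a, f, b = res.x
    return ScatteringFitParams(
        a_prime=float(a), f_ray=float(f), b_mie=float(b), lambda0=lambda0,
        residual_norm=float(np.linalg.norm(res.fun)),
    )
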