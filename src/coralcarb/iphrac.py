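"""Abiotic-kinetics calcification model (IpHRAC) and the empirical rate fit.

The bio-inorganic view of coral calcification treats aragonite precipitation
in the calcifying fluid as following the abiotic rate law

    G = k_a (Omega_cf - 1)^n

with temperature-dependent empirical parameters

    k_a = -0.0177 T^2 + 1.47 T + 14.9
    n   =  0.0628 T + 0.0985          (T in degC).

G is in model rate units; an optional least-squares scale factor aligns the
curve with measured surface-normalized calcification rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P

from .errors import DomainError

__all__ = ["IpHRACParams", "iphrac_params", "iphrac_rate", "scale_to_data", "fit_calcification_vs_omega", "PolyFit"]


@dataclass(frozen=True)
class IpHRACParams:
    temperature: float
    k_a: float
    n: float


def iphrac_params(temperature: float) -> IpHRACParams:
    """Rate-law parameters k_a(T) and n(T); both positive for T in [15, 32] degC."""
    T = float(temperature)
    k_a = -0.0177 * T**2 + 1.47 * T + 14.9
    n = 0.0628 * T + 0.0985
    if k_a <= 0 or n <= 0:
        raise DomainError(f"IpHRAC parameters undefined at T={T} degC (k_a={k_a}, n={n})")
    return IpHRACParams(temperature=T, k_a=k_a, n=n)


def iphrac_rate(omega_cf: float, temperature: float) -> float:
    """Abiotic precipitation rate G = k_a (Omega_cf - 1)^n; G(1) = 0.

    Undefined for Omega_cf < 1 (undersaturated fluid).
    """
    omega = np.asarray(omega_cf, dtype=float)
    if np.any(omega < 1):
        raise DomainError(f"omega_cf={omega_cf!r} < 1: model undefined for undersaturation")
    p = iphrac_params(temperature)
    return p.k_a * (omega - 1.0) ** p.n


def scale_to_data(omega_cf, rates, temperature: float) -> float:
    """Least-squares factor s minimizing ||rates - s * G(omega)|| (units bridge)."""
    g = iphrac_rate(np.asarray(omega_cf, dtype=float), temperature)
    denom = float(np.dot(g, g))
    if denom == 0:
        raise DomainError("cannot scale: model rates are identically zero")
    return float(np.dot(np.asarray(rates, dtype=float), g) / denom)


@dataclass(frozen=True)
class PolyFit:
    """Least-squares polynomial y = c0 + c1 x + ... + cd x^d with diagnostics."""

    coefficients: tuple   # ascending order
    r_squared: float
    residuals: tuple

    def __call__(self, x):
        return P.polyval(np.asarray(x, dtype=float), np.asarray(self.coefficients))


def fit_calcification_vs_omega(omega_cf, rates, degree: int = 2) -> PolyFit:
    """Fit calcification rate against Omega_cf with a least-squares polynomial.

    Requires at least degree + 2 points; duplicate abscissae are fine as long
    as the design matrix has full column rank.
    """
    x = np.asarray(omega_cf, dtype=float)
    y = np.asarray(rates, dtype=float)
    if x.size < degree + 2:
        raise DomainError(f"need at least {degree + 2} points for a degree-{degree} fit")
    if np.unique(x).size < degree + 1:
        raise DomainError("rank-deficient design: too few distinct Omega_cf values")
    coefs = P.polyfit(x, y, degree)
    fitted = P.polyval(x, coefs)
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PolyFit(coefficients=tuple(coefs), r_squared=r2, residuals=tuple(resid))
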