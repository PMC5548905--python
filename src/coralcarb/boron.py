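"""Boron-proxy reconstruction of coral calcifying-fluid carbonate chemistry.

Two skeletal measurements constrain the fluid from which coral aragonite
precipitated:

* delta11B, the boron isotopic composition, records the pH of the calcifying
  fluid (pH_cf) because only the borate ion B(OH)4- — whose isotopic
  composition is a known, pH-dependent function of seawater delta11B — is
  incorporated into aragonite:

      pH_cf = pK_B - log10[ (d11B_sw - d11B_carb)
                            / (alpha * d11B_carb - d11B_sw + 1000 (alpha - 1)) ]

  with d11B_sw = 39.61 permil and the boric/borate fractionation factor
  alpha = 1.0272.

* the B/Ca ratio, combined with pH_cf, yields the carbonate-ion concentration
  via an empirical distribution coefficient calibrated on inorganic aragonite:

      [CO3^2-]_cf = K_D [B(OH)4-]_cf / (B/Ca),
      K_D = K_D0 exp(-k_KD [H+])

  with K_D0 = 2.97e-3 and k_KD = 0.0202.  At calcifying-fluid pH (>8.3) the
  exponential attenuation is negligible when [H+] is expressed in umol kg^-1
  (the default here, which reproduces published coral reconstructions); the
  unit is configurable.

DIC_cf follows from (pH_cf, [CO3^2-]_cf) through the carbonic-acid speciation,
and Omega_cf from [CO3^2-]_cf and seawater calcium.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .carbonate import ConstantsSet, dic_from_pH_co3, equilibrium_constants, omega_aragonite
from .errors import DomainError

__all__ = [
    "BoronConstants",
    "BoronGeochem",
    "CalcifyingFluidState",
    "pHcf_from_d11B",
    "d11B_from_pHcf",
    "co3cf_from_BCa",
    "resolve_calcifying_fluid",
]

_H_UNIT_SCALE = {"mol": 1.0, "umol": 1e6, "nmol": 1e9}


@dataclass(frozen=True)
class BoronConstants:
    """Calibration constants of the delta11B and B/Ca proxies.

    Attributes
    ----------
    d11B_seawater : float
        Seawater boron isotopic composition, permil vs NIST 951.
    alpha_B3_B4 : float
        Boric-acid/borate isotopic fractionation factor.
    KD0 : float
        Amplitude of the B/Ca distribution coefficient (mol/mol scale).
    k_KD : float
        Exponential [H+] coefficient of K_D; units of 1/(h_unit of H+).
    h_unit : str
        Unit of [H+] inside the K_D exponent: "mol", "umol" (default) or
        "nmol" kg^-1.  At pH_cf > 8.3 the choice only matters for "nmol".
    KD0_sd : float
        1-sigma calibration uncertainty of KD0, available to Monte-Carlo
        propagation but not used by default (only measurement errors are
        propagated).
    """

    d11B_seawater: float = 39.61
    alpha_B3_B4: float = 1.0272
    KD0: float = 2.97e-3
    k_KD: float = 0.0202
    h_unit: str = "umol"
    KD0_sd: float = 0.17e-3

    def __post_init__(self) -> None:
        if self.alpha_B3_B4 <= 1:
            raise DomainError("alpha_B3_B4 must exceed 1")
        if self.KD0 <= 0:
            raise DomainError("KD0 must be > 0")
        if self.d11B_seawater <= 0:
            raise DomainError("d11B_seawater must be > 0")
        if self.h_unit not in _H_UNIT_SCALE:
            raise DomainError(f"h_unit must be one of {sorted(_H_UNIT_SCALE)}")

    @property
    def d11B_lower_limit(self) -> float:
        """delta11B at which the pH-equation denominator vanishes (domain boundary)."""
        return (self.d11B_seawater - 1000.0 * (self.alpha_B3_B4 - 1.0)) / self.alpha_B3_B4


@dataclass(frozen=True)
class BoronGeochem:
    """One colony's skeletal boron measurement."""

    d11B: float   # permil vs NIST 951
    BCa: float    # umol mol^-1

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.BCa) <= 0):
            raise DomainError(f"BCa={self.BCa!r} must be > 0")


@dataclass(frozen=True)
class CalcifyingFluidState:
    """Reconstructed calcifying-fluid chemistry (mol kg^-1 internally)."""

    pH_cf: float
    borate_cf: float   # [B(OH)4-]_cf, mol kg^-1
    co3_cf: float      # mol kg^-1
    DIC_cf: float      # mol kg^-1
    omega_cf: float


def pHcf_from_d11B(
    d11B: float,
    temperature: float,
    salinity: float,
    constants: BoronConstants = BoronConstants(),
    carb_constants: Optional[ConstantsSet] = None,
) -> float:
    """Calcifying-fluid pH (total scale) from skeletal delta11B.

    Monotonically increasing in d11B; defined for d11B strictly between the
    denominator root (~12.1 permil at default constants) and seawater
    delta11B (39.61 permil).
    """
    d11B = np.asarray(d11B, dtype=float)
    c = constants
    numer = c.d11B_seawater - d11B
    denom = c.alpha_B3_B4 * d11B - c.d11B_seawater + 1000.0 * (c.alpha_B3_B4 - 1.0)
    if np.any(numer <= 0):
        raise DomainError(
            f"numerator non-positive: d11B={d11B!r} must be < d11B_seawater={c.d11B_seawater}"
        )
    if np.any(denom <= 0):
        raise DomainError(
            f"denominator non-positive: d11B={d11B!r} must exceed {c.d11B_lower_limit:.3f} permil"
        )
    cc = carb_constants if carb_constants is not None else equilibrium_constants(
        temperature, salinity
    )
    return cc.pKB - np.log10(numer / denom)


def d11B_from_pHcf(
    pH_cf: float,
    temperature: float,
    salinity: float,
    constants: BoronConstants = BoronConstants(),
    carb_constants: Optional[ConstantsSet] = None,
) -> float:
    """Algebraic inverse of :func:`pHcf_from_d11B` (round trips to ~1e-12)."""
    c = constants
    cc = carb_constants if carb_constants is not None else equilibrium_constants(
        temperature, salinity
    )
    # pKB - pH = log10(numer/denom); solve the linear equation for d11B.
    r = 10.0 ** (cc.pKB - np.asarray(pH_cf, dtype=float))
    return (
        c.d11B_seawater * (1.0 + r) - 1000.0 * r * (c.alpha_B3_B4 - 1.0)
    ) / (1.0 + r * c.alpha_B3_B4)


def co3cf_from_BCa(
    BCa: float,
    pH_cf: float,
    temperature: float,
    salinity: float,
    constants: BoronConstants = BoronConstants(),
    carb_constants: Optional[ConstantsSet] = None,
) -> float:
    """Calcifying-fluid [CO3^2-] (mol kg^-1) from skeletal B/Ca and pH_cf.

    The fluid is assumed to carry seawater total boron at the ambient
    salinity, speciated at pH_cf with the ambient-condition K_B; B/Ca is in
    umol mol^-1.
    """
    BCa = np.asarray(BCa, dtype=float)
    if np.any(BCa <= 0):
        raise DomainError(f"BCa={BCa!r} must be > 0")
    cc = carb_constants if carb_constants is not None else equilibrium_constants(
        temperature, salinity
    )
    H = 10.0 ** (-np.asarray(pH_cf, dtype=float))
    borate = cc.B_total / (1.0 + H / cc.KB)
    KD = constants.KD0 * np.exp(-constants.k_KD * H * _H_UNIT_SCALE[constants.h_unit])
    return KD * borate / (BCa * 1e-6)


def resolve_calcifying_fluid(
    geochem: BoronGeochem,
    temperature: float,
    salinity: float,
    constants: BoronConstants = BoronConstants(),
    carb_constants: Optional[ConstantsSet] = None,
    colony_id: Optional[str] = None,
) -> CalcifyingFluidState:
    """Full reconstruction: (delta11B, B/Ca) -> (pH_cf, [CO3]_cf, DIC_cf, Omega_cf)."""
    cc = carb_constants if carb_constants is not None else equilibrium_constants(
        temperature, salinity
    )
    try:
        pH_cf = pHcf_from_d11B(geochem.d11B, temperature, salinity, constants, cc)
        co3 = co3cf_from_BCa(geochem.BCa, pH_cf, temperature, salinity, constants, cc)
    except DomainError as exc:
        if colony_id is not None:
            raise DomainError(f"colony {colony_id!r}: {exc}") from exc
        raise
    H = 10.0 ** (-pH_cf)
    return CalcifyingFluidState(
        pH_cf=pH_cf,
        borate_cf=cc.B_total / (1.0 + H / cc.KB),
        co3_cf=co3,
        DIC_cf=dic_from_pH_co3(pH_cf, co3, cc),
        omega_cf=omega_aragonite(co3, cc),
    )


def with_kd0(constants: BoronConstants, KD0: float) -> BoronConstants:
    """Copy of the constants with a perturbed KD0 (for sensitivity studies)."""
    return replace(constants, KD0=KD0)
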