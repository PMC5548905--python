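"""Seawater CO2-system thermodynamics on the total pH scale.

Equilibrium constants are evaluated from named literature formulations and the
speciation is solved in closed form from the measured (pH_T, A_T) pair, the
input combination used for mesocosm carbonate-chemistry monitoring.  The
alkalinity model includes the carbonate, borate and water terms; phosphate,
silicate and ammonia contributions are omitted (not measured in typical
mesocosm monitoring and negligible in oligotrophic coastal seawater).

All concentrations are mol kg-seawater^-1 internally; micromolar units appear
only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, SolverError

__all__ = [
    "SeawaterState",
    "ConstantsSet",
    "CarbonateSpeciation",
    "equilibrium_constants",
    "solve_from_pH_alkalinity",
    "dic_from_pH_co3",
    "omega_aragonite",
    "alkalinity_from_speciation",
]

# Valid ranges for the constant formulations used here.
TEMPERATURE_RANGE = (-2.0, 40.0)
SALINITY_RANGE = (1.0, 45.0)
PH_RANGE = (6.0, 9.5)


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < lo) or np.any(arr > hi):
        raise DomainError(f"{name}={value!r} outside valid range [{lo}, {hi}]")


@dataclass(frozen=True)
class SeawaterState:
    """Measured seawater conditions for one tank, date, or treatment mean.

    Parameters
    ----------
    temperature : float
        In-situ temperature, degC.
    salinity : float
        Practical salinity.
    pH_total : float
        pH on the total hydrogen-ion scale (Tris-calibrated).
    alkalinity : float
        Total alkalinity, mol kg-sw^-1.
    """

    temperature: float
    salinity: float
    pH_total: float
    alkalinity: float

    def __post_init__(self) -> None:
        _check_range("temperature", self.temperature, *TEMPERATURE_RANGE)
        _check_range("salinity", self.salinity, *SALINITY_RANGE)
        _check_range("pH_total", self.pH_total, *PH_RANGE)
        if np.any(np.asarray(self.alkalinity) <= 0):
            raise DomainError(f"alkalinity={self.alkalinity!r} must be > 0")


@dataclass(frozen=True)
class ConstantsSet:
    """Equilibrium constants (mol kg^-1, total pH scale) plus conservative totals."""

    K0: float
    K1: float
    K2: float
    KB: float
    Kw: float
    Ksp_aragonite: float
    B_total: float
    Ca_total: float
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in ("K0", "K1", "K2", "KB", "Kw", "Ksp_aragonite", "B_total", "Ca_total"):
            if not np.all(np.asarray(getattr(self, name)) > 0):
                raise DomainError(f"{name} must be > 0")
        if not np.all(np.asarray(self.K1) > np.asarray(self.K2)):
            raise DomainError("K1 must exceed K2")

    @property
    def pKB(self) -> float:
        return -np.log10(self.KB)


@dataclass(frozen=True)
class CarbonateSpeciation:
    """Fully solved CO2 system for one seawater state."""

    DIC: float            # mol kg^-1 (C_T)
    pCO2: float           # uatm
    CO3: float            # mol kg^-1
    HCO3: float           # mol kg^-1
    CO2aq: float          # mol kg^-1
    omega_aragonite: float
    constants_used: ConstantsSet


# ---------------------------------------------------------------------------
# Constant formulations
# ---------------------------------------------------------------------------

def _k0_weiss1974(TK, S):
    # CO2 solubility, mol kg^-1 atm^-1 (Weiss 1974).
    return np.exp(
        -60.2409
        + 93.4517 * (100.0 / TK)
        + 23.3585 * np.log(TK / 100.0)
        + S * (0.023517 - 0.023656 * (TK / 100.0) + 0.0047036 * (TK / 100.0) ** 2)
    )


def _k1k2_lueker2000(TK, S):
    lnT = np.log(TK)
    pK1 = 3633.86 / TK - 61.2172 + 9.6777 * lnT - 0.011555 * S + 0.0001152 * S**2
    pK2 = 471.78 / TK + 25.929 - 3.16967 * lnT - 0.01781 * S + 0.0001122 * S**2
    return 10.0**-pK1, 10.0**-pK2


def _k1k2_roy1993(TK, S):
    lnT = np.log(TK)
    sq = np.sqrt(S)
    conv = np.log(1 - 0.001005 * S)  # mol kg-H2O -> mol kg-sw
    lnK1 = (
        -2307.1266 / TK + 2.83655 - 1.5529413 * lnT
        + (-4.0484 / TK - 0.20760841) * sq
        + 0.08468345 * S - 0.00654208 * S**1.5 + conv
    )
    lnK2 = (
        -3351.6106 / TK - 9.226508 - 0.2005743 * lnT
        + (-23.9722 / TK - 0.106901773) * sq
        + 0.1130822 * S - 0.00846934 * S**1.5 + conv
    )
    return np.exp(lnK1), np.exp(lnK2)


def _kb_dickson1990(TK, S):
    lnT = np.log(TK)
    sq = np.sqrt(S)
    lnKB = (
        (-8966.90 - 2890.53 * sq - 77.942 * S + 1.728 * S**1.5 - 0.0996 * S**2) / TK
        + 148.0248 + 137.1942 * sq + 1.62142 * S
        + (-24.4344 - 25.085 * sq - 0.2474 * S) * lnT
        + 0.053105 * sq * TK
    )
    return np.exp(lnKB)


def _kw_millero1995(TK, S):
    lnT = np.log(TK)
    sq = np.sqrt(S)
    lnKw = (
        148.9802 - 13847.26 / TK - 23.6521 * lnT
        + (118.67 / TK - 5.977 + 1.0495 * lnT) * sq
        - 0.01615 * S
    )
    return np.exp(lnKw)


def _ksp_arag_mucci1983(TK, S):
    sq = np.sqrt(S)
    log10Ksp = (
        -171.945 - 0.077993 * TK + 2903.293 / TK + 71.595 * np.log10(TK)
        + (-0.068393 + 0.0017276 * TK + 88.135 / TK) * sq
        - 0.10018 * S + 0.0059415 * S**1.5
    )
    return 10.0**log10Ksp


def _btotal_lee2010(S):
    return 0.0004326 * S / 35.0


def _btotal_uppstrom1974(S):
    return 0.0004157 * S / 35.0


_K1K2 = {"lueker2000": _k1k2_lueker2000, "roy1993": _k1k2_roy1993}
_BTOTAL = {"lee2010": _btotal_lee2010, "uppstrom1974": _btotal_uppstrom1974}


def equilibrium_constants(
    temperature: float,
    salinity: float,
    *,
    k1k2: str = "lueker2000",
    btotal: str = "lee2010",
) -> ConstantsSet:
    """Evaluate the CO2-system constants at (T, S) on the total pH scale.

    Defaults follow common seawater-CO2 software conventions: K1/K2 from
    Lueker et al. (2000), K_B from Dickson (1990), aragonite Ksp from Mucci
    (1983), K0 from Weiss (1974), Kw from Millero (1995), total boron from
    Lee et al. (2010) and calcium from Riley & Tongudai (0.010282 x S/35).
    """
    _check_range("temperature", temperature, *TEMPERATURE_RANGE)
    _check_range("salinity", salinity, *SALINITY_RANGE)
    if k1k2 not in _K1K2:
        raise DomainError(f"unknown k1k2 formulation {k1k2!r}; choose from {sorted(_K1K2)}")
    if btotal not in _BTOTAL:
        raise DomainError(f"unknown btotal formulation {btotal!r}; choose from {sorted(_BTOTAL)}")

    TK = np.asarray(temperature, dtype=float) + 273.15
    S = np.asarray(salinity, dtype=float)
    K1, K2 = _K1K2[k1k2](TK, S)
    return ConstantsSet(
        K0=_k0_weiss1974(TK, S),
        K1=K1,
        K2=K2,
        KB=_kb_dickson1990(TK, S),
        Kw=_kw_millero1995(TK, S),
        Ksp_aragonite=_ksp_arag_mucci1983(TK, S),
        B_total=_BTOTAL[btotal](S),
        Ca_total=0.010282 * S / 35.0,
        provenance={
            "K0": "weiss1974",
            "K1K2": k1k2,
            "KB": "dickson1990",
            "Kw": "millero1995",
            "Ksp_aragonite": "mucci1983",
            "B_total": btotal,
            "Ca_total": "riley_tongudai1967",
        },
    )


# ---------------------------------------------------------------------------
# Speciation
# ---------------------------------------------------------------------------

def solve_from_pH_alkalinity(
    state: SeawaterState, constants: ConstantsSet | None = None
) -> CarbonateSpeciation:
    """Solve the full CO2 system from measured pH_T and total alkalinity.

    The carbonate alkalinity is obtained by subtracting the borate, hydroxide
    and free-proton terms from A_T; DIC then follows in closed form from the
    carbonic-acid speciation fractions at the given [H+].
    """
    c = constants if constants is not None else equilibrium_constants(
        state.temperature, state.salinity
    )
    H = 10.0 ** (-np.asarray(state.pH_total, dtype=float))
    borate = c.B_total / (1.0 + H / c.KB)
    OH = c.Kw / H
    carb_alk = np.asarray(state.alkalinity, dtype=float) - borate - OH + H

    denom_alk = c.K1 * H + 2.0 * c.K1 * c.K2
    gamma = H**2 + c.K1 * H + c.K1 * c.K2
    DIC = carb_alk * gamma / denom_alk
    if np.any(DIC <= 0):
        raise SolverError(
            "no positive-DIC solution: carbonate alkalinity is non-positive "
            f"(pH_total={state.pH_total}, alkalinity={state.alkalinity})"
        )
    CO2aq = DIC * H**2 / gamma
    HCO3 = DIC * c.K1 * H / gamma
    CO3 = DIC * c.K1 * c.K2 / gamma
    return CarbonateSpeciation(
        DIC=DIC,
        pCO2=CO2aq / c.K0 * 1e6,
        CO3=CO3,
        HCO3=HCO3,
        CO2aq=CO2aq,
        omega_aragonite=omega_aragonite(CO3, c),
        constants_used=c,
    )


def alkalinity_from_speciation(
    spec: CarbonateSpeciation, pH_total: float
) -> float:
    """Recompute A_T from a solved speciation (round-trip/conservation check)."""
    c = spec.constants_used
    H = 10.0 ** (-np.asarray(pH_total, dtype=float))
    borate = c.B_total / (1.0 + H / c.KB)
    return spec.HCO3 + 2.0 * spec.CO3 + borate + c.Kw / H - H


def dic_from_pH_co3(pH: float, co3: float, constants: ConstantsSet) -> float:
    """DIC from a (pH, [CO3^2-]) pair.

    DIC = [CO3^2-] (1 + [H+]/K2 + [H+]^2/(K1 K2)); this is the conversion used
    to derive the calcifying-fluid DIC from proxy-reconstructed pH_cf and
    [CO3^2-]_cf.
    """
    if np.any(np.asarray(co3) < 0):
        raise DomainError(f"co3={co3!r} must be >= 0")
    H = 10.0 ** (-np.asarray(pH, dtype=float))
    return np.asarray(co3) * (1.0 + H / constants.K2 + H**2 / (constants.K1 * constants.K2))


def omega_aragonite(co3: float, constants: ConstantsSet) -> float:
    """Aragonite saturation state Omega = [Ca2+][CO3^2-]/Ksp_aragonite."""
    if np.any(np.asarray(co3) < 0):
        raise DomainError(f"co3={co3!r} must be >= 0")
    return np.asarray(co3) * constants.Ca_total / constants.Ksp_aragonite
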