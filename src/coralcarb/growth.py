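"""Net calcification from buoyant-weight time series.

A coral nubbin weighed submerged in seawater registers only the part of its
skeletal weight not offset by buoyancy, so a change in buoyant weight maps to
a change in dry aragonite mass through the density contrast
(Archimedes' principle):

    dry gain = buoyant gain / (1 - rho_seawater / rho_aragonite)

with rho_aragonite = 2.93 g cm^-3.  Net calcification is the dry-mass gain
normalized to living tissue surface area and elapsed time, in
mg CaCO3 cm^-2 d^-1; surface area is either supplied per colony or derived
from dry skeletal weight through an allometric relation SA = a W^b.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from typing import Optional, Union

import numpy as np

from .errors import DomainError

__all__ = [
    "ARAGONITE_DENSITY",
    "GrowthRecord",
    "AllometricSA",
    "dry_from_buoyant",
    "seawater_density",
    "net_calcification",
]

ARAGONITE_DENSITY = 2.93  # g cm^-3

DateLike = Union[date, datetime, str, None]


def _as_date(d: DateLike) -> Optional[date]:
    if d is None:
        return None
    if isinstance(d, datetime):
        return d.date()
    if isinstance(d, date):
        return d
    return date.fromisoformat(str(d))


@dataclass(frozen=True)
class AllometricSA:
    """Allometric tissue surface area: SA (cm^2) = a * (dry skeletal weight, g)^b."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise DomainError("allometric coefficient a must be > 0")
        if not 0 < self.b <= 1.5:
            raise DomainError("allometric exponent b must be in (0, 1.5]")

    def surface_area(self, dry_weight_g: float) -> float:
        return self.a * np.asarray(dry_weight_g, dtype=float) ** self.b


@dataclass(frozen=True)
class GrowthRecord:
    """One colony's buoyant-weight observations bracketing the incubation."""

    colony_id: str
    buoyant_mass_initial: float   # g
    buoyant_mass_final: float     # g
    seawater_density: float       # g cm^-3
    surface_area: float           # cm^2
    date_initial: DateLike = None
    date_final: DateLike = None

    def __post_init__(self) -> None:
        if self.buoyant_mass_initial <= 0 or self.buoyant_mass_final <= 0:
            raise DomainError(f"colony {self.colony_id!r}: buoyant masses must be > 0")
        if not 1.0 <= self.seawater_density <= 1.04:
            raise DomainError(
                f"colony {self.colony_id!r}: seawater_density={self.seawater_density} "
                "outside [1.0, 1.04] g cm^-3"
            )
        d0, d1 = _as_date(self.date_initial), _as_date(self.date_final)
        if d0 is not None and d1 is not None and d1 <= d0:
            raise DomainError(f"colony {self.colony_id!r}: date_final must follow date_initial")

    @property
    def elapsed_days(self) -> float:
        """Calendar days between weighings; 56 d (8 weeks) when dates are absent."""
        d0, d1 = _as_date(self.date_initial), _as_date(self.date_final)
        if d0 is None or d1 is None:
            return 56.0
        return float((d1 - d0).days)


def dry_from_buoyant(
    delta_buoyant: float,
    seawater_density: float,
    aragonite_density: float = ARAGONITE_DENSITY,
) -> float:
    """Convert a buoyant-weight change (g) to a dry aragonite mass change (g)."""
    if not aragonite_density > seawater_density:
        raise DomainError(
            f"aragonite_density={aragonite_density} must exceed "
            f"seawater_density={seawater_density}"
        )
    return np.asarray(delta_buoyant, dtype=float) / (1.0 - seawater_density / aragonite_density)


def seawater_density(temperature: float, salinity: float) -> float:
    """Surface seawater density (g cm^-3) from the EOS-80 one-atmosphere equation.

    UNESCO (1983) polynomial; e.g. (21 degC, S 35.5) -> 1.0249 g cm^-3.
    """
    T = np.asarray(temperature, dtype=float)
    S = np.asarray(salinity, dtype=float)
    rho_w = (
        999.842594
        + 6.793952e-2 * T
        - 9.095290e-3 * T**2
        + 1.001685e-4 * T**3
        - 1.120083e-6 * T**4
        + 6.536332e-9 * T**5
    )
    A = 8.24493e-1 - 4.0899e-3 * T + 7.6438e-5 * T**2 - 8.2467e-7 * T**3 + 5.3875e-9 * T**4
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T**2
    C = 4.8314e-4
    rho = rho_w + A * S + B * S**1.5 + C * S**2  # kg m^-3
    return rho / 1000.0


def net_calcification(record: GrowthRecord) -> float:
    """Net calcification rate in mg CaCO3 cm^-2 d^-1 (negative = net dissolution)."""
    if record.surface_area <= 0:
        raise DomainError(f"colony {record.colony_id!r}: surface_area must be > 0")
    dry_gain_g = dry_from_buoyant(
        record.buoyant_mass_final - record.buoyant_mass_initial, record.seawater_density
    )
    return float(dry_gain_g * 1000.0 / record.surface_area / record.elapsed_days)
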