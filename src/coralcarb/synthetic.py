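"""Synthetic mesocosm experiment with the full nested design.

Emulates an 8-week, 2-species x 3-pH ocean-acidification experiment: three pH
treatments (8.09, 7.81, 7.63) each replicated in 4 header tanks, each header
tank feeding 3 incubation tanks holding one colony per species (n = 12
colonies per species per treatment, 72 total).

Colony-level observables are drawn from the published treatment-level
structure:

* seawater pH per tank and sampling date = treatment target + header-tank
  offset + observation jitter (total SD 0.05); alkalinity ~ N(2358, 5)
  umol kg^-1; temperature and salinity fixed per treatment;
* skeletal delta11B = species regression on the tank's seawater pH
  (2.37 pH + 4.41 and 4.37 pH - 12.11) + tank effect + between-colony noise
  + 0.17 permil analytical noise;
* skeletal B/Ca = species regression on delta11B (31.6 d11B - 124 and
  25.8 d11B + 98.5) + residual + 18 umol mol^-1 analytical noise;
* calcification rate = species x treatment mean + tank effect + colony noise
  (colony SD = published SE x sqrt(12)); buoyant weights are back-computed
  from the target rate through the aragonite-density identity so the growth
  module recovers the rate exactly.

Between-colony SDs are calibrated so treatment-level standard errors at
n = 12 match the published tables; header-tank variance defaults to 10% of
colony variance (tank effects negligible).  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .growth import seawater_density, AllometricSA, ARAGONITE_DENSITY
from .errors import ConfigError

__all__ = ["SpeciesParams", "GeneratorParams", "SyntheticExperiment", "generate_experiment"]


@dataclass(frozen=True)
class SpeciesParams:
    """Generating model for one species."""

    d11B_slope: float            # permil per seawater pH unit
    d11B_intercept: float        # permil
    bca_slope: float             # umol/mol per permil
    bca_intercept: float         # umol/mol
    d11B_colony_sd: float        # between-colony biological SD, permil
    bca_resid_sd: float          # B/Ca residual around the d11B regression, umol/mol
    calcification_mean: tuple    # mg cm^-2 d^-1 per treatment (ordered by target pH desc)
    calcification_se: tuple      # published SE at n = 12, per treatment
    initial_dry_weight_g: float = 8.0
    initial_dry_weight_cv: float = 0.2


_DEFAULT_SPECIES = {
    "A_youngei": SpeciesParams(
        d11B_slope=2.37, d11B_intercept=4.41,
        bca_slope=31.6, bca_intercept=-124.0,
        d11B_colony_sd=0.50, bca_resid_sd=8.0,
        calcification_mean=(1.97, 1.65, 1.34),
        calcification_se=(0.13, 0.10, 0.09),
    ),
    "P_damicornis": SpeciesParams(
        d11B_slope=4.37, d11B_intercept=-12.11,
        bca_slope=25.8, bca_intercept=98.5,
        d11B_colony_sd=0.85, bca_resid_sd=20.0,
        calcification_mean=(1.07, 1.00, 0.97),
        calcification_se=(0.08, 0.08, 0.08),
    ),
}


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions of the emulated experiment."""

    treatments: tuple = ("pH8.1", "pH7.8", "pH7.6")
    target_pH: tuple = (8.09, 7.81, 7.63)
    temperature: tuple = (20.9, 20.9, 21.0)     # degC per treatment
    salinity: float = 35.5
    alkalinity_mean: float = 2358.0             # umol kg^-1
    alkalinity_sd: float = 5.0
    pH_obs_sd: float = 0.046                    # observation-level jitter
    pH_tank_sd: float = 0.02                    # header-tank offset (total ~0.05)
    n_header_per_treatment: int = 4
    n_incubation_per_header: int = 3
    n_dates: int = 28                           # pH sampled every ~2 d over 8 weeks
    d11B_analytical_sd: float = 0.17            # permil
    bca_analytical_sd: float = 18.0             # umol/mol
    tank_variance_fraction: float = 0.10        # tank variance / colony variance
    duration_days: int = 56
    date_initial: str = "2015-10-19"
    allometric_sa: AllometricSA = AllometricSA(a=5.0, b=0.8)
    species: dict = field(default_factory=lambda: dict(_DEFAULT_SPECIES))

    def __post_init__(self) -> None:
        if not (len(self.treatments) == len(self.target_pH) == len(self.temperature)):
            raise ConfigError("treatments, target_pH and temperature must align")
        if self.n_header_per_treatment < 2 or self.n_incubation_per_header < 1:
            raise ConfigError("need >= 2 header tanks per treatment and >= 1 incubation each")
        for sp, p in self.species.items():
            if len(p.calcification_mean) != len(self.treatments):
                raise ConfigError(f"species {sp}: calcification means do not match treatments")

    def to_dict(self) -> dict:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k not in ("species", "allometric_sa")
        }
        d["allometric_sa"] = {"a": self.allometric_sa.a, "b": self.allometric_sa.b}
        d["species"] = {
            sp: {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in p.__dict__.items()
            }
            for sp, p in self.species.items()
        }
        return d


@dataclass(frozen=True)
class SyntheticExperiment:
    """The three generated tables plus the parameters that produced them."""

    seawater: pd.DataFrame
    geochem: pd.DataFrame
    growth: pd.DataFrame
    params: GeneratorParams
    seed: int

    def write(self, out_dir) -> dict:
        """Write seawater/geochem/growth CSVs and a params YAML snapshot."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("seawater", "geochem", "growth"):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = str(p)
        snap = out / "params.yaml"
        with open(snap, "w") as fh:
            yaml.safe_dump({"seed": self.seed, **self.params.to_dict()}, fh, sort_keys=True)
        paths["params"] = str(snap)
        return paths


def generate_experiment(
    params: GeneratorParams = GeneratorParams(), seed: int = 0
) -> SyntheticExperiment:
    """Draw one full synthetic experiment (deterministic for a fixed seed)."""
    rng = np.random.default_rng(seed)
    p = params
    date0 = pd.Timestamp(p.date_initial)
    date1 = date0 + pd.Timedelta(days=p.duration_days)

    sw_rows, geo_rows, gr_rows = [], [], []
    header_idx = 0
    tank_idx = 0
    sample_dates = [
        date0 + pd.Timedelta(days=float(d))
        for d in np.linspace(0, p.duration_days, p.n_dates)
    ]

    for it, (tr, pH_t, T) in enumerate(zip(p.treatments, p.target_pH, p.temperature)):
        rho_sw = float(seawater_density(T, p.salinity))
        for _h in range(p.n_header_per_treatment):
            header_idx += 1
            header = f"H{header_idx:02d}"
            tank_pH = pH_t + rng.normal(0.0, p.pH_tank_sd)
            # header-tank random effects, variance = fraction of colony variance
            tank_eff = {
                sp: {
                    "d11B": rng.normal(0, np.sqrt(p.tank_variance_fraction) * spp.d11B_colony_sd),
                    "calc": rng.normal(
                        0,
                        np.sqrt(p.tank_variance_fraction)
                        * spp.calcification_se[it] * np.sqrt(12.0),
                    ),
                }
                for sp, spp in p.species.items()
            }
            for _i in range(p.n_incubation_per_header):
                tank_idx += 1
                tank = f"T{tank_idx:02d}"
                for d in sample_dates:
                    sw_rows.append({
                        "tank_id": tank,
                        "header_tank": header,
                        "treatment": tr,
                        "date": d.date().isoformat(),
                        "pH_total": tank_pH + rng.normal(0.0, p.pH_obs_sd),
                        "alkalinity_umol_kg": rng.normal(p.alkalinity_mean, p.alkalinity_sd),
                        "temperature_C": T,
                        "salinity": p.salinity,
                    })
                for sp, spp in p.species.items():
                    colony = f"{sp}_{tank}"
                    d11B_true = (
                        spp.d11B_slope * tank_pH + spp.d11B_intercept
                        + tank_eff[sp]["d11B"]
                        + rng.normal(0.0, spp.d11B_colony_sd)
                    )
                    d11B_meas = d11B_true + rng.normal(0.0, p.d11B_analytical_sd)
                    bca_true = (
                        spp.bca_slope * d11B_true + spp.bca_intercept
                        + rng.normal(0.0, spp.bca_resid_sd)
                    )
                    bca_meas = bca_true + rng.normal(0.0, p.bca_analytical_sd)
                    geo_rows.append({
                        "colony_id": colony,
                        "species": sp,
                        "treatment": tr,
                        "header_tank": header,
                        "incubation_tank": tank,
                        "d11B_permil": d11B_meas,
                        "BCa_umol_mol": bca_meas,
                    })
                    # growth: back-computed buoyant masses from the target rate
                    rate = (
                        spp.calcification_mean[it]
                        + tank_eff[sp]["calc"]
                        + rng.normal(0.0, spp.calcification_se[it] * np.sqrt(12.0))
                    )
                    w0 = spp.initial_dry_weight_g * rng.lognormal(
                        0.0, spp.initial_dry_weight_cv
                    )
                    sa = float(p.allometric_sa.surface_area(w0))
                    dry_gain = rate * sa * p.duration_days / 1000.0  # g
                    factor = 1.0 - rho_sw / ARAGONITE_DENSITY
                    gr_rows.append({
                        "colony_id": colony,
                        "buoyant_g_initial": w0 * factor,
                        "buoyant_g_final": (w0 + dry_gain) * factor,
                        "date_initial": date0.date().isoformat(),
                        "date_final": date1.date().isoformat(),
                        "surface_area_cm2": sa,
                    })

    return SyntheticExperiment(
        seawater=pd.DataFrame(sw_rows),
        geochem=pd.DataFrame(geo_rows),
        growth=pd.DataFrame(gr_rows),
        params=p,
        seed=seed,
    )
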