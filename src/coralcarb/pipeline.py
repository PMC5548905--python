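"""End-to-end analysis: tables in, per-colony reconstructions and summaries out.

The pipeline mirrors a mesocosm proxy study: solve the seawater CO2 system
from every (pH_T, A_T) observation and summarize by treatment; reconstruct
each colony's calcifying fluid from its skeletal (delta11B, B/Ca) with
Monte-Carlo uncertainties; compute buoyant-weight calcification rates; then
run the nested-design statistics (tank gate, one-way ANOVA + Tukey) and the
proxy regressions per species.  All randomness flows from a single seed and
outputs are byte-identical across reruns with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boron import BoronConstants, BoronGeochem, resolve_calcifying_fluid
from .carbonate import SeawaterState, equilibrium_constants, solve_from_pH_alkalinity
from .errors import ConfigError
from .growth import AllometricSA, GrowthRecord, net_calcification, seawater_density
from .montecarlo import MCSpec, propagate
from .stats import linear_fit, tank_effect_gate, treatment_test

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "analyze"]

log = logging.getLogger("coralcarb")

SEAWATER_COLUMNS = ["tank_id", "date", "pH_total", "alkalinity_umol_kg", "temperature_C"]
GEOCHEM_COLUMNS = [
    "colony_id", "species", "treatment", "header_tank", "incubation_tank",
    "d11B_permil", "BCa_umol_mol",
]
GROWTH_COLUMNS = [
    "colony_id", "buoyant_g_initial", "buoyant_g_final", "date_initial", "date_final",
]

STAT_RESPONSES = ("calcification", "pH_cf", "DIC_cf_umol_kg", "omega_cf")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    seawater_csv: str
    geochem_csv: str
    growth_csv: str
    out_dir: str = "results"
    salinity: float = 35.5              # used when the seawater table lacks a column
    k1k2: str = "lueker2000"
    btotal: str = "lee2010"
    h_unit: str = "umol"
    mc_iterations: int = 1000
    mc_distribution: str = "gaussian"
    d11B_sd: float = 0.17
    BCa_sd: float = 18.0
    allometric_a: Optional[float] = None
    allometric_b: Optional[float] = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All result tables of one run."""

    seawater_summary: pd.DataFrame     # per-treatment carbonate chemistry
    colonies: pd.DataFrame             # per-colony reconstruction + growth + MC SDs
    treatment_summary: pd.DataFrame    # species x treatment mean +/- SE
    anova: pd.DataFrame                # tank gate + treatment tests per response
    tukey: pd.DataFrame
    regressions: pd.DataFrame          # proxy regressions per species
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("seawater_summary", "colonies", "treatment_summary",
                     "anova", "tukey", "regressions"):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = str(p)
        prov = out / "provenance.json"
        with open(prov, "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
        paths["provenance"] = str(prov)
        return paths


def _require_columns(df: pd.DataFrame, cols, table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigError(f"{table} table missing columns: {missing}")


def _validate_rows(df: pd.DataFrame, cols, table: str) -> None:
    for col in cols:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ConfigError(f"{table} table: missing {col!r} in rows {list(bad[:5])}")


def summarize_seawater(seawater: pd.DataFrame, salinity: float, k1k2: str = "lueker2000",
                       btotal: str = "lee2010") -> pd.DataFrame:
    """Solve every seawater observation and average by treatment.

    Per-observation solving (rather than solving at the treatment-mean pH)
    matches monitoring practice and matters for convex quantities like pCO2.
    """
    _require_columns(seawater, SEAWATER_COLUMNS, "seawater")
    _validate_rows(seawater, ["pH_total", "alkalinity_umol_kg", "temperature_C"], "seawater")
    df = seawater.copy()
    if "salinity" not in df.columns:
        df["salinity"] = salinity
    if "treatment" not in df.columns:
        df["treatment"] = "all"

    sols = []
    for (T, S), grp in df.groupby(["temperature_C", "salinity"]):
        c = equilibrium_constants(T, S, k1k2=k1k2, btotal=btotal)
        state = SeawaterState(
            temperature=T, salinity=S,
            pH_total=grp["pH_total"].to_numpy(),
            alkalinity=grp["alkalinity_umol_kg"].to_numpy() * 1e-6,
        )
        sp = solve_from_pH_alkalinity(state, c)
        sols.append(pd.DataFrame({
            "treatment": grp["treatment"].to_numpy(),
            "pH_total": grp["pH_total"].to_numpy(),
            "alkalinity_umol_kg": grp["alkalinity_umol_kg"].to_numpy(),
            "temperature_C": T,
            "DIC_umol_kg": sp.DIC * 1e6,
            "pCO2_uatm": sp.pCO2,
            "omega_arag": sp.omega_aragonite,
        }, index=grp.index))
    solved = pd.concat(sols).sort_index()

    def _mse(x):
        return x.std(ddof=1) / np.sqrt(len(x))

    agg = solved.groupby("treatment", sort=False).agg(
        pH_total_mean=("pH_total", "mean"), pH_total_se=("pH_total", _mse),
        alkalinity_mean=("alkalinity_umol_kg", "mean"), alkalinity_se=("alkalinity_umol_kg", _mse),
        DIC_mean=("DIC_umol_kg", "mean"), DIC_se=("DIC_umol_kg", _mse),
        pCO2_mean=("pCO2_uatm", "mean"), pCO2_se=("pCO2_uatm", _mse),
        omega_arag_mean=("omega_arag", "mean"), omega_arag_se=("omega_arag", _mse),
        temperature_mean=("temperature_C", "mean"),
        n=("pH_total", "size"),
    ).reset_index()
    order = (
        df.groupby("treatment", sort=False)["pH_total"].mean().sort_values(ascending=False)
    )
    return agg.set_index("treatment").loc[order.index].reset_index()


def analyze(
    seawater: pd.DataFrame,
    geochem: pd.DataFrame,
    growth: pd.DataFrame,
    config: RunConfig,
) -> PipelineResult:
    """Run the full analysis on in-memory tables."""
    _require_columns(geochem, GEOCHEM_COLUMNS, "geochem")
    _validate_rows(geochem, ["colony_id", "d11B_permil", "BCa_umol_mol"], "geochem")
    _require_columns(growth, GROWTH_COLUMNS, "growth")
    _validate_rows(growth, ["colony_id", "buoyant_g_initial", "buoyant_g_final"], "growth")

    boron_consts = BoronConstants(h_unit=config.h_unit)
    sw_summary = summarize_seawater(seawater, config.salinity, config.k1k2, config.btotal)

    # treatment-level (T, S) for the proxy evaluation
    sw = seawater.copy()
    if "salinity" not in sw.columns:
        sw["salinity"] = config.salinity
    env = sw.groupby("treatment").agg(
        temperature=("temperature_C", "mean"), salinity=("salinity", "mean"),
        pH_sw=("pH_total", "mean"),
    )

    mc_spec_base = MCSpec(
        n_iterations=config.mc_iterations,
        d11B_sd=config.d11B_sd,
        BCa_sd=config.BCa_sd,
        distribution=config.mc_distribution,
    )
    allometric = None
    if config.allometric_a is not None and config.allometric_b is not None:
        allometric = AllometricSA(config.allometric_a, config.allometric_b)

    growth_idx = growth.set_index("colony_id")
    rows = []
    for i, rec in enumerate(geochem.itertuples(index=False)):
        if rec.treatment not in env.index:
            raise ConfigError(
                f"geochem row for colony {rec.colony_id!r}: treatment {rec.treatment!r} "
                "absent from seawater table"
            )
        T = float(env.loc[rec.treatment, "temperature"])
        S = float(env.loc[rec.treatment, "salinity"])
        cf = resolve_calcifying_fluid(
            BoronGeochem(d11B=rec.d11B_permil, BCa=rec.BCa_umol_mol),
            T, S, boron_consts, colony_id=rec.colony_id,
        )
        mc = propagate(
            rec.d11B_permil, rec.BCa_umol_mol, T, S,
            spec=MCSpec(**{**mc_spec_base.__dict__, "seed": config.seed + i}),
            constants=boron_consts,
        )
        row = {
            "colony_id": rec.colony_id,
            "species": rec.species,
            "treatment": rec.treatment,
            "header_tank": rec.header_tank,
            "incubation_tank": rec.incubation_tank,
            "pH_sw": float(env.loc[rec.treatment, "pH_sw"]),
            "d11B_permil": rec.d11B_permil,
            "BCa_umol_mol": rec.BCa_umol_mol,
            "pH_cf": float(cf.pH_cf),
            "co3_cf_umol_kg": float(cf.co3_cf * 1e6),
            "DIC_cf_umol_kg": float(cf.DIC_cf * 1e6),
            "omega_cf": float(cf.omega_cf),
            "pH_cf_sd": mc.pH_cf.sd,
            "DIC_cf_sd_umol_kg": mc.DIC_cf.sd * 1e6,
            "omega_cf_sd": mc.omega_cf.sd,
        }
        if rec.colony_id in growth_idx.index:
            g = growth_idx.loc[rec.colony_id]
            rho = float(seawater_density(T, S))
            if "surface_area_cm2" in growth_idx.columns and pd.notna(
                g.get("surface_area_cm2", np.nan)
            ):
                sa = float(g["surface_area_cm2"])
            elif allometric is not None:
                sa = float(allometric.surface_area(
                    float(g["buoyant_g_initial"]) / (1.0 - rho / 2.93)
                ))
            else:
                raise ConfigError(
                    f"growth row for colony {rec.colony_id!r}: no surface_area_cm2 and "
                    "no allometric relation configured"
                )
            row["calcification"] = net_calcification(GrowthRecord(
                colony_id=rec.colony_id,
                buoyant_mass_initial=float(g["buoyant_g_initial"]),
                buoyant_mass_final=float(g["buoyant_g_final"]),
                seawater_density=rho,
                surface_area=sa,
                date_initial=g.get("date_initial"),
                date_final=g.get("date_final"),
            ))
        else:
            row["calcification"] = np.nan
        rows.append(row)
    colonies = pd.DataFrame(rows)

    # species x treatment summary (Table-2 shape)
    def _mse(x):
        return x.std(ddof=1) / np.sqrt(len(x))

    treat_order = env["pH_sw"].sort_values(ascending=False).index.tolist()
    summary = colonies.groupby(["species", "treatment"], sort=False).agg(
        n=("colony_id", "size"),
        calcification_mean=("calcification", "mean"), calcification_se=("calcification", _mse),
        pH_cf_mean=("pH_cf", "mean"), pH_cf_se=("pH_cf", _mse),
        DIC_cf_mean=("DIC_cf_umol_kg", "mean"), DIC_cf_se=("DIC_cf_umol_kg", _mse),
        omega_cf_mean=("omega_cf", "mean"), omega_cf_se=("omega_cf", _mse),
    ).reset_index()
    summary["treatment"] = pd.Categorical(summary["treatment"], categories=treat_order, ordered=True)
    summary = summary.sort_values(["species", "treatment"]).reset_index(drop=True)

    # statistics per species x response
    anova_rows, tukey_frames = [], []
    for sp, sub in colonies.groupby("species"):
        for resp in STAT_RESPONSES:
            if sub[resp].isna().all():
                continue
            gate = tank_effect_gate(sub, resp)
            test = treatment_test(sub, resp)
            anova_rows.append({
                "species": sp, "response": resp,
                "tank_p": gate.p_tank, "tank_decision": gate.decision,
                "treatment_p_over_tank": gate.p_treatment_over_tank,
                "treatment_p_over_residual": gate.p_treatment_over_residual,
                "oneway_F": test.f_value, "oneway_p": test.p_value,
            })
            tk = test.tukey.copy()
            tk.insert(0, "response", resp)
            tk.insert(0, "species", sp)
            tukey_frames.append(tk)
    anova = pd.DataFrame(anova_rows)
    tukey = pd.concat(tukey_frames, ignore_index=True) if tukey_frames else pd.DataFrame()

    reg_rows = []
    for sp, sub in colonies.groupby("species"):
        for name, xcol, ycol in (
            ("d11B_vs_pHsw", "pH_sw", "d11B_permil"),
            ("pHcf_vs_pHsw", "pH_sw", "pH_cf"),
            ("BCa_vs_d11B", "d11B_permil", "BCa_umol_mol"),
        ):
            fit = linear_fit(sub[xcol], sub[ycol])
            reg_rows.append({
                "species": sp, "regression": name,
                "slope": fit.slope, "intercept": fit.intercept,
                "slope_se": fit.stderr_slope, "p_value": fit.p_value,
                "r_squared": fit.r_squared,
            })
    regressions = pd.DataFrame(reg_rows)

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "constants": equilibrium_constants(
            21.0, config.salinity, k1k2=config.k1k2, btotal=config.btotal
        ).provenance,
        "n_colonies": int(len(colonies)),
        "n_seawater_obs": int(len(seawater)),
    }
    return PipelineResult(
        seawater_summary=sw_summary,
        colonies=colonies,
        treatment_summary=summary,
        anova=anova,
        tukey=tukey,
        regressions=regressions,
        provenance=provenance,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load the input CSVs, run :func:`analyze`, and write all outputs."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for path in (config.seawater_csv, config.geochem_csv, config.growth_csv):
        if not Path(path).exists():
            raise ConfigError(f"input file not found: {path}")
    seawater = pd.read_csv(config.seawater_csv)
    geochem = pd.read_csv(config.geochem_csv)
    growth = pd.read_csv(config.growth_csv)
    log.info("loaded %d seawater obs, %d colonies", len(seawater), len(geochem))
    result = analyze(seawater, geochem, growth, config)
    paths = result.write(config.out_dir)
    log.info("wrote results to %s", config.out_dir)
    result.provenance["outputs"] = paths
    return result
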