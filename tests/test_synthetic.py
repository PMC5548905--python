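"""Synthetic mesocosm generator: design structure and parameter recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import coralcarb as cc
from coralcarb.errors import ConfigError

from conftest import D11B_REGRESSIONS, SALINITY, TREATMENTS


def _noise_free_params():
    species = {
        sp: dataclasses.replace(p, d11B_colony_sd=0.0, bca_resid_sd=0.0,
                                initial_dry_weight_cv=0.0,
                                calcification_se=(0.0,) * len(p.calcification_se))
        for sp, p in cc.GeneratorParams().species.items()
    }
    return cc.GeneratorParams(
        pH_obs_sd=0.0, pH_tank_sd=0.0, alkalinity_sd=0.0,
        d11B_analytical_sd=0.0, bca_analytical_sd=0.0,
        tank_variance_fraction=0.0, species=species,
    )


class TestDesignStructure:
    def test_colony_and_tank_counts(self, synthetic_experiment):
        geo = synthetic_experiment.geochem
        assert len(geo) == 72                          # 2 species x 36 colonies
        assert geo["species"].nunique() == 2
        assert geo.groupby(["species", "treatment"]).size().eq(12).all()
        # 4 header tanks per treatment, 3 incubation tanks per header
        tanks = geo.groupby("treatment")["header_tank"].nunique()
        assert tanks.eq(4).all()
        per_header = geo.groupby(["species", "header_tank"])["incubation_tank"].nunique()
        assert per_header.eq(3).all()
        # one colony per species per incubation tank
        assert geo.groupby(["species", "incubation_tank"]).size().eq(1).all()

    def test_seawater_table_covers_all_tanks(self, synthetic_experiment):
        sw = synthetic_experiment.seawater
        assert sw["tank_id"].nunique() == 36
        assert set(sw.columns) >= {
            "tank_id", "date", "pH_total", "alkalinity_umol_kg", "temperature_C", "salinity"
        }

    def test_deterministic_under_seed(self):
        a = cc.generate_experiment(seed=11)
        b = cc.generate_experiment(seed=11)
        pd.testing.assert_frame_equal(a.geochem, b.geochem)
        pd.testing.assert_frame_equal(a.seawater, b.seawater)
        pd.testing.assert_frame_equal(a.growth, b.growth)

    def test_invalid_design_rejected(self):
        with pytest.raises(ConfigError):
            cc.GeneratorParams(n_header_per_treatment=1)
        with pytest.raises(ConfigError):
            cc.GeneratorParams(target_pH=(8.09, 7.81))


class TestNoiseFreeDegenerate:
    def test_regressions_reproduced_exactly(self):
        """With all noise off, delta11B and B/Ca sit exactly on the generating
        regressions and buoyant weights encode the exact target rates."""
        exp = cc.generate_experiment(_noise_free_params(), seed=0)
        for sp, (slope, intercept) in D11B_REGRESSIONS.items():
            sub = exp.geochem[exp.geochem["species"] == sp]
            for (pH_sw, _T), tr in zip(TREATMENTS, exp.params.treatments):
                got = sub.loc[sub["treatment"] == tr, "d11B_permil"]
                assert np.allclose(got, slope * pH_sw + intercept, atol=1e-12)
        # growth identity: net_calcification recovers the configured means
        merged = exp.geochem.merge(exp.growth, on="colony_id")
        for sp, p in exp.params.species.items():
            for i, tr in enumerate(exp.params.treatments):
                sub = merged[(merged["species"] == sp) & (merged["treatment"] == tr)]
                T = exp.params.temperature[i]
                rho = float(cc.seawater_density(T, SALINITY))
                rates = [
                    cc.net_calcification(cc.GrowthRecord(
                        r.colony_id, r.buoyant_g_initial, r.buoyant_g_final,
                        rho, r.surface_area_cm2, r.date_initial, r.date_final,
                    ))
                    for r in sub.itertuples(index=False)
                ]
                assert np.allclose(rates, p.calcification_mean[i], atol=1e-9)


@pytest.fixture(scope="module")
def recovery():
    """Proxy regressions and treatment means over 20 seeds."""
    slopes = {sp: {"d11B": [], "pHcf": []} for sp in D11B_REGRESSIONS}
    phcf_means = {sp: [] for sp in D11B_REGRESSIONS}
    calc_decline = []
    for seed in range(20):
        exp = cc.generate_experiment(seed=seed)
        geo = exp.geochem.copy()
        tank_pH = exp.seawater.groupby("tank_id")["pH_total"].mean()
        geo["pH_sw"] = geo["incubation_tank"].map(tank_pH)
        temps = dict(zip(exp.params.treatments, exp.params.temperature))
        geo["pH_cf"] = [
            float(cc.pHcf_from_d11B(r.d11B_permil, temps[r.treatment], SALINITY))
            for r in geo.itertuples(index=False)
        ]
        merged = geo.merge(exp.growth, on="colony_id")
        rho = float(cc.seawater_density(21.0, SALINITY))
        merged["rate"] = [
            cc.net_calcification(cc.GrowthRecord(
                r.colony_id, r.buoyant_g_initial, r.buoyant_g_final,
                rho, r.surface_area_cm2, r.date_initial, r.date_final,
            ))
            for r in merged.itertuples(index=False)
        ]
        for sp in D11B_REGRESSIONS:
            sub = geo[geo["species"] == sp]
            slopes[sp]["d11B"].append(cc.linear_fit(sub["pH_sw"], sub["d11B_permil"]).slope)
            slopes[sp]["pHcf"].append(cc.linear_fit(sub["pH_sw"], sub["pH_cf"]).slope)
            phcf_means[sp].append(
                sub.groupby("treatment", sort=False)["pH_cf"].mean().to_numpy()
            )
        ay = merged[merged["species"] == "A_youngei"]
        m = ay.groupby("treatment", sort=False)["rate"].mean()
        calc_decline.append(1.0 - m["pH7.6"] / m["pH8.1"])
    return slopes, phcf_means, calc_decline

class TestParameterRecovery:
    @pytest.mark.parametrize(
        "species, key, target",
        [
            ("A_youngei", "d11B", 2.37),
            ("P_damicornis", "d11B", 4.37),
            ("A_youngei", "pHcf", 0.157),
            ("P_damicornis", "pHcf", 0.30),
        ],
    )
    def test_regression_slopes_recovered(self, recovery, species, key, target):
        """Mean recovered slope lies within 2 SE of the generating slope."""
        vals = np.asarray(recovery[0][species][key])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - target) <= 2 * se + 1e-9

    def test_phcf_treatment_means_recovered(self, recovery):
        """Treatment-mean pH_cf across seeds is within 2 SE of the published
        species x treatment values."""
        published = {
            "A_youngei": (8.51, 8.46, 8.44),
            "P_damicornis": (8.48, 8.40, 8.35),
        }
        for sp, arrs in recovery[1].items():
            arr = np.vstack(arrs)
            mean = arr.mean(axis=0)
            se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
            # analytic-vs-published rounding adds up to ~0.01
            assert np.all(np.abs(mean - published[sp]) <= 2 * se + 0.01)

    def test_calcification_decline_band(self, recovery):
        """The fast calcifier's relative decline from ambient to the lowest pH
        falls in the 25-40% band."""
        decline = float(np.mean(recovery[2]))
        assert 0.25 <= decline <= 0.40
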