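"""Nested-design statistics: tank gate, one-way ANOVA + Tukey, regressions."""

import numpy as np
import pandas as pd
import pytest

import coralcarb as cc
from coralcarb.errors import DesignError


def nested_table(rng, treatment_effects=(0.0, 0.0, 0.0), tank_sd=0.0, resid_sd=1.0,
                 n_tanks=4, n_reps=3):
    """Balanced 3-treatment x 4-header-tank x 3-replicate design table."""
    rows = []
    tank_id = 0
    for t, eff in enumerate(treatment_effects):
        for _ in range(n_tanks):
            tank_id += 1
            tank_eff = rng.normal(0, tank_sd) if tank_sd > 0 else 0.0
            for r in range(n_reps):
                rows.append({
                    "treatment": f"T{t}",
                    "header_tank": f"H{tank_id:02d}",
                    "y": eff + tank_eff + rng.normal(0, resid_sd),
                })
    return pd.DataFrame(rows)


class TestTankGate:
    def test_zero_tank_variance_drop_rate_matches_uniform_p(self):
        """With no tank variance the tank p-value is uniform, so the p > 0.25
        rule drops the tank term in ~75% of simulated experiments."""
        rng = np.random.default_rng(101)
        dropped = sum(
            cc.tank_effect_gate(nested_table(rng), "y").decision == "drop_tank"
            for _ in range(200)
        )
        assert 0.65 * 200 <= dropped <= 0.85 * 200

    def test_strong_tank_effects_kept(self):
        """Tank variance far above residual variance triggers keep_tank."""
        rng = np.random.default_rng(7)
        kept = sum(
            cc.tank_effect_gate(
                nested_table(rng, tank_sd=5.0, resid_sd=0.5), "y"
            ).decision == "keep_tank"
            for _ in range(100)
        )
        assert kept >= 95

    def test_constant_response_degenerate(self):
        rng = np.random.default_rng(0)
        df = nested_table(rng)
        df["y"] = 3.0
        res = cc.tank_effect_gate(df, "y")
        assert res.decision == "drop_tank"
        assert res.p_tank == 1.0

    def test_both_treatment_denominators_reported(self):
        rng = np.random.default_rng(3)
        res = cc.tank_effect_gate(nested_table(rng, treatment_effects=(0, 1, 2)), "y")
        assert 0 <= res.p_treatment_over_tank <= 1
        assert 0 <= res.p_treatment_over_residual <= 1
        # over-residual has many more denominator df, so it is at least as powerful
        assert res.p_treatment_over_residual <= res.p_treatment_over_tank + 0.1

    def test_design_validation(self):
        rng = np.random.default_rng(0)
        df = nested_table(rng, n_tanks=1)
        with pytest.raises(DesignError, match="fewer than 2 header tanks"):
            cc.tank_effect_gate(df, "y")
        df2 = nested_table(rng)
        df2.loc[df2.index[df2["header_tank"] == "H01"][0], "treatment"] = "T2"
        with pytest.raises(DesignError, match="multiple treatments"):
            cc.tank_effect_gate(df2, "y")


class TestTreatmentTest:
    def test_identical_groups_null(self):
        """Three identical groups give F = 0, p = 1 and no significant pairs."""
        vals = [1.0, 2.0, 3.0, 4.0]
        df = pd.DataFrame({
            "treatment": np.repeat(["A", "B", "C"], 4),
            "y": vals * 3,
        })
        res = cc.treatment_test(df, "y")
        assert res.p_value == pytest.approx(1.0)
        assert not res.tukey["reject"].astype(bool).any()

    def test_acropora_like_decline_detected(self):
        """Calcification means declining from 1.97 to 1.34 with published SEs
        are detected (p < 0.05) in >= 90% of simulated experiments, and the
        strong p < 0.001 outcome occurs in a substantial fraction."""
        rng = np.random.default_rng(21)
        h05 = h001 = 0
        n_sim = 50
        for _ in range(n_sim):
            df = nested_table(
                rng, treatment_effects=(1.97, 1.65, 1.34), tank_sd=0.0,
                resid_sd=0.11 * np.sqrt(12),
            )
            p = cc.treatment_test(df, "y").p_value
            h05 += p < 0.05
            h001 += p < 0.001
        assert h05 >= 0.9 * n_sim
        assert h001 >= 0.4 * n_sim

    def test_pocillopora_like_flat_response(self):
        """Flat means (1.07, 1.00, 0.97) with SE 0.08 stay non-significant in
        >= 80% of simulated experiments."""
        rng = np.random.default_rng(22)
        hits = 0
        n_sim = 30
        for _ in range(n_sim):
            df = nested_table(
                rng, treatment_effects=(1.07, 1.00, 0.97),
                resid_sd=0.08 * np.sqrt(12),
            )
            hits += cc.treatment_test(df, "y").p_value > 0.05
        assert hits >= 0.8 * n_sim

    def test_tukey_intervals_contain_raw_differences(self):
        rng = np.random.default_rng(5)
        df = nested_table(rng, treatment_effects=(0.0, 0.7, 1.5))
        res = cc.treatment_test(df, "y")
        means = df.groupby("treatment")["y"].mean()
        for row in res.tukey.itertuples(index=False):
            diff = means[row.group2] - means[row.group1]
            assert row.lower <= diff <= row.upper
            assert float(row.meandiff) == pytest.approx(diff, abs=1e-9)

    def test_familywise_error_under_null(self):
        """Under the global null, any-pair rejection rate stays near 0.05."""
        rng = np.random.default_rng(99)
        n_sim = 400
        rejections = 0
        for _ in range(n_sim):
            df = pd.DataFrame({
                "treatment": np.repeat(["A", "B", "C"], 12),
                "y": rng.normal(0, 1, 36),
            })
            res = cc.treatment_test(df, "y")
            rejections += res.tukey["reject"].astype(bool).any()
        rate = rejections / n_sim
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"treatment": ["A"] * 5, "y": np.arange(5.0)})
        with pytest.raises(DesignError):
            cc.treatment_test(df, "y")


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = cc.linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_slope_p_value_matches_scipy(self):
        from scipy.stats import linregress

        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 30)
        y = 0.5 * x + rng.normal(0, 1, 30)
        fit = cc.linear_fit(x, y)
        ref = linregress(x, y)
        assert fit.slope == pytest.approx(ref.slope, rel=1e-10)
        assert fit.p_value == pytest.approx(ref.pvalue, rel=1e-8)
        assert fit.stderr_slope == pytest.approx(ref.stderr, rel=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DesignError):
            cc.linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(DesignError):
            cc.linear_fit([1.0, 2.0], [1.0, 2.0])
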