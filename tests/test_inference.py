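import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secsim.inference import (
    PowerModelConfig,
    classify_community,
    classify_telematics,
    classify_traffic,
    crash_relative_risk,
    build_crash_risk_table,
    fit_rud_regression,
    spillover_linearity,
)


def synthetic_results(rng, n=200, noise_sd=0.5, coefs=None):
    """Results table with a known linear RUD structure."""
    coefs = coefs or dict(
        const=30.0, FIX2=-0.5, FIX3=-1.0, P2P=-10.0,
        demand=-3.0, b=0.6, c=0.7, tel=-0.2,
    )
    df = pd.DataFrame(
        {
            "sec_type": rng.choice(["FIX1", "FIX2", "FIX3", "P2P"], n),
            "telematics_pct": rng.integers(0, 11, n).astype(float),
            "pct_B": rng.choice(range(10, 55, 5), n).astype(float),
            "pct_C": rng.choice(range(1, 6), n).astype(float),
            "demand_vph": rng.choice(range(500, 4000, 500), n).astype(float),
        }
    )
    df["rud_pct"] = (
        coefs["const"]
        + coefs["FIX2"] * (df.sec_type == "FIX2")
        + coefs["FIX3"] * (df.sec_type == "FIX3")
        + coefs["P2P"] * (df.sec_type == "P2P")
        + coefs["demand"] * df.demand_vph / 1000
        + coefs["b"] * df.pct_B
        + coefs["c"] * df.pct_C
        + coefs["tel"] * df.telematics_pct
        + rng.normal(0, noise_sd, n)
    )
    return df


class TestRudRegression:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        coefs = dict(const=5.0, FIX2=0.0, FIX3=0.0, P2P=0.0,
                     demand=0.0, b=0.0, c=0.0, tel=-0.3)
        df = synthetic_results(rng, n=2000, noise_sd=0.01, coefs=coefs)
        fit = fit_rud_regression(df)
        assert -0.31 < fit.params["telematics_pct"] < -0.29

    def test_noise_free_fit_is_perfect(self):
        rng = np.random.default_rng(2)
        df = synthetic_results(rng, n=300, noise_sd=0.0)
        fit = fit_rud_regression(df)
        assert fit.rsquared_adj == pytest.approx(1.0, abs=1e-10)
        assert fit.params["sec_P2P"] == pytest.approx(-10.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        df = synthetic_results(rng, n=50, noise_sd=2.0)
        fit = fit_rud_regression(df)
        X = fit.model.exog.to_numpy()
        y = fit.model.endog
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-8)

    def test_confidence_interval_consistency(self):
        rng = np.random.default_rng(4)
        fit = fit_rud_regression(synthetic_results(rng, n=400))
        ci = fit.conf_int()
        half = 1.96 * fit.bse
        np.testing.assert_allclose(
            ci["ci_high"] - fit.params, half, rtol=2e-2
        )

    def test_rank_deficient_design_named(self):
        rng = np.random.default_rng(5)
        df = synthetic_results(rng, n=100)
        df["telematics_pct"] = 0.0  # constant column, collinear with intercept
        with pytest.raises(ValueError, match="collinear.*telematics_pct"):
            fit_rud_regression(df)

    def test_missing_column_named(self):
        with pytest.raises(KeyError, match="rud_pct"):
            fit_rud_regression(pd.DataFrame({"sec_type": ["FIX1", "FIX2"]}))

    def test_small_p_values_formatted(self):
        rng = np.random.default_rng(6)
        fit = fit_rud_regression(synthetic_results(rng, n=500, noise_sd=0.1))
        table = fit.to_frame()
        assert "<0.001" in set(table["p"])


class TestClassifiers:
    @pytest.mark.parametrize(
        "b, c, expected",
        [
            (15, 1, "law-abiding"),
            (10, 2, "law-abiding"),
            (25, 3, "average"),
            (40, 3, "law-avoiding"),
            (50, 3, "law-avoiding"),
            (25, 5, "law-carefree"),
            (20, 4, "law-carefree"),
            (50, 5, None),
            (30, 1, None),
            (10, 3, None),
            # boundary tie: B=20, C=3 belongs to "average" by priority
            (20, 3, "average"),
            (30, 3, "average"),
        ],
    )
    def test_community(self, b, c, expected):
        assert classify_community(b, c) == expected

    @pytest.mark.parametrize(
        "demand, expected",
        [(500, "low"), (1000, "low"), (1500, "low"), (2000, None),
         (2500, "moderate"), (3000, "moderate"), (3500, "moderate"), (4000, None)],
    )
    def test_traffic(self, demand, expected):
        assert classify_traffic(demand) == expected

    def test_traffic_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            classify_traffic(0)

    @pytest.mark.parametrize(
        "pct, expected",
        [(0, "none"), (1, "none"), (5, None), (8, "enforcement"),
         (9, "enforcement"), (10, "enforcement"), (50, None)],
    )
    def test_telematics(self, pct, expected):
        assert classify_telematics(pct) == expected


class TestPowerModel:
    def test_identity(self):
        rr, pct = crash_relative_risk(90.0, 90.0)
        assert rr == pytest.approx(1.0, abs=1e-12)
        assert pct == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_cubes(self):
        rr, pct = crash_relative_risk(100.0, 90.0)
        assert rr == pytest.approx(0.729, abs=1e-12)
        assert pct == pytest.approx(-27.1, abs=1e-10)
        rr, pct = crash_relative_risk(80.0, 88.0)
        assert rr == pytest.approx(1.331, abs=1e-12)
        assert pct == pytest.approx(33.1, abs=1e-10)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError):
            crash_relative_risk(0.0, 90.0)
        with pytest.raises(ValueError):
            PowerModelConfig(exponent=0.0)

    @given(
        a=st.floats(30.0, 150.0),
        b=st.floats(30.0, 150.0),
        c=st.floats(30.0, 150.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_chain_consistency_and_monotonicity(self, a, b, c):
        rr_ab = crash_relative_risk(a, b)[0]
        rr_bc = crash_relative_risk(b, c)[0]
        rr_ac = crash_relative_risk(a, c)[0]
        assert rr_ab * rr_bc == pytest.approx(rr_ac, rel=1e-9)
        if b > c:
            assert rr_ab > rr_ac  # monotone increasing in the alternative speed


def cell_results_frame(speed_by_sec, b=25, c=3, tel=0, demand=1000):
    rows = []
    for sec, v in speed_by_sec.items():
        rows.append(
            dict(
                sec_type=sec, pct_B=b, pct_C=c, telematics_pct=tel,
                demand_vph=demand, rud_pct=10.0,
                distance_vkm=v * 10.0, time_vh=10.0,
            )
        )
    return pd.DataFrame(rows)


class TestCrashRiskTable:
    def test_identical_speeds_give_zero_change(self):
        df = cell_results_frame({s: 85.0 for s in ("FIX1", "FIX2", "FIX3", "P2P")})
        tab = build_crash_risk_table(df)
        assert np.allclose(tab["pct_change"], 0.0)

    def test_hand_computed_p2p_change(self):
        df = cell_results_frame({"FIX1": 100.0, "P2P": 96.4})
        tab = build_crash_risk_table(df)
        assert len(tab) == 1
        assert tab["pct_change"].iloc[0] == pytest.approx(100 * (0.964**3 - 1), abs=1e-9)

    def test_missing_reference_is_hard_error(self):
        df = cell_results_frame({"FIX2": 85.0, "P2P": 80.0})
        with pytest.raises(ValueError, match="FIX1"):
            build_crash_risk_table(df)

    def test_unclassified_rows_are_omitted(self):
        df = cell_results_frame({"FIX1": 85.0, "P2P": 80.0}, b=30, c=1)  # no community
        assert build_crash_risk_table(df).empty

    def test_full_grid_cell_count(self):
        """All 4 communities x 2 traffic x 2 telematics cells, 3 comparisons."""
        frames = []
        reps = {
            "law-abiding": (15, 1), "average": (25, 3),
            "law-avoiding": (40, 3), "law-carefree": (25, 5),
        }
        for (comm, (b, c)), d, t in itertools.product(
            reps.items(), (1000, 3000), (0, 9)
        ):
            frames.append(
                cell_results_frame(
                    {s: 85.0 for s in ("FIX1", "FIX2", "FIX3", "P2P")},
                    b=b, c=c, tel=t, demand=d,
                )
            )
        tab = build_crash_risk_table(pd.concat(frames, ignore_index=True))
        assert len(tab) == 4 * 2 * 2 * 3

    def test_pooled_speed_is_distance_over_time(self):
        # two runs of the same layout pool their distance and time first
        df = pd.concat(
            [
                cell_results_frame({"FIX1": 80.0, "P2P": 80.0}),
                cell_results_frame({"FIX1": 100.0, "P2P": 80.0}),
            ],
            ignore_index=True,
        )
        tab = build_crash_risk_table(df)
        assert tab.mean_speed_ref.iloc[0] == pytest.approx(90.0)  # (800+1000)/20


class TestSpilloverLinearity:
    def grid(self, f):
        rows = []
        for tel in range(10, 100, 10):
            rows.append(
                dict(sec_type="FIX1", demand_vph=2000, telematics_pct=tel,
                     rud_pct=f(tel))
            )
        return pd.DataFrame(rows)

    def test_exact_line_recovered(self):
        out = spillover_linearity(self.grid(lambda t: 20 - 0.2 * t))
        assert out.r_squared.iloc[0] == pytest.approx(1.0)
        assert out.slope.iloc[0] == pytest.approx(-0.2)
        assert out.max_abs_residual.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_input_flagged(self):
        out = spillover_linearity(self.grid(lambda t: 0.01 * (t - 50) ** 2))
        assert out.r_squared.iloc[0] < 1.0
        assert out.max_abs_residual.iloc[0] > 1.0

    def test_too_few_levels_rejected(self):
        df = self.grid(lambda t: t)[:2]
        with pytest.raises(ValueError, match="levels"):
            spillover_linearity(df)
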