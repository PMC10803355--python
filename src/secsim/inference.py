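"""Statistical analysis of simulated scenario results.

Three pieces:

* an OLS regression of the ratio of unsafe driving (RUD, percent) on the
  scenario factors — camera-layout indicators (one fixed camera as the
  reference), traffic demand per 1000 VPH, the two violator-group shares and
  the telematics share — exposed statsmodels-style as
  :class:`RudRegression` / :class:`RudRegressionResults`;
* classifiers mapping grid cells into implementation scenarios (community
  behaviour × traffic level × telematics level);
* the Nilsson Power Model translation of mean-speed changes into crash
  relative risk, RR = (v_alt / v_ref)^n with n = 3 for fatal and serious
  injury crashes, and the resulting camera-comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RudRegression",
    "RudRegressionResults",
    "PowerModelConfig",
    "classify_community",
    "classify_traffic",
    "classify_telematics",
    "crash_relative_risk",
    "build_crash_risk_table",
    "spillover_linearity",
]

REGRESSORS = [
    "const",
    "sec_FIX2",
    "sec_FIX3",
    "sec_P2P",
    "demand_kvph",
    "pct_B",
    "pct_C",
    "telematics_pct",
]

COMMUNITIES = ("law-abiding", "average", "law-avoiding", "law-carefree")


# --------------------------------------------------------------------------
# RUD regression (Model / Results pair)


class RudRegression:
    """OLS of per-run RUD (percent) on the scenario design factors.

    Camera layout enters as indicators for FIX2, FIX3 and P2P with the single
    fixed camera (FIX1) as reference; demand enters per 1000 VPH; group
    shares and telematics share enter in percent. Classical (non-robust)
    standard errors, alpha = 0.05.
    """

    def __init__(self, endog: np.ndarray, exog: pd.DataFrame):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        rank = np.linalg.matrix_rank(exog.to_numpy())
        if rank < exog.shape[1]:
            # name the offending columns for the caller
            bad = [
                c
                for c in exog.columns
                if c != "const"
                and np.linalg.matrix_rank(exog.drop(columns=c).to_numpy()) == rank
            ]
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    @classmethod
    def from_results(cls, results: pd.DataFrame) -> "RudRegression":
        """Build the design from a scenario-results table (see run_batch)."""
        required = ["rud_pct", "sec_type", "demand_vph", "pct_B", "pct_C", "telematics_pct"]
        missing = [c for c in required if c not in results.columns]
        if missing:
            raise KeyError(f"results table missing columns: {missing}")
        if results["rud_pct"].isna().any():
            raise ValueError("missing RUD outcomes in results table")
        counts = results["sec_type"].value_counts()
        thin = [s for s, n in counts.items() if n < 2]
        if thin:
            raise ValueError(f"need >= 2 rows per SEC type; too few for {thin}")
        exog = pd.DataFrame(
            {
                "const": 1.0,
                "sec_FIX2": (results["sec_type"] == "FIX2").astype(float),
                "sec_FIX3": (results["sec_type"] == "FIX3").astype(float),
                "sec_P2P": (results["sec_type"] == "P2P").astype(float),
                "demand_kvph": results["demand_vph"] / 1000.0,
                "pct_B": results["pct_B"].astype(float),
                "pct_C": results["pct_C"].astype(float),
                "telematics_pct": results["telematics_pct"].astype(float),
            }
        )
        return cls(results["rud_pct"].to_numpy(), exog)

    def fit(self) -> "RudRegressionResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return RudRegressionResults(self, res)


class RudRegressionResults:
    """Estimates, uncertainties and diagnostics of a fitted RUD regression."""

    def __init__(self, model: RudRegression, sm_results):
        self.model = model
        self._sm = sm_results

    @property
    def params(self) -> pd.Series:
        return self._sm.params

    @property
    def bse(self) -> pd.Series:
        return self._sm.bse

    @property
    def tvalues(self) -> pd.Series:
        return self._sm.tvalues

    @property
    def pvalues(self) -> pd.Series:
        return self._sm.pvalues

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._sm.conf_int(alpha)
        ci.columns = ["ci_low", "ci_high"]
        return ci

    @property
    def rsquared(self) -> float:
        return float(self._sm.rsquared)

    @property
    def rsquared_adj(self) -> float:
        return float(self._sm.rsquared_adj)

    @property
    def nobs(self) -> int:
        return int(self._sm.nobs)

    def summary(self):
        return self._sm.summary(xname=list(self.model.exog.columns))

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table in the reporting layout (one row per variable)."""
        ci = self.conf_int()
        pstr = [
            "<0.001" if p < 0.001 else f"{p:.3f}" for p in self.pvalues
        ]
        return pd.DataFrame(
            {
                "variable": list(self.model.exog.columns),
                "coefficient": self.params.to_numpy(),
                "ci_low": ci["ci_low"].to_numpy(),
                "ci_high": ci["ci_high"].to_numpy(),
                "se": self.bse.to_numpy(),
                "t": self.tvalues.to_numpy(),
                "p": pstr,
            }
        )


def fit_rud_regression(results: pd.DataFrame) -> RudRegressionResults:
    """Convenience wrapper: build and fit the RUD regression in one call."""
    return RudRegression.from_results(results).fit()


# --------------------------------------------------------------------------
# Implementation-scenario classifiers


def classify_community(pct_b: float, pct_c: float) -> str | None:
    """Community-behaviour class of a (%B, %C) composition.

    law-abiding: B 10-20, C 1-2; average: B 20-30, C 3; law-avoiding:
    B 35-50, C 3; law-carefree: B 20-30, C 4-5. Exact boundary ties resolve
    in that priority order; compositions outside every range return None.
    """
    if 10 <= pct_b <= 20 and 1 <= pct_c <= 2:
        return "law-abiding"
    if 20 <= pct_b <= 30 and pct_c == 3:
        return "average"
    if 35 <= pct_b <= 50 and pct_c == 3:
        return "law-avoiding"
    if 20 <= pct_b <= 30 and 4 <= pct_c <= 5:
        return "law-carefree"
    return None


def classify_traffic(demand_vph: float) -> str | None:
    """Traffic level: 500-1500 VPH low, 2500-3500 moderate, otherwise None
    (2000 VPH sits in the gap between the defined bins)."""
    if demand_vph <= 0:
        raise ValueError("demand must be positive")
    if 500 <= demand_vph <= 1500:
        return "low"
    if 2500 <= demand_vph <= 3500:
        return "moderate"
    return None


def classify_telematics(pct: float) -> str | None:
    """Telematics level: 0-1 % none, 8-10 % enforcement, otherwise None."""
    if not 0 <= pct <= 100:
        raise ValueError(f"percent out of range: {pct}")
    if pct <= 1:
        return "none"
    if 8 <= pct <= 10:
        return "enforcement"
    return None


# --------------------------------------------------------------------------
# Power Model crash-risk translation


@dataclass(frozen=True)
class PowerModelConfig:
    """Exponent of the Power Model; n = 3 links mean speed to fatal and
    serious injury crash risk."""

    exponent: float = 3.0

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")


def crash_relative_risk(
    mean_speed_ref: float,
    mean_speed_alt: float,
    config: PowerModelConfig = PowerModelConfig(),
) -> tuple[float, float]:
    """Relative crash risk of the alternative vs the reference scenario.

    RR = (v_alt / v_ref)^n; also returns the percent change 100·(RR − 1).
    """
    if mean_speed_ref <= 0 or mean_speed_alt <= 0:
        raise ValueError("mean speeds must be positive")
    rr = (mean_speed_alt / mean_speed_ref) ** config.exponent
    return float(rr), float(100.0 * (rr - 1.0))


COMPARISONS = [("FIX2", "FIX2-vs-FIX1"), ("FIX3", "FIX3-vs-FIX1"), ("P2P", "P2P-vs-FIX1")]


def build_crash_risk_table(
    results: pd.DataFrame, config: PowerModelConfig = PowerModelConfig()
) -> pd.DataFrame:
    """Camera-layout crash-risk comparisons per implementation cell.

    Rows of ``results`` are pooled into (community × traffic × telematics)
    cells; within a cell the pooled space-mean speed per camera layout is
    total distance / total time across all scenario-seed runs; each layout is
    compared with the single fixed camera via the Power Model. Cells with no
    classified data are omitted; a populated cell lacking its FIX1 reference
    is an error.
    """
    df = results.copy()
    df["community"] = [
        classify_community(b, c) for b, c in zip(df["pct_B"], df["pct_C"])
    ]
    df["traffic"] = df["demand_vph"].map(classify_traffic)
    df["telematics"] = df["telematics_pct"].map(classify_telematics)
    df = df.dropna(subset=["community", "traffic", "telematics"])

    rows = []
    for (comm, traf, tele), cell in df.groupby(["community", "traffic", "telematics"]):
        pooled = cell.groupby("sec_type").agg(
            distance_vkm=("distance_vkm", "sum"), time_vh=("time_vh", "sum")
        )
        speed = pooled["distance_vkm"] / pooled["time_vh"]
        if "FIX1" not in speed.index:
            raise ValueError(
                f"cell ({comm}, {traf}, {tele}) lacks the FIX1 reference"
            )
        ref = float(speed["FIX1"])
        for sec, label in COMPARISONS:
            if sec not in speed.index:
                continue
            rr, pct = crash_relative_risk(ref, float(speed[sec]), config)
            rows.append(
                {
                    "community": comm,
                    "traffic": traf,
                    "telematics": tele,
                    "comparison": label,
                    "mean_speed_ref": ref,
                    "mean_speed_alt": float(speed[sec]),
                    "relative_risk": rr,
                    "pct_change": pct,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Spill-over linearity


def spillover_linearity(spillover_results: pd.DataFrame) -> pd.DataFrame:
    """Linear fit of mean RUD vs telematics % per (camera layout × demand).

    A near-linear decline (high R²) indicates the absence of a spill-over
    effect at high telematics penetration. Reports slope, intercept, R² and
    the maximum absolute residual per group.
    """
    rows = []
    for (sec, demand), g in spillover_results.groupby(["sec_type", "demand_vph"]):
        means = g.groupby("telematics_pct")["rud_pct"].mean()
        if len(means) < 3:
            raise ValueError(
                f"need >= 3 telematics levels for ({sec}, {demand}), got {len(means)}"
            )
        x = means.index.to_numpy(dtype=float)
        y = means.to_numpy(dtype=float)
        slope, intercept = np.polyfit(x, y, 1)
        fitted = slope * x + intercept
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        rows.append(
            {
                "sec_type": sec,
                "demand_vph": demand,
                "slope": float(slope),
                "intercept": float(intercept),
                "r_squared": r2,
                "max_abs_residual": float(np.abs(y - fitted).max()),
            }
        )
    return pd.DataFrame(rows)
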