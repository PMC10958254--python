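"""Baseline predictors of 12-month RORA growth.

Growth is regressed on three baseline biomarkers — the PRD/RPE-loss area
ratio, isolated PRD area and intact-macula area — with ordinary least
squares; the coefficient of determination is reported from bootstrapped
refits (resampling eyes with replacement, 100 resamples by default).
Quartile stratification of a baseline variable summarises growth per
quartile and tests monotonicity.

Growth can be measured either as √area change (mm, default — the scale
on which GA growth is linear in time) or as raw area change (mm²); both
are supported and the choice is recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

PREDICTORS = ("ratio_prd_rpe", "prd_isolated_mm2", "intact_macula_mm2")


@dataclass
class RegressionReport:
    """OLS coefficients with p-values plus the bootstrap R² summary."""

    coefficients: pd.DataFrame  # term, coef, se, p, boot_low, boot_high
    r2_insample: float
    r2_boot_mean: float
    r2_boot_ci: tuple[float, float]
    n: int
    n_boot: int
    seed: int
    response: str

    def coef(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "coef"])

    def pvalue(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "p"])


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res < 1e-12 else 0.0
    return 1.0 - ss_res / ss_tot


def bootstrap_ols(
    X: np.ndarray,
    y: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
    indices: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """OLS refits on eye-level bootstrap resamples.

    Returns (R² per resample, coefficient matrix of shape n_boot × p).
    ``indices`` overrides the random resampling (one array of row indices
    per resample); a single identity resample reproduces the in-sample
    fit.  Degenerate resamples (zero predictor variance) fall back to the
    least-norm solution with R² = 0 unless the fit is exact.
    """
    n = len(y)
    rng = np.random.default_rng(seed)
    if indices is None:
        indices = [rng.integers(0, n, n) for _ in range(n_boot)]
    r2s = np.empty(len(indices))
    coefs = np.empty((len(indices), X.shape[1]))
    for i, idx in enumerate(indices):
        Xb, yb = X[idx], y[idx]
        coef, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        r2s[i] = _r2(yb, Xb @ coef)
        coefs[i] = coef
    return np.clip(r2s, 0.0, 1.0), coefs


def bootstrap_r2(
    X: np.ndarray,
    y: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
    indices: list[np.ndarray] | None = None,
) -> np.ndarray:
    """In-sample R² of OLS refits on eye-level bootstrap resamples."""
    return bootstrap_ols(X, y, n_boot=n_boot, seed=seed, indices=indices)[0]


def _ols_report(
    df: pd.DataFrame,
    predictors: list[str],
    response: str,
    n_boot: int,
    seed: int,
) -> RegressionReport:
    X = sm.add_constant(df[predictors].to_numpy(float))
    y = df[response].to_numpy(float)
    fit = sm.OLS(y, X).fit()
    terms = ["const"] + predictors
    r2s, boot_coefs = bootstrap_ols(X, y, n_boot=n_boot, seed=seed)
    coefs = pd.DataFrame(
        {
            "term": terms,
            "coef": fit.params,
            "se": fit.bse,
            "p": fit.pvalues,
            "boot_low": np.percentile(boot_coefs, 2.5, axis=0),
            "boot_high": np.percentile(boot_coefs, 97.5, axis=0),
        }
    )
    return RegressionReport(
        coefficients=coefs,
        r2_insample=float(fit.rsquared),
        r2_boot_mean=float(r2s.mean()),
        r2_boot_ci=(float(np.percentile(r2s, 2.5)), float(np.percentile(r2s, 97.5))),
        n=len(df),
        n_boot=n_boot,
        seed=seed,
        response=response,
    )


def univariable_ratio_model(
    table: pd.DataFrame,
    response: str = "growth_12m",
    n_boot: int = 100,
    seed: int = 0,
) -> RegressionReport:
    """OLS of 12-month growth on the baseline PRD/RPE-loss ratio."""
    if len(table) < 10:
        raise ValueError("need at least 10 eyes")
    if table["ratio_prd_rpe"].std(ddof=0) == 0:
        raise ValueError("predictor ratio_prd_rpe has zero variance")
    return _ols_report(table, ["ratio_prd_rpe"], response, n_boot, seed)


def multivariable_growth_model(
    table: pd.DataFrame,
    response: str = "growth_12m",
    n_boot: int = 100,
    seed: int = 0,
) -> RegressionReport:
    """OLS of growth on ratio, isolated-PRD and intact-macula baselines."""
    if len(table) < 20:
        raise ValueError("need at least 20 eyes")
    X = table[list(PREDICTORS)].to_numpy(float)
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < len(PREDICTORS):
        degenerate = [p for p in PREDICTORS if table[p].std(ddof=0) == 0]
        if not degenerate:
            corr = np.corrcoef(Xc, rowvar=False)
            pairs = [
                f"{PREDICTORS[i]}~{PREDICTORS[j]}"
                for i in range(len(PREDICTORS))
                for j in range(i + 1, len(PREDICTORS))
                if abs(corr[i, j]) > 1 - 1e-9
            ]
            degenerate = pairs or list(PREDICTORS)
        raise ValueError(f"rank-deficient predictors: {', '.join(degenerate)}")
    return _ols_report(table, list(PREDICTORS), response, n_boot, seed)


@dataclass
class QuartileSummary:
    """Per-quartile growth summaries of one baseline variable."""

    variable: str
    cuts: tuple[float, float, float]
    table: pd.DataFrame  # quartile, n, mean, sd, median
    by_arm: pd.DataFrame | None
    spearman_rho: float


def quartile_stratify(
    table: pd.DataFrame,
    variable: str,
    response: str = "growth_12m",
    by_arm: bool = False,
) -> QuartileSummary:
    """Growth summaries by sample quartile of a baseline variable.

    Values equal to a cut point fall in the lower quartile.  Reports n,
    mean, SD and median of growth per quartile plus the Spearman
    correlation of quartile index against the quartile mean (the
    monotonicity statistic).
    """
    if len(table) < 8:
        raise ValueError("need at least 8 eyes for quartile stratification")
    x = table[variable].to_numpy(float)
    cuts = np.quantile(x, [0.25, 0.5, 0.75])
    q = 1 + (x[:, None] > cuts[None, :]).sum(axis=1)
    if len(np.unique(q)) < 4:
        raise ValueError(
            f"heavy ties in {variable!r} leave fewer than 4 nonempty quartiles; "
            "use fewer bins"
        )
    df = table.assign(quartile=q)
    summary = (
        df.groupby("quartile")[response]
        .agg(n="size", mean="mean", sd="std", median="median")
        .reset_index()
    )
    rho = float(stats.spearmanr(summary.quartile, summary["mean"]).statistic)
    per_arm = None
    if by_arm:
        per_arm = (
            df.groupby(["arm", "quartile"])[response]
            .agg(n="size", mean="mean", sd="std", median="median")
            .reset_index()
        )
    return QuartileSummary(
        variable=variable,
        cuts=tuple(float(c) for c in cuts),
        table=summary,
        by_arm=per_arm,
        spearman_rho=rho,
    )


def build_predictor_table(
    long_table: pd.DataFrame,
    month: int = 12,
    response: str = "sqrt_change",
) -> pd.DataFrame:
    """Assemble the per-eye predictor table from a quantified long table.

    Baseline (month 0) areas give the PRD/RPE-loss ratio, isolated PRD and
    intact macula; the response is that eye's RORA growth to ``month``,
    either ``"sqrt_change"`` (mm) or ``"area_change"`` (mm²).
    """
    if response not in ("sqrt_change", "area_change"):
        raise ValueError("response must be 'sqrt_change' or 'area_change'")
    base = long_table[long_table.visit_month == 0].pivot_table(
        index=["eye_id", "arm"], columns="feature", values="area_mm2"
    )
    rora = long_table[
        (long_table.feature == "RORA") & (long_table.visit_month == month)
    ].set_index("eye_id")
    rows = []
    for (eye, arm), areas in base.iterrows():
        if eye not in rora.index or areas["RPE_LOSS"] <= 0:
            continue
        if response == "sqrt_change":
            growth = float(rora.loc[eye, "sqrt_change_mm"])
        else:
            growth = float(rora.loc[eye, "area_mm2"] - rora.loc[eye, "baseline_area_mm2"])
        rows.append(
            {
                "eye_id": eye,
                "arm": arm,
                "ratio_prd_rpe": float(areas["PRD"] / areas["RPE_LOSS"]),
                "prd_isolated_mm2": float(areas["PRD_ISOLATED"]),
                "intact_macula_mm2": float(areas["INTACT_MACULA"]),
                "growth_12m": growth,
            }
        )
    return pd.DataFrame(rows)
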