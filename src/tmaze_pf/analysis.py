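"""Hyperparameter sensitivity analysis: Spearman correlations and OLS fits.

Each evaluation metric is related to the two swept hyperparameters (the
reward learning rate alpha_r and the trace decay lambda) in two ways:

* Spearman rank correlation of the metric against each hyperparameter
  separately, over run-level (or run-by-block) observations;
* an ordinary-least-squares fit of the metric on an intercept, alpha_r and
  lambda jointly, with classical 95% confidence intervals.

Hyperparameters enter on their natural grid scales, uncentred.  Rank
correlations use mid-ranks for ties with the two-sided t-approximation for
p-values; OLS inference is normal-theory with n - 3 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: Metric column -> (runs-level table, adaptation-level table) membership.
RUN_METRICS = ("cumulative_reward", "mean_step_length")
ADAPTATION_METRICS = ("adaptation_rate", "adaptation_steps")

_TERMS = ("constant", "alpha_r", "lam")


@dataclass(frozen=True)
class CorrelationResult:
    metric: str
    hyperparameter: str
    rs: float
    p_value: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    metric: str
    terms: tuple[str, ...]
    coefficients: tuple[float, ...]
    ci95: tuple[tuple[float, float], ...]
    n: int

    def coefficient(self, term: str) -> float:
        return self.coefficients[self.terms.index(term)]

    def ci(self, term: str) -> tuple[float, float]:
        return self.ci95[self.terms.index(term)]


def spearman(
    x, y, metric: str = "", hyperparameter: str = ""
) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks and t-approximate p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for constant input")
    rs, p = stats.spearmanr(x, y)
    return CorrelationResult(
        metric=metric,
        hyperparameter=hyperparameter,
        rs=float(rs),
        p_value=float(p),
        n=int(x.size),
    )


def ols_two_predictor(y, a, l, metric: str = "") -> RegressionResult:
    """OLS of y on [1, alpha_r, lambda] with classical 95% CIs."""
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    l = np.asarray(l, dtype=float)
    if not (y.shape == a.shape == l.shape) or y.ndim != 1:
        raise ValueError("y, a, l must be 1-D of equal length")
    X = np.column_stack([np.ones_like(a), a, l])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix [1, alpha_r, lam] is rank deficient")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        metric=metric,
        terms=_TERMS,
        coefficients=tuple(float(c) for c in fit.params),
        ci95=tuple((float(lo), float(hi)) for lo, hi in ci),
        n=int(y.size),
    )


def _check_grid(df: pd.DataFrame) -> None:
    lams = sorted(df["lam"].unique())
    alphas = sorted(df["alpha_r"].unique())
    present = set(zip(df["lam"], df["alpha_r"]))
    missing = [
        (lam, a) for lam in lams for a in alphas if (lam, a) not in present
    ]
    if missing:
        raise ValueError(f"incomplete hyperparameter grid; missing {missing}")


def _spearman_table(df: pd.DataFrame, metrics: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    for metric in metrics:
        for hyper in ("alpha_r", "lam"):
            res = spearman(df[hyper], df[metric], metric, hyper)
            rows.append((metric, hyper, res.rs, res.p_value, res.n))
    return pd.DataFrame(
        rows, columns=["metric", "hyperparameter", "rs", "p_value", "n"]
    )


def _ols_table(df: pd.DataFrame, metrics: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    for metric in metrics:
        res = ols_two_predictor(
            df[metric], df["alpha_r"], df["lam"], metric=metric
        )
        for term, coef, (lo, hi) in zip(res.terms, res.coefficients, res.ci95):
            rows.append((metric, term, coef, lo, hi, res.n))
    return pd.DataFrame(
        rows, columns=["metric", "term", "coefficient", "ci_low", "ci_high", "n"]
    )


def build_tables(
    runs: pd.DataFrame, adaptation: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """The four analysis tables from the per-run and per-block summaries.

    Correlation/regression observations are per run (n = configs x runs) for
    cumulative reward and step length, and per run per goal block
    (n = configs x runs x blocks, censored blocks included) for the
    adaptation metrics.
    """
    _check_grid(runs)
    _check_grid(adaptation)
    return {
        "table1_spearman": _spearman_table(runs, RUN_METRICS),
        "table2_ols": _ols_table(runs, RUN_METRICS),
        "table3_spearman_adapt": _spearman_table(adaptation, ADAPTATION_METRICS),
        "table4_ols_adapt": _ols_table(adaptation, ADAPTATION_METRICS),
    }
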