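"""Response-surface regression analysis of enumerated staffing scenarios.

Fits ordinary-least-squares models of a simulated outcome (typically the
mean total system time of severely injured patients) on staff headcounts:
a main-effects model with the full diagnostic suite (standardized
coefficients, VIF/tolerance, PRESS-based predicted R-squared, ANOVA F,
residual normality and heteroscedasticity checks), a Pareto ranking of
standardized effects, and forward stepwise model building over two-way
interaction and quadratic candidate terms.

On a balanced full-factorial design the main effects are orthogonal, so all
variance inflation factors equal 1 exactly and coefficient estimates do not
depend on which other main effects are in the model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan, lilliefors, normal_ad

__all__ = [
    "TermSpec",
    "RegressionModel",
    "FitDiagnostics",
    "ModelBuildingReport",
    "main_effects",
    "quadratic_candidates",
    "fit_ols",
    "predict",
    "pareto_standardized_effects",
    "stepwise_build",
    "residual_diagnostics",
    "shapiro_francia",
]


@dataclass(frozen=True)
class TermSpec:
    """One model term: intercept, a linear effect, a two-way interaction of
    distinct predictors, or a quadratic effect."""

    kind: str  # intercept | linear | interaction | quadratic
    predictors: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind == "interaction" and (len(self.predictors) != 2 or self.predictors[0] == self.predictors[1]):
            raise ValueError("interaction terms reference exactly two distinct predictors")
        if self.kind == "quadratic" and len(self.predictors) != 1:
            raise ValueError("quadratic terms reference exactly one predictor")
        if self.kind == "linear" and len(self.predictors) != 1:
            raise ValueError("linear terms reference exactly one predictor")
        if self.kind == "intercept" and self.predictors:
            raise ValueError("intercept takes no predictors")
        if self.kind not in ("intercept", "linear", "interaction", "quadratic"):
            raise ValueError(f"unknown term kind {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == "intercept":
            return "Intercept"
        if self.kind == "linear":
            return self.predictors[0]
        if self.kind == "quadratic":
            return f"{self.predictors[0]}^2"
        return ":".join(self.predictors)

    def column(self, data: pd.DataFrame) -> np.ndarray:
        if self.kind == "intercept":
            return np.ones(len(data))
        if self.kind == "linear":
            return data[self.predictors[0]].to_numpy(dtype=float)
        if self.kind == "quadratic":
            return data[self.predictors[0]].to_numpy(dtype=float) ** 2
        a, b = self.predictors
        return data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float)


def main_effects(predictors) -> list[TermSpec]:
    return [TermSpec("linear", (p,)) for p in predictors]


def quadratic_candidates(predictors) -> list[TermSpec]:
    """Linear + all two-way interactions + quadratics over the predictors."""
    terms = main_effects(predictors)
    terms += [TermSpec("interaction", (a, b)) for a, b in itertools.combinations(predictors, 2)]
    terms += [TermSpec("quadratic", (p,)) for p in predictors]
    return terms


@dataclass
class RegressionModel:
    """Fitted coefficients with per-term inference.

    ``beta`` is the standardized coefficient B_j * sd(x_j) / sd(y)
    (NaN for the intercept).
    """

    terms: list[TermSpec]
    names: list[str]
    b: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    df_resid: int
    residuals: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)

    def coef(self, name: str) -> float:
        return float(self.b[self.names.index(name)])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "B": self.b,
                "Beta": self.beta,
                "SE": self.se,
                "t": self.t,
                "p": self.p,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass
class FitDiagnostics:
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    resid_se: float
    f_stat: float
    f_p: float
    vif: dict[str, float]
    tolerance: dict[str, float]


@dataclass
class ModelBuildingReport:
    """Forward-selection sequence: (added term, adjusted R^2 after adding)."""

    steps: list[tuple[str, float]]

    @property
    def term_order(self) -> list[str]:
        return [name for name, _ in self.steps]


def _design(data: pd.DataFrame, terms: list[TermSpec]) -> tuple[np.ndarray, list[str]]:
    cols = [t.column(data) for t in terms]
    X = np.column_stack([np.ones(len(data))] + cols)
    names = ["Intercept"] + [t.name for t in terms]
    return X, names


def fit_ols(
    data: pd.DataFrame,
    response,
    terms: list[TermSpec] | None = None,
    alpha: float = 0.05,
) -> tuple[RegressionModel, FitDiagnostics]:
    """Fit an OLS model of ``response`` on the given terms (default: main
    effects of every other column) with the full diagnostic suite.

    Raises on rank deficiency and on n <= p + 1.
    """
    if isinstance(response, str):
        y = data[response].to_numpy(dtype=float)
        predictors = [c for c in data.columns if c != response]
    else:
        y = np.asarray(response, dtype=float)
        predictors = list(data.columns)
    if terms is None:
        terms = main_effects(predictors)
    terms = [t for t in terms if t.kind != "intercept"]
    X, names = _design(data, terms)
    n, p1 = X.shape
    if n <= p1:
        raise ValueError(f"n = {n} rows cannot identify {p1} coefficients")
    if np.linalg.matrix_rank(X) < p1:
        raise ValueError("design matrix is rank deficient (collinear or duplicated terms)")

    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=alpha)
    sd_y = np.std(y, ddof=1)
    beta = np.full(p1, np.nan)
    for j in range(1, p1):
        beta[j] = fit.params[j] * np.std(X[:, j], ddof=1) / sd_y

    model = RegressionModel(
        terms=terms,
        names=names,
        b=np.asarray(fit.params),
        beta=beta,
        se=np.asarray(fit.bse),
        t=np.asarray(fit.tvalues),
        p=np.asarray(fit.pvalues),
        ci_low=np.asarray(ci[:, 0]),
        ci_high=np.asarray(ci[:, 1]),
        n=n,
        df_resid=int(fit.df_resid),
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
    )

    # PRESS / predicted R^2 via the hat-matrix shortcut
    q, _ = np.linalg.qr(X)
    hat = np.einsum("ij,ij->i", q, q)
    press = float(np.sum((fit.resid / (1.0 - hat)) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    pred_r2 = 1.0 - press / sst if sst > 0 else float("nan")

    vif: dict[str, float] = {}
    tol: dict[str, float] = {}
    for j in range(1, p1):
        others = np.delete(X, j, axis=1)
        bj, _, _, _ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ bj
        ssx = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2j = 1.0 - np.sum(resid**2) / ssx if ssx > 0 else 0.0
        v = 1.0 / (1.0 - r2j) if r2j < 1 else float("inf")
        vif[names[j]] = float(v)
        tol[names[j]] = float(1.0 / v)

    diag = FitDiagnostics(
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        pred_r2=float(pred_r2),
        press=press,
        resid_se=float(np.sqrt(fit.mse_resid)),
        f_stat=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        vif=vif,
        tolerance=tol,
    )
    return model, diag


def predict(model: RegressionModel, values: dict[str, float]) -> float:
    """Evaluate the fitted linear combination at the given predictor values."""
    out = model.b[0]
    for j, term in enumerate(model.terms, start=1):
        try:
            if term.kind == "linear":
                x = values[term.predictors[0]]
            elif term.kind == "quadratic":
                x = values[term.predictors[0]] ** 2
            else:
                x = values[term.predictors[0]] * values[term.predictors[1]]
        except KeyError as e:
            raise ValueError(f"missing predictor value for {e.args[0]!r}") from None
        out += model.b[j] * x
    return float(out)


def pareto_standardized_effects(model: RegressionModel, alpha: float = 0.05) -> tuple[pd.DataFrame, float]:
    """Terms ranked by |t| (descending, ties broken by name) with the
    two-sided critical t at the residual degrees of freedom — the textual
    form of a Pareto chart of standardized effects."""
    if len(model.terms) == 0:
        raise ValueError("intercept-only model has no effects to rank")
    rows = [
        {"term": model.names[j], "abs_t": abs(float(model.t[j])), "beta": float(model.beta[j])}
        for j in range(1, len(model.names))
    ]
    rows.sort(key=lambda r: (-r["abs_t"], r["term"]))
    crit = float(stats.t.ppf(1 - alpha / 2, model.df_resid))
    return pd.DataFrame(rows), crit


def stepwise_build(
    candidates: list[TermSpec],
    data: pd.DataFrame,
    response,
    enforce_hierarchy: bool = False,
) -> ModelBuildingReport:
    """Forward selection maximizing adjusted-R^2 gain per step.

    Stops when no remaining candidate improves adjusted R^2.  By default a
    quadratic or interaction term may enter before its parent main effects;
    ``enforce_hierarchy`` restricts entry to terms whose parents are already
    in the model.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    y = data[response].to_numpy(dtype=float) if isinstance(response, str) else np.asarray(response, float)
    selected: list[TermSpec] = []
    remaining = list(candidates)
    steps: list[tuple[str, float]] = []
    current_adj = -np.inf

    def _adj_r2(terms: list[TermSpec]) -> float:
        X, _ = _design(data, terms)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            return -np.inf
        fit = sm.OLS(y, X).fit()
        return float(fit.rsquared_adj)

    while remaining:
        best_gain, best_term, best_adj = 0.0, None, current_adj
        for term in remaining:
            if enforce_hierarchy and term.kind in ("interaction", "quadratic"):
                have = {t.name for t in selected}
                if not all(p in have for p in term.predictors):
                    continue
            adj = _adj_r2(selected + [term])
            if adj > best_adj + 1e-12:
                best_gain, best_term, best_adj = adj - current_adj, term, adj
        if best_term is None:
            break
        selected.append(best_term)
        remaining.remove(best_term)
        current_adj = best_adj
        steps.append((best_term.name, current_adj))
    return ModelBuildingReport(steps=steps)


def shapiro_francia(x) -> tuple[float, float]:
    """Shapiro-Francia normality test (correlation of order statistics with
    normal scores), with the standard log-normal approximation of the null
    distribution of ln(1 - W') for 5 <= n <= 5000."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError("Shapiro-Francia needs at least 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    m = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    w = np.corrcoef(x, m)[0, 1] ** 2
    u, v = math.log(n), math.log(math.log(n))
    mu = -1.2725 + 1.0521 * (v - u)
    sigma = 1.0308 - 0.26758 * (v + 2.0 / u)
    z = (math.log(1.0 - w) - mu) / sigma
    return float(w), float(stats.norm.sf(z))


def residual_diagnostics(model: RegressionModel, data: pd.DataFrame | None = None) -> dict:
    """Residual checks: four normality tests (moment-based Jarque-Bera,
    EDF-based Anderson-Darling and Lilliefors, correlation-based
    Shapiro-Francia) and a Breusch-Pagan-type heteroscedasticity regression
    of squared residuals on the fitted values."""
    resid = model.residuals
    if resid is None or len(resid) < 8:
        raise ValueError("too few residuals for the diagnostic suite")
    if np.ptp(resid) == 0:
        raise ValueError("constant residuals: diagnostics undefined")
    ad_stat, ad_p = normal_ad(resid)
    lf_stat, lf_p = lilliefors(resid, dist="norm")
    jb = stats.jarque_bera(resid)
    sf_stat, sf_p = shapiro_francia(resid)
    exog = np.column_stack([np.ones(len(resid)), model.fitted])
    bp_lm, bp_lm_p, bp_f, bp_f_p = het_breuschpagan(resid, exog)
    return {
        "normality": {
            "jarque_bera": (float(jb.statistic), float(jb.pvalue)),
            "anderson_darling": (float(ad_stat), float(ad_p)),
            "lilliefors": (float(lf_stat), float(lf_p)),
            "shapiro_francia": (sf_stat, sf_p),
        },
        "heteroscedasticity": {
            "breusch_pagan_lm": (float(bp_lm), float(bp_lm_p)),
            "breusch_pagan_f": (float(bp_f), float(bp_f_p)),
        },
    }
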