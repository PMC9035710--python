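"""Correlation and hierarchical-regression analysis of a cohort table.

Implements the study-style analysis: Pearson correlations with t statistics
on n-2 degrees of freedom and Fisher-z 95% confidence intervals; a
three-stage hierarchical (nested) OLS regression of choline on GPC+PC, the
number of reversals, and the behavioural/model-parameter block, with R^2,
adjusted R^2, Delta-R^2 and F-change tests per stage; and the assumption
diagnostics (variance inflation factors, Durbin-Watson, Cook's distance).
The same model re-run with NAA as the response serves as the specificity
control.

OLS machinery is delegated to statsmodels; the derived quantities
(F-change, VIF via auxiliary regressions, standardised coefficients by
refitting on z-scored variables) are assembled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import OLSInfluence
from statsmodels.stats.stattools import durbin_watson as _sm_dw

#: default stage structure of the hierarchical regression
PAPER_STAGES = (
    ("gpcpc_mM",),
    ("gpcpc_mM", "reversals"),
    ("gpcpc_mM", "reversals", "alpha_pos", "alpha_neg", "beta",
     "perseverative", "regressive"),
)

ANALYSIS_MEASURES = (
    "correct", "perseverative", "regressive", "reversals",
    "alpha_pos", "alpha_neg", "beta",
    "choline_mM", "gpcpc_mM", "naa_mM",
)


class RankDeficientError(ValueError):
    """Design matrix is (numerically) rank deficient, e.g. duplicated
    predictors; raised rather than silently dropping columns."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t: float
    df: int
    ci_low: float
    ci_high: float
    p: float


def pearson_with_ci(x: Sequence[float], y: Sequence[float], conf: float = 0.95) -> CorrelationResult:
    """Pearson correlation with its t test and Fisher-z confidence interval.

    t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom; the CI is
    tanh(atanh(r) +/- z / sqrt(n-3)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df) / np.sqrt(1 - r**2)
        p = 2 * sps.t.sf(abs(t), df)
    zcrit = sps.norm.ppf(0.5 + conf / 2)
    zr = np.arctanh(r)
    lo, hi = np.tanh(zr - zcrit / np.sqrt(n - 3)), np.tanh(zr + zcrit / np.sqrt(n - 3))
    return CorrelationResult(r=r, t=float(t), df=df, ci_low=float(lo),
                             ci_high=float(hi), p=float(p))


def t_from_r(r: float, n: int) -> float:
    """t statistic of a Pearson correlation on n-2 degrees of freedom."""
    return r * np.sqrt(n - 2) / np.sqrt(1 - r**2)


def correlation_matrix(data: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """All pairwise correlations with t, CI and p (long format)."""
    cols = list(columns) if columns is not None else list(data.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            res = pearson_with_ci(data[a], data[b])
            rows.append({"x": a, "y": b, "r": res.r, "t": res.t, "df": res.df,
                         "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p})
    return pd.DataFrame(rows)


def _design(data: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    X = sm.add_constant(data[list(predictors)].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise RankDeficientError(
            f"design with predictors {list(predictors)} is rank deficient"
        )
    return X


def ols_fit(data: pd.DataFrame, response: str, predictors: Sequence[str]):
    """OLS with intercept; returns the statsmodels results object."""
    X = _design(data, predictors)
    return sm.OLS(data[response].astype(float), X).fit()


def standardized_coefs(data: pd.DataFrame, response: str, predictors: Sequence[str]) -> pd.Series:
    """Standardised betas: the same fit on z-scored response and predictors."""
    zdata = (data[[response, *predictors]].astype(float))
    zdata = (zdata - zdata.mean()) / zdata.std(ddof=1)
    fit = ols_fit(zdata, response, predictors)
    return fit.params.drop("const")


def vif(data: pd.DataFrame, predictors: Sequence[str]) -> pd.Series:
    """Variance inflation factors, 1 / (1 - R^2_j) from regressing each
    predictor on the remaining ones."""
    _design(data, predictors)  # rank check
    out = {}
    for p in predictors:
        others = [q for q in predictors if q != p]
        if not others:
            out[p] = 1.0
            continue
        r2 = ols_fit(data, p, others).rsquared
        out[p] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def durbin_watson(residuals: Sequence[float]) -> float:
    """Durbin-Watson statistic sum (e_t - e_{t-1})^2 / sum e_t^2."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 3:
        raise ValueError("need at least 3 residuals")
    if np.sum(e**2) == 0:
        raise ValueError("zero residual variance")
    return float(_sm_dw(e))


def cooks_distance(fit) -> np.ndarray:
    """Cook's distance per observation for a fitted OLS model.

    A numerically exact fit (zero residual sum of squares) has no influence
    to measure; all distances are 0 rather than the 0/0 ratio.
    """
    tss = float(np.sum((fit.model.endog - fit.model.endog.mean()) ** 2))
    if fit.ssr <= 1e-12 * max(tss, 1.0):
        return np.zeros(int(fit.nobs))
    return np.asarray(OLSInfluence(fit).cooks_distance[0])


@dataclass(frozen=True)
class RegressionStage:
    """One stage of a hierarchical regression."""

    index: int
    predictors: tuple[str, ...]
    r: float
    r2: float
    adj_r2: float
    delta_r2: float
    f: float
    f_p: float
    df_model: int
    df_resid: int
    f_change: float
    f_change_p: float
    df_change: tuple[int, int]
    coefs: pd.DataFrame  # unstandardised b, standardised beta, t, p per predictor


@dataclass
class Diagnostics:
    vif: pd.Series
    durbin_watson: float
    cooks: np.ndarray

    @property
    def high_influence(self) -> np.ndarray:
        return np.flatnonzero(self.cooks > 1.0)


@dataclass
class HierarchicalOLSResults:
    """Stages, diagnostics (final stage) and correlation matrix of a
    hierarchical regression."""

    response: str
    n: int
    stages: list[RegressionStage]
    diagnostics: Diagnostics
    correlations: Optional[pd.DataFrame] = None

    def summary(self) -> str:
        """Rendered table in the familiar stage layout with p-value stars
        (* p<.05, ** p<.01, *** p<.001)."""
        lines = [
            f"Hierarchical regression predicting {self.response} (N = {self.n})",
            "=" * 72,
            f"{'Variable':<18}{'b':>9}{'beta':>9}{'t':>10}"
            f"{'R':>8}{'R2/adjR2':>14}{'dR2':>9}",
        ]
        for st in self.stages:
            lines.append(
                f"Stage {st.index:<12}{'':>9}{'':>9}{'':>10}"
                f"{st.r:8.3f}{st.r2:7.3f}/{st.adj_r2:6.3f}"
                f"{st.delta_r2:8.3f}{_stars(st.f_change_p) if st.index > 1 else _stars(st.f_p)}"
            )
            for name, row in st.coefs.iterrows():
                lines.append(
                    f"  {name:<16}{row['b']:9.3f}{row['beta']:9.3f}"
                    f"{row['t']:10.3f} {_stars(row['p'])}"
                )
        d = self.diagnostics
        lines += [
            "-" * 72,
            f"Durbin-Watson = {d.durbin_watson:.3f}; max VIF = {d.vif.max():.2f}; "
            f"Cook's D > 1 for {len(d.high_influence)} observation(s)",
            "* p < .05; ** p < .01; *** p < .001",
        ]
        return "\n".join(lines)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


class HierarchicalOLS:
    """Hierarchical (nested, staged) multiple regression, statsmodels-style.

    Parameters
    ----------
    data : DataFrame
        Cohort table with the response and all predictors.
    response : str
        Response column.
    stages : sequence of predictor tuples
        Nested predictor sets, each stage a superset of the previous one.
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 stages: Sequence[Sequence[str]] = PAPER_STAGES):
        missing = {response, *(p for st in stages for p in st)} - set(data.columns)
        if missing:
            raise KeyError(f"missing columns: {sorted(missing)}")
        for a, b in zip(stages, stages[1:]):
            if not set(a) <= set(b):
                raise ValueError("stages must be nested predictor sets")
        self.data = data.reset_index(drop=True)
        self.response = response
        self.stages = [tuple(s) for s in stages]

    def fit(self, correlations: bool = True) -> HierarchicalOLSResults:
        n = len(self.data)
        full = self.stages[-1]
        k_full = len(full)
        if n <= k_full + 1:
            raise ValueError("too few observations for the final stage")
        results: list[RegressionStage] = []
        prev_r2 = 0.0
        prev_k = 0
        final_fit = None
        for idx, preds in enumerate(self.stages, start=1):
            fit = ols_fit(self.data, self.response, preds)
            final_fit = fit
            std = standardized_coefs(self.data, self.response, preds)
            coefs = pd.DataFrame(
                {
                    "b": fit.params.drop("const"),
                    "beta": std,
                    "t": fit.tvalues.drop("const"),
                    "p": fit.pvalues.drop("const"),
                }
            )
            r2 = float(fit.rsquared)
            delta = r2 - prev_r2
            dk = len(preds) - prev_k
            df_denom = n - len(preds) - 1
            denom = (1.0 - r2) / df_denom
            f_change = np.inf if denom == 0 else (delta / dk) / denom
            f_change_p = float(sps.f.sf(f_change, dk, df_denom)) if np.isfinite(f_change) else 0.0
            results.append(
                RegressionStage(
                    index=idx,
                    predictors=tuple(preds),
                    r=float(np.sqrt(max(r2, 0.0))),
                    r2=r2,
                    adj_r2=float(fit.rsquared_adj),
                    delta_r2=float(delta),
                    f=float(fit.fvalue),
                    f_p=float(fit.f_pvalue),
                    df_model=int(fit.df_model),
                    df_resid=int(fit.df_resid),
                    f_change=float(f_change),
                    f_change_p=f_change_p,
                    df_change=(dk, df_denom),
                    coefs=coefs,
                )
            )
            prev_r2, prev_k = r2, len(preds)
        diag = Diagnostics(
            vif=vif(self.data, full),
            durbin_watson=durbin_watson(final_fit.resid),
            cooks=cooks_distance(final_fit),
        )
        corr = None
        if correlations:
            cols = [c for c in ANALYSIS_MEASURES if c in self.data.columns]
            corr = correlation_matrix(self.data, cols)
        return HierarchicalOLSResults(
            response=self.response, n=n, stages=results,
            diagnostics=diag, correlations=corr,
        )


def hierarchical_regression(
    data: pd.DataFrame, response: str, stages: Sequence[Sequence[str]]
) -> list[RegressionStage]:
    """Functional wrapper around :class:`HierarchicalOLS`."""
    return HierarchicalOLS(data, response, stages).fit(correlations=False).stages


def run_paper_analysis(cohort: pd.DataFrame, response: str = "choline_mM") -> HierarchicalOLSResults:
    """The study's three-stage analysis on a cohort table.

    Stage 1: GPC+PC; stage 2: + reversals; stage 3: + learning rates,
    inverse temperature and error counts. ``response`` may be ``choline_mM``
    or ``naa_mM`` (the specificity control).
    """
    if response not in ("choline_mM", "naa_mM"):
        raise ValueError("response must be 'choline_mM' or 'naa_mM'")
    return HierarchicalOLS(cohort, response, PAPER_STAGES).fit()
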