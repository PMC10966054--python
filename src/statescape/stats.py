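"""Statistical comparison and correlation harness.

Implements the battery applied to the per-subject measure table: two-way
mixed ANOVA (between group x within session), Welch and paired t tests,
Kendall/Pearson correlation matrices with an effective-number-of-tests
correction, Benjamini-Yekutieli FDR, mixed linear models with a per-subject
random intercept, a median-split paired test, and the two-predictor linear
model for insightfulness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DegenerateDataError,
    DesignError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "TestResult",
    "CorrelationMatrixResult",
    "MixedModelResult",
    "LinearModelComparison",
    "mixed_anova",
    "welch_t",
    "paired_t",
    "correlation_matrix",
    "estimate_m_eff",
    "by_fdr",
    "fit_mixed_lm",
    "median_split_test",
    "insightfulness_model",
]


@dataclass
class TestResult:
    """A single hypothesis-test outcome."""

    name: str
    statistic: float
    df: float
    p: float
    df2: float = np.nan
    effect: str = ""
    correction: str = "none"
    p_corrected: float = np.nan
    note: str = ""

    @property
    def insufficient_data(self) -> bool:
        return self.note == "insufficient-data"


@dataclass
class CorrelationMatrixResult:
    method: str
    variables: list[str]
    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_corrected: pd.DataFrame
    m_eff: float


@dataclass
class MixedModelResult:
    """Random-intercept mixed linear model fit."""

    outcome: str
    formula: str
    params: pd.DataFrame  # index: term; columns: coef, stat, p
    marginal_r2: float
    conditional_r2: float
    singular: bool = False
    note: str = ""


@dataclass
class LinearModelComparison:
    """Full (interaction) vs reduced OLS model for one outcome."""

    outcome: str
    full: pd.DataFrame
    full_f: float
    full_f_p: float
    full_r2: float
    full_adj_r2: float
    full_df: tuple[float, float] = (np.nan, np.nan)
    reduced_adj_r2: float = np.nan
    reduced_r2: float = np.nan
    note: str = ""


# ---------------------------------------------------------------------------
# ANOVA and t tests
# ---------------------------------------------------------------------------

def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    between: str = "group",
    within: str = "session",
    subject: str = "subject_id",
) -> dict[str, TestResult]:
    """Two-way mixed ANOVA; returns between / within / interaction results."""
    data = table[[dv, between, within, subject]].dropna()
    cells = data.groupby([between, within], observed=True)[dv].count()
    n_b = data[between].nunique()
    n_w = data[within].nunique()
    if len(cells) < n_b * n_w or (cells < 2).any():
        raise DesignError("missing or underfilled design cell")
    counts = data.groupby(subject, observed=True)[within].nunique()
    if (counts < n_w).any():
        raise DesignError("every subject must be observed at all within levels")
    if np.isclose(data[dv].var(ddof=1), 0.0):
        raise DegenerateDataError(f"{dv} has zero variance")
    aov = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                         between=between)
    out: dict[str, TestResult] = {}
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    for _, r in aov.iterrows():
        src = r["Source"]
        effect = {between: "between", within: "within"}.get(src, "interaction")
        out[effect] = TestResult(
            name=f"mixed_anova_{dv}_{effect}",
            statistic=float(r["F"]),
            df=float(r["DF1"]),
            df2=float(r["DF2"]),
            p=float(r[p_col]),
            effect=effect,
        )
    return out


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ParameterError("samples must be one-dimensional")
    return a[~np.isnan(a)]


def welch_t(x, y, name: str = "welch_t") -> TestResult:
    """Independent-samples t test, unequal-variance (Welch) form."""
    x, y = _as_array(x), _as_array(y)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("need >= 2 observations per sample")
    if np.isclose(x.var(ddof=1), 0.0) and np.isclose(y.var(ddof=1), 0.0):
        raise DegenerateDataError("both samples have zero variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(name=name, statistic=float(res.statistic),
                      df=float(res.df), p=float(res.pvalue))


def paired_t(x, y, name: str = "paired_t") -> TestResult:
    """Paired t test on x - y; identical samples give t = 0, p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 2:
        raise ParameterError("need >= 2 complete pairs")
    diff = x - y
    if np.allclose(diff, 0.0):
        return TestResult(name=name, statistic=0.0, df=float(len(x) - 1), p=1.0)
    if np.isclose(diff.std(ddof=1), 0.0):
        raise DegenerateDataError("zero-variance nonzero differences")
    res = sps.ttest_rel(x, y)
    return TestResult(name=name, statistic=float(res.statistic),
                      df=float(len(x) - 1), p=float(res.pvalue))


# ---------------------------------------------------------------------------
# Correlations and multiplicity
# ---------------------------------------------------------------------------

def _pairwise_corr(a: np.ndarray, b: np.ndarray, method: str) -> tuple[float, float]:
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 4:
        return np.nan, np.nan
    if np.isclose(a.std(), 0.0) or np.isclose(b.std(), 0.0):
        return np.nan, np.nan  # undefined-correlation flag
    if method == "kendall":
        r, p = sps.kendalltau(a, b)
    else:
        r, p = sps.pearsonr(a, b)
    return float(r), float(p)


def correlation_matrix(
    table: pd.DataFrame,
    measures: list[str],
    scales: list[str],
    method: str = "kendall",
    m_eff_method: str = "nyholt",
) -> CorrelationMatrixResult:
    """Pairwise correlations over measures + scales.

    Corrected p values are ``raw * M_eff`` (capped at 1), with ``M_eff``
    estimated from the eigenvalues of the psychometric battery's own
    correlation matrix — the battery, not the full variable set, drives the
    multiplicity.
    """
    if method not in ("kendall", "pearson"):
        raise ParameterError(f"unknown method {method!r}")
    variables = list(measures) + [s for s in scales if s not in measures]
    m = len(variables)
    r = np.eye(m)
    p = np.zeros((m, m))
    cols = {v: table[v].to_numpy(dtype=float) for v in variables}
    for i in range(m):
        for j in range(i + 1, m):
            rij, pij = _pairwise_corr(cols[variables[i]], cols[variables[j]], method)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij

    if len(scales) >= 2:
        sidx = [variables.index(s) for s in scales]
        battery = r[np.ix_(sidx, sidx)]
        if np.all(np.isfinite(battery)):
            m_eff = estimate_m_eff(battery, method=m_eff_method)
        else:
            m_eff = float(len(scales))
    else:
        m_eff = 1.0
    p_corr = np.clip(p * m_eff, 0.0, 1.0)
    np.fill_diagonal(p_corr, 0.0)
    idx = pd.Index(variables)
    return CorrelationMatrixResult(
        method=method,
        variables=variables,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p_raw=pd.DataFrame(p, index=idx, columns=idx),
        p_corrected=pd.DataFrame(p_corr, index=idx, columns=idx),
        m_eff=m_eff,
    )


def estimate_m_eff(corr: np.ndarray, method: str = "nyholt") -> float:
    """Effective number of tests from the eigenvalues of a correlation matrix.

    ``nyholt``: ``M_eff = 1 + (M - 1) * (1 - Var(lambda) / M)`` with the
    sample variance (denominator ``M - 1``), clamped to ``[1, M]``.
    ``li_ji``: ``sum_i [I(lambda_i >= 1) + (lambda_i - floor(lambda_i))]``.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValidationError("correlation matrix must have unit diagonal")
    m = corr.shape[0]
    if m == 1:
        return 1.0
    lam = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    if lam.min() < -1e-6:
        raise ValidationError("correlation matrix must be positive semi-definite")
    if method == "nyholt":
        m_eff = 1.0 + (m - 1) * (1.0 - np.var(lam, ddof=1) / m)
    elif method == "li_ji":
        lam = np.abs(lam)
        m_eff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    else:
        raise ParameterError(f"unknown M_eff method {method!r}")
    return float(min(max(m_eff, 1.0), float(m)))


def by_fdr(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("pvals must be a non-empty 1-D sequence")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


# ---------------------------------------------------------------------------
# Mixed and linear models
# ---------------------------------------------------------------------------

def fit_mixed_lm(
    table: pd.DataFrame,
    outcome: str,
    fixed: str,
    group: str = "subject_id",
) -> MixedModelResult:
    """Random-intercept mixed linear model ``outcome ~ fixed``.

    Reports fixed-effect coefficients with Wald statistics and Nakagawa-style
    marginal / conditional R-squared (variance-partition definitions).  A fit
    with vanishing random-effect variance is flagged ``singular`` and the
    corresponding OLS reduced model's coefficients are reported instead.
    """
    data = table.dropna(subset=[c for c in table.columns
                                if c in (outcome, group)]).copy()
    counts = data.groupby(group, observed=True)[outcome].count()
    if (counts < 2).any():
        raise DesignError("need >= 2 observations per subject")
    formula = f"{outcome} ~ {fixed}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[group])
        fit = model.fit(reml=True)
    var_re = float(np.asarray(fit.cov_re).ravel()[0])
    var_res = float(fit.scale)
    singular = var_re < 1e-6 * max(var_res, 1e-12)
    note = ""
    params = pd.DataFrame(
        {
            "coef": fit.fe_params,
            "stat": fit.tvalues[fit.fe_params.index],
            "p": fit.pvalues[fit.fe_params.index],
        }
    )
    if singular:
        note = "singular random-effect variance; OLS coefficients reported"
        ols = smf.ols(formula, data=data).fit()
        params = pd.DataFrame({"coef": ols.params, "stat": ols.tvalues,
                               "p": ols.pvalues})
    fe_pred = np.asarray(model.exog) @ np.asarray(fit.fe_params)
    var_f = float(np.var(fe_pred, ddof=1))
    total = var_f + var_re + var_res
    return MixedModelResult(
        outcome=outcome,
        formula=formula,
        params=params,
        marginal_r2=var_f / total,
        conditional_r2=(var_f + var_re) / total,
        singular=singular,
        note=note,
    )


def median_split_test(
    table: pd.DataFrame,
    split_var: str,
    dv_pre: str,
    dv_post: str,
) -> dict[str, TestResult]:
    """Median split on ``split_var``; paired t on (pre, post) per subgroup.

    Ties (values equal to the median) go to the lower subgroup.  Subgroups
    with fewer than 3 complete pairs are flagged, not tested.
    """
    data = table.dropna(subset=[split_var])
    if data.empty:
        raise ParameterError("split variable entirely missing")
    med = float(np.median(data[split_var]))
    groups = {
        "low": data[data[split_var] <= med],
        "high": data[data[split_var] > med],
    }
    out: dict[str, TestResult] = {}
    for label, sub in groups.items():
        pairs = sub.dropna(subset=[dv_pre, dv_post])
        name = f"median_split_{label}"
        if len(pairs) < 3:
            out[label] = TestResult(name=name, statistic=np.nan, df=np.nan,
                                    p=np.nan, note="insufficient-data")
            continue
        tr = paired_t(pairs[dv_pre], pairs[dv_post], name=name)
        tr.effect = label
        out[label] = tr
    return out


def insightfulness_model(
    table: pd.DataFrame,
    outcome: str = "insightfulness",
    x1: str = "positive_derealization",
    x2: str = "d_OM1_OM2",
) -> LinearModelComparison:
    """OLS ``outcome ~ x1 * x2`` plus the ``x1``-only reduced model."""
    data = table.dropna(subset=[outcome, x1, x2]).copy()
    if len(data) < 5:
        raise ParameterError("need >= 5 complete cases")
    full = smf.ols(f"{outcome} ~ {x1} * {x2}", data=data).fit()
    reduced = smf.ols(f"{outcome} ~ {x1}", data=data).fit()
    note = ""
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        note = "rank-deficient design"
    params = pd.DataFrame({"coef": full.params, "stat": full.tvalues,
                           "p": full.pvalues})
    return LinearModelComparison(
        outcome=outcome,
        full=params,
        full_f=float(full.fvalue),
        full_f_p=float(full.f_pvalue),
        full_r2=float(full.rsquared),
        full_adj_r2=float(full.rsquared_adj),
        full_df=(float(full.df_model), float(full.df_resid)),
        reduced_r2=float(reduced.rsquared),
        reduced_adj_r2=float(reduced.rsquared_adj),
        note=note,
    )
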