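"""Association statistics: correlations, contingency tests, group
differences, covariate-adjusted regressions, FDR control and survival.

Conventions shared by all operations:

* missing values are dropped pairwise-complete and the usable sample size is
  reported as ``n_used``;
* Benjamini-Hochberg adjustment is applied within an analysis block (e.g. all
  clinicopathological variables tested against one gene), never across
  blocks;
* every operation is deterministic and invariant to sample ordering.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class AssociationResult:
    predictor: str
    outcome: str
    test_name: str
    statistic: float
    p_value: float
    n_used: int
    fdr: float | None = None
    direction: str = ""
    warnings: list[str] = field(default_factory=list)


@dataclass
class RegressionFit:
    """Summary of a fitted linear or logistic model."""

    outcome: str
    terms: list[tuple[str, float, float]]  # (name, coefficient, p)
    adjusted_r2: float | None
    f_statistic: float | None
    model_p: float | None
    n_used: int
    dropped_terms: list[str] = field(default_factory=list)
    separation_flag: bool = False

    def coef(self, name: str) -> float:
        return {t[0]: t[1] for t in self.terms}[name]

    def p(self, name: str) -> float:
        return {t[0]: t[2] for t in self.terms}[name]


# ---------------------------------------------------------------------------
# Correlation


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation.

    p-value from the t approximation; for n < 10 an exact permutation p is
    computed by full enumeration of rank orderings.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rho, p = sps.spearmanr(x, y)
    if n < 10:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(_pearson(rx, ry))
        perms = np.array(list(itertools.permutations(range(n))))
        ry_perm = ry[perms] - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_perm**2).sum(axis=1))
        r_all = (ry_perm @ rx_c) / denom
        p = float(np.mean(np.abs(r_all) >= obs - 1e-12))
    return float(rho), float(p)


def _pearson(a, b) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom else math.nan


# ---------------------------------------------------------------------------
# Contingency


def chi_square(table, predictor: str = "", outcome: str = "") -> AssociationResult:
    """Pearson chi-square on an r x c contingency table (no Yates correction).

    Empty rows/columns are dropped first; a warning is recorded when any
    expected count falls below 5.
    """
    counts = np.asarray(table, dtype=float)
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("contingency table must hold non-negative integer counts")
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("degenerate table after dropping empty margins")
    stat, p, dof, expected = sps.chi2_contingency(counts, correction=False)
    warnings = []
    if (expected < 5).any():
        warnings.append(f"{int((expected < 5).sum())} cells with expected count < 5")
    return AssociationResult(
        predictor=predictor,
        outcome=outcome,
        test_name="chi_square",
        statistic=float(stat),
        p_value=float(p),
        n_used=int(counts.sum()),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Multiple testing


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, original
    order restored)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Group differences


def group_difference(values, groups, method: str = "anova",
                     predictor: str = "", outcome: str = "") -> AssociationResult:
    """Mean (one-way ANOVA) or median (Brown-Mood K-sample median test)
    difference of a continuous variable across discrete groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    mask = np.isfinite(values) & (groups != None)  # noqa: E711 — object arrays
    values, groups = values[mask], groups[mask]
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == lev] for lev in levels]
    if method == "anova":
        if any(s.size < 2 for s in samples):
            raise ValueError("ANOVA needs >=2 members per group")
        stat, p = sps.f_oneway(*samples)
        name = "anova"
    elif method == "median_test":
        res = sps.median_test(*samples, correction=False, ties="below")
        stat, p = res.statistic, res.pvalue
        name = "median_test"
    else:
        raise ValueError(f"unknown method {method!r}")
    return AssociationResult(
        predictor=predictor, outcome=outcome, test_name=name,
        statistic=float(stat), p_value=float(p), n_used=int(values.size),
    )


# ---------------------------------------------------------------------------
# Regression


def _prepare_design(terms: pd.DataFrame, add_intercept: bool) -> tuple[pd.DataFrame, list[str]]:
    X = terms.astype(float).copy()
    dropped = []
    # drop constant columns, then greedily drop columns that are linear
    # combinations of the preceding ones
    for col in list(X.columns):
        if X[col].nunique() <= 1:
            X = X.drop(columns=[col])
            dropped.append(col)
    cols = list(X.columns)
    kept: list[str] = []
    base = np.ones((X.shape[0], 1)) if add_intercept else np.empty((X.shape[0], 0))
    current = base
    for col in cols:
        candidate = np.column_stack([current, X[col].to_numpy()])
        if np.linalg.matrix_rank(candidate) > np.linalg.matrix_rank(current):
            kept.append(col)
            current = candidate
        else:
            dropped.append(col)
    X = X[kept]
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    return X, dropped


def fit_linear(outcome, terms: pd.DataFrame, outcome_name: str = "y",
               add_intercept: bool = True) -> RegressionFit:
    """Ordinary least squares of ``outcome`` on the design-table columns.

    Constant and collinear columns are dropped (and reported) before the
    fit; per-term two-sided p-values, adjusted R2 and the overall F test are
    returned.
    """
    y = np.asarray(outcome, dtype=float)
    mask = np.isfinite(y) & np.isfinite(terms.astype(float)).all(axis=1).to_numpy()
    y = y[mask]
    X, dropped = _prepare_design(terms.loc[mask], add_intercept)
    if y.size <= X.shape[1] + 1:
        raise ValueError("not enough observations for the number of terms")
    model = sm.OLS(y, X).fit()
    terms_out = [
        (name, float(model.params[name]), float(model.pvalues[name]))
        for name in X.columns
    ]
    return RegressionFit(
        outcome=outcome_name,
        terms=terms_out,
        adjusted_r2=float(model.rsquared_adj),
        f_statistic=float(model.fvalue) if model.df_model > 0 else math.nan,
        model_p=float(model.f_pvalue) if model.df_model > 0 else math.nan,
        n_used=int(y.size),
        dropped_terms=dropped,
    )


def fit_logistic(outcome, terms: pd.DataFrame, outcome_name: str = "y",
                 add_intercept: bool = True) -> RegressionFit:
    """Binary logistic regression with Wald p-values.

    Raises on a single-class outcome; (quasi-)separation is detected from
    non-convergence or exploding coefficients and flagged, not raised.
    """
    y = np.asarray(outcome, dtype=float)
    mask = np.isfinite(y) & np.isfinite(terms.astype(float)).all(axis=1).to_numpy()
    y = y[mask]
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("logistic outcome must have exactly two classes")
    y01 = (y == classes.max()).astype(float)
    X, dropped = _prepare_design(terms.loc[mask], add_intercept)
    if y.size <= X.shape[1]:
        raise ValueError("not enough observations for the number of terms")
    separation = False
    with np.errstate(all="ignore"):
        model = sm.Logit(y01, X).fit(disp=False, maxiter=200)
    if not model.mle_retvals.get("converged", True) or np.abs(model.params).max() > 20:
        separation = True
    terms_out = [
        (name, float(model.params[name]), float(model.pvalues[name]))
        for name in X.columns
    ]
    return RegressionFit(
        outcome=outcome_name,
        terms=terms_out,
        adjusted_r2=float(model.prsquared),
        f_statistic=None,
        model_p=float(model.llr_pvalue),
        n_used=int(y.size),
        dropped_terms=dropped,
        separation_flag=separation,
    )


# ---------------------------------------------------------------------------
# Survival


def km_logrank(time, event, group):
    """Two-group log-rank test (1 df) with Kaplan-Meier survival curves.

    Returns ``(chi_square, p, curves)`` where ``curves`` maps group label to
    a DataFrame of the Kaplan-Meier step function.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError("log-rank comparison requires exactly two groups")
    if not event.any():
        raise ValueError("no events observed")
    a, b = (group == levels[0]), (group == levels[1])
    res = logrank_test(time[a], time[b], event_observed_A=event[a], event_observed_B=event[b])
    curves = {}
    for lev, m in ((levels[0], a), (levels[1], b)):
        km = KaplanMeierFitter()
        km.fit(time[m], event[m], label=str(lev))
        curves[lev] = km.survival_function_
    return float(res.test_statistic), float(res.p_value), curves


# ---------------------------------------------------------------------------
# Block-level convenience


def association_block(results: list[AssociationResult]) -> pd.DataFrame:
    """Apply BH adjustment across one analysis block and return a tidy table."""
    fdr = bh_adjust([r.p_value for r in results]) if results else np.array([])
    rows = []
    for r, q in zip(results, fdr):
        r.fdr = float(q)
        rows.append(
            {
                "predictor": r.predictor,
                "outcome": r.outcome,
                "test": r.test_name,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "n_used": r.n_used,
                "direction": r.direction,
                "warnings": "; ".join(r.warnings),
            }
        )
    return pd.DataFrame(rows)
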