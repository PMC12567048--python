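"""Expression preprocessing: winsorization, scaling, pooling, dichotomization.

The chain applied to each cohort before any scoring is:

1. per-gene symmetric winsorization (default total trimmed mass 15% for
   NTRK1/NTRK3, 30% for NTRK2 — i.e. half of the mass clamped per tail),
2. per-gene zero-to-one (min-max) normalization,
3. pooling of the independently normalized cohorts into one table, keeping
   the cohort label as a covariate and reporting per-variable cohort-bias
   tests (one-way ANOVA for continuous variables, chi-square for
   categorical ones),
4. median dichotomization of the pooled normalized values into high/low.

A rank-based inverse-normal transform is provided for analyses that require
approximately Gaussian variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_TRIM_FRACTIONS = {"NTRK1": 0.15, "NTRK2": 0.30, "NTRK3": 0.15}


@dataclass
class NormalizationRecipe:
    """Per-gene winsorization fractions and the dichotomization rule.

    ``trim_fraction_per_gene`` maps gene symbol -> total trimmed mass in
    [0, 0.5); with ``per_tail=False`` (default) half the mass is clamped in
    each tail, with ``per_tail=True`` the stated fraction is clamped per tail.
    ``dichotomy_rule`` is ``per-gene-pooled-median`` (default) or
    ``pooled-all-genes-median``.
    """

    trim_fraction_per_gene: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRIM_FRACTIONS)
    )
    default_trim_fraction: float = 0.0
    per_tail: bool = False
    dichotomy_rule: str = "per-gene-pooled-median"
    cohort_column: str = "cohort"

    def __post_init__(self):
        for gene, frac in self.trim_fraction_per_gene.items():
            if not 0 <= frac < 0.5:
                raise ValueError(f"trim fraction for {gene} must be in [0, 0.5)")
        if self.dichotomy_rule not in {"per-gene-pooled-median", "pooled-all-genes-median"}:
            raise ValueError(f"unknown dichotomy rule {self.dichotomy_rule!r}")

    def tail_fraction(self, gene: str) -> float:
        total = self.trim_fraction_per_gene.get(gene, self.default_trim_fraction)
        return total if self.per_tail else total / 2.0


def winsorize(values, fraction: float):
    """Clamp values below the ``fraction/2`` quantile (and symmetrically at
    the top) to those quantiles; linear (type-7) quantile interpolation.

    ``fraction`` is the total trimmed mass. Length and order statistics of
    interior values are unchanged. A constant vector is returned unchanged.
    """
    arr = np.asarray(values, dtype=float)
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    finite = arr[np.isfinite(arr)]
    if finite.size < 3:
        raise ValueError("need at least 3 finite values")
    if fraction == 0 or finite.min() == finite.max():
        return arr.copy()
    lo = np.quantile(finite, fraction / 2.0)
    hi = np.quantile(finite, 1.0 - fraction / 2.0)
    return np.clip(arr, lo, hi)


def minmax_normalize(values):
    """Affine map of the finite range onto [0, 1]; constant input maps to 0.5."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite values")
    lo, hi = finite.min(), finite.max()
    if lo == hi:
        out = np.full_like(arr, 0.5)
        out[~np.isfinite(arr)] = np.nan
        return out
    return (arr - lo) / (hi - lo)


def winsorize_normalize(expression: pd.DataFrame, recipe: NormalizationRecipe) -> pd.DataFrame:
    """Apply per-gene winsorization followed by min-max normalization."""
    out = {}
    for gene, row in expression.iterrows():
        total_mass = 2.0 * recipe.tail_fraction(gene)  # winsorize() takes total mass
        clipped = winsorize(row.to_numpy(), total_mass)
        out[gene] = minmax_normalize(clipped)
    return pd.DataFrame(out, index=expression.columns).T


def dichotomize(values, cutoff: float | None = None) -> np.ndarray:
    """Median split into 'high'/'low'; ties at the cutoff are labelled low."""
    arr = np.asarray(values, dtype=float)
    if cutoff is None:
        cutoff = float(np.nanmedian(arr))
    labels = np.where(arr > cutoff, "high", "low")
    return labels


def dichotomize_matrix(expression: pd.DataFrame, recipe: NormalizationRecipe) -> pd.DataFrame:
    """Dichotomize each gene row of a pooled normalized matrix."""
    if recipe.dichotomy_rule == "pooled-all-genes-median":
        cutoff = float(np.nanmedian(expression.to_numpy()))
        return expression.apply(lambda row: pd.Series(dichotomize(row, cutoff), index=row.index), axis=1)
    return expression.apply(lambda row: pd.Series(dichotomize(row), index=row.index), axis=1)


def normalize_to_gaussian(values):
    """Two-step rank-based inverse-normal transform.

    Fractional ranks (mid-ranks for ties, Van der Waerden proportion
    r/(n+1)) are mapped through the standard-normal quantile function. The
    transform is monotone; tied inputs map to equal outputs.
    """
    arr = np.asarray(values, dtype=float)
    finite_mask = np.isfinite(arr)
    if finite_mask.sum() < 3:
        raise ValueError("need at least 3 finite values")
    out = np.full(arr.shape, np.nan)
    finite = arr[finite_mask]
    ranks = sps.rankdata(finite, method="average")
    out[finite_mask] = sps.norm.ppf(ranks / (finite.size + 1))
    return out


def pool_cohorts(
    cohort_tables: dict[str, pd.DataFrame],
    recipe: NormalizationRecipe,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate per-cohort sample tables and test each variable for
    cohort bias.

    ``cohort_tables`` maps cohort label -> sample-indexed table whose
    expression columns are already winsorized and normalized within the
    cohort. Returns ``(pooled, bias_report)`` where ``pooled`` carries the
    cohort label in ``recipe.cohort_column`` and ``bias_report`` has one row
    per tested variable with the test name, statistic and p-value.
    """
    frames = []
    for label, table in cohort_tables.items():
        t = table.copy()
        t[recipe.cohort_column] = label
        frames.append(t)
    pooled = pd.concat(frames, axis=0)
    if pooled.index.duplicated().any():
        dups = pooled.index[pooled.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids across cohorts: {dups[:5]}")

    if continuous is None:
        continuous = [
            c for c in pooled.columns
            if c != recipe.cohort_column and pd.api.types.is_numeric_dtype(pooled[c])
        ]
    if categorical is None:
        categorical = [
            c for c in pooled.columns
            if c != recipe.cohort_column and not pd.api.types.is_numeric_dtype(pooled[c])
        ]

    rows = []
    groups_by_cohort = pooled.groupby(recipe.cohort_column)
    for var in continuous:
        samples = [g[var].dropna().to_numpy() for _, g in groups_by_cohort]
        samples = [s for s in samples if s.size >= 2]
        if len(samples) < 2:
            continue
        stat, p = sps.f_oneway(*samples)
        rows.append({"variable": var, "test": "anova", "statistic": stat, "p_value": p})
    for var in categorical:
        table = pd.crosstab(pooled[var], pooled[recipe.cohort_column])
        table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        stat, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        rows.append({"variable": var, "test": "chi_square", "statistic": stat, "p_value": p})
    report = pd.DataFrame(rows, columns=["variable", "test", "statistic", "p_value"])
    return pooled, report
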