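"""Covariate-adjusted group statistics.

All comparisons reduce to exact least squares on small design matrices:

* ``ancova_group_test`` -- partial F for group indicators on top of an
  intercept + covariate model (one-way ANOVA when there are no covariates).
* ``adjusted_pairwise_t`` -- the t statistic of a two-group indicator in the
  same covariate-adjusted model ("age- and sex-corrected t-test").
* ``partial_correlation`` -- Pearson correlation of the residuals of x and y
  after regressing both on the covariates.
* ``chi_square_independence`` -- Pearson chi-square, no continuity correction.
* ``bonferroni`` -- p_adj = min(1, p * m).

Two-sided p values throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError


@dataclass
class StatResult:
    statistic_name: str              # "F" | "t" | "chi2" | "r"
    value: float
    df: tuple[float, ...] | float
    p_raw: float
    p_adjusted: float | None = None
    covariates: tuple[str, ...] = ()
    n: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_raw <= 1:
            raise ValidationError(f"p_raw out of range: {self.p_raw}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValidationError("p_adjusted must be >= p_raw")


def _as_design(covariates, n: int) -> tuple[np.ndarray, tuple[str, ...]]:
    if covariates is None:
        return np.empty((n, 0)), ()
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValidationError("covariate rows do not match sample size")
    names = tuple(f"cov{i}" for i in range(cov.shape[1]))
    return cov, names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(names[j])
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def ancova_group_test(
    y, group, covariates=None, covariate_names: tuple[str, ...] | None = None
) -> StatResult:
    """Partial F-test of group membership, adjusting for covariates."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    n = y.size
    levels = list(dict.fromkeys(group.tolist()))  # first-appearance order
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    for lev in levels:
        if (group == lev).sum() < 2:
            raise ValidationError(f"group {lev!r} has fewer than 2 subjects")
    cov, auto_names = _as_design(covariates, n)
    names = covariate_names or auto_names
    dummies = np.column_stack([(group == lev).astype(float) for lev in levels[1:]])
    X_full = np.column_stack([np.ones(n), dummies, cov])
    X_red = np.column_stack([np.ones(n), cov])
    col_names = ["intercept"] + [f"group[{lev}]" for lev in levels[1:]] + list(names)
    _check_full_rank(X_full, col_names)
    _, rss_full = _ols_rss(X_full, y)
    _, rss_red = _ols_rss(X_red, y)
    df1 = len(levels) - 1
    df2 = n - X_full.shape[1]
    if df2 <= 0:
        raise ValidationError("not enough residual degrees of freedom")
    if rss_full <= 0:
        f_val = np.inf if rss_red > rss_full else 0.0
    else:
        f_val = ((rss_red - rss_full) / df1) / (rss_full / df2)
    f_val = max(f_val, 0.0)
    p = float(sps.f.sf(f_val, df1, df2))
    return StatResult("F", float(f_val), (float(df1), float(df2)), p,
                      covariates=tuple(names), n=n)


def adjusted_pairwise_t(
    y, group, pair: tuple[str, str], covariates=None,
    covariate_names: tuple[str, ...] | None = None,
) -> StatResult:
    """t for the indicator of pair[1] vs pair[0] in a covariate-adjusted model."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    mask = np.isin(group, list(pair))
    if (group == pair[0]).sum() == 0 or (group == pair[1]).sum() == 0:
        raise ValidationError(f"empty group in pair {pair}")
    y = y[mask]
    g = group[mask]
    n = y.size
    cov_all, auto_names = _as_design(covariates, group.size)
    cov = cov_all[mask]
    names = covariate_names or auto_names
    indicator = (g == pair[1]).astype(float)
    X = np.column_stack([np.ones(n), indicator, cov])
    col_names = ["intercept", f"group[{pair[1]}]"] + list(names)
    _check_full_rank(X, col_names)
    beta, rss = _ols_rss(X, y)
    df = n - X.shape[1]
    if df <= 0:
        raise ValidationError("not enough residual degrees of freedom")
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t_val = beta[1] / se if se > 0 else np.inf * np.sign(beta[1])
    p = float(2 * sps.t.sf(abs(t_val), df))
    return StatResult("t", float(t_val), float(df), p,
                      covariates=tuple(names), n=n)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """p_adj = min(1, p * m); m defaults to the family size len(p_values)."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValidationError("family size m must be >= number of p values")
    return [min(1.0, p * m) for p in ps]


def chi_square_independence(counts) -> StatResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValidationError("contingency table must be 2-D")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValidationError("counts must be nonnegative integers")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValidationError("contingency table has a zero margin")
    total = table.sum()
    expected = np.outer(rows, cols) / total
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    return StatResult("chi2", chi2, float(df), p, n=int(total))


def partial_correlation(
    x, y, covariates=None, covariate_names: tuple[str, ...] | None = None
) -> StatResult:
    """Correlation of x and y after removing covariate effects from both."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    cov, auto_names = _as_design(covariates, n)
    names = covariate_names or auto_names
    c = cov.shape[1]
    if n <= c + 2:
        raise ValidationError("need n > number of covariates + 2")
    X = np.column_stack([np.ones(n), cov])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if rx.std() < 1e-12 * max(1.0, np.abs(x).max()) or \
       ry.std() < 1e-12 * max(1.0, np.abs(y).max()):
        raise ValidationError("degenerate residuals: zero variance after adjustment")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2 - c
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t_val = r * np.sqrt(df / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t_val), df))
    return StatResult("r", r, float(df), p, covariates=tuple(names), n=n)
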