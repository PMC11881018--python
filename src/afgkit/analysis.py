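"""Correlation and regression layer of the analysis pipeline.

Rank correlations (Spearman) with Holm-Bonferroni correction across the
battery's variable pairs, and SPSS-style forward stepwise OLS regression
(entry p < .05 on the partial F, removal p > .10) reporting per-step
adjusted R-squared and standardized coefficients.  The latent-variable
models live in :mod:`afgkit.sem` and are re-exported here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .sem import (  # noqa: F401  (re-exported: the SEM layer is part of the pipeline)
    SemModelSpec, SemFit, BootstrapResult,
    sem_fit, fit_indices, bootstrap_rmsea, build_paper_models,
)

__all__ = [
    "spearman_matrix",
    "holm_adjust",
    "StepwiseResult",
    "StepwiseStep",
    "stepwise_fit",
    "SemModelSpec", "SemFit", "BootstrapResult",
    "sem_fit", "fit_indices", "bootstrap_rmsea", "build_paper_models",
]


def spearman_matrix(table: pd.DataFrame, columns=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman correlations with two-sided p-values.

    Ties receive average ranks; p-values use the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 degrees of freedom.
    Constant columns yield NaN entries (flagged with a warning).
    """
    cols = list(columns) if columns is not None else list(table.columns)
    if len(table.dropna(subset=cols, how="all")) < 3:
        raise ValueError("need at least 3 complete rows")
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                warnings.warn(f"constant column in pair ({cols[i]}, {cols[j]}); rho undefined")
                r = p = np.nan
            else:
                res = stats.spearmanr(x, y)
                r, p = float(res.statistic), float(res.pvalue)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    np.fill_diagonal(pval.values, 0.0)
    return rho, pval


def holm_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values.

    Sorted ascending, p_(i) is multiplied by (m - i + 1), the running
    maximum is enforced (monotonicity) and results are capped at 1.  ``m``
    defaults to the number of p-values; pass it explicitly when the family
    of tests is larger than the vector supplied (e.g. 21 unique pairs of a
    7-variable battery).
    """
    p = np.asarray(list(pvals), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    m = k if m is None else int(m)
    if m < k:
        raise ValueError("family size m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    adj = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, p[idx] * (m - rank))
        adj[idx] = min(running, 1.0)
    return adj


@dataclass(frozen=True)
class StepwiseStep:
    variable: str
    beta_std: float
    adj_r2: float
    p_enter: float


@dataclass(frozen=True)
class StepwiseResult:
    steps: tuple[StepwiseStep, ...]
    selected: tuple[str, ...]
    final_adj_r2: float
    final_r2: float
    n: int

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.variable, s.beta_std, s.adj_r2, s.p_enter) for s in self.steps],
            columns=["variable", "beta_std", "adj_r2", "p"],
        )


def stepwise_fit(
    table: pd.DataFrame,
    outcome: str,
    candidates,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> StepwiseResult:
    """Forward stepwise OLS with SPSS default entry/removal criteria.

    At each step the candidate with the smallest partial-F p-value enters if
    p < ``entry_p`` (ties broken by larger absolute partial correlation);
    after each entry, included predictors with p > ``removal_p`` are
    removed.  Collinear candidates (no added rank) are dropped with a
    warning.  Coefficients are standardized (fitted on z-scores); per-step
    adjusted R-squared refers to the model after the step's entry.
    """
    candidates = list(candidates)
    data = table[[outcome] + candidates].dropna().astype(float)
    n = len(data)
    if n <= len(candidates) + 2:
        raise ValueError("need n > number of candidates + 2")
    z = (data - data.mean()) / data.std(ddof=1)
    y = z[outcome]

    selected: list[str] = []
    steps: list[StepwiseStep] = []
    pool = list(candidates)
    while pool:
        best_var, best_p, best_pc = None, None, 0.0
        for var in list(pool):
            X = sm.add_constant(z[selected + [var]])
            if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
                warnings.warn(f"dropping collinear candidate {var!r}")
                pool.remove(var)
                continue
            fit = sm.OLS(y, X).fit()
            p_var = float(fit.pvalues[var])
            resid_y = sm.OLS(y, sm.add_constant(z[selected])).fit().resid if selected else y
            resid_x = sm.OLS(z[var], sm.add_constant(z[selected])).fit().resid if selected else z[var]
            pc = abs(float(np.corrcoef(resid_y, resid_x)[0, 1]))
            if best_p is None or p_var < best_p or (p_var == best_p and pc > best_pc):
                best_var, best_p, best_pc = var, p_var, pc
        if best_var is None or best_p is None or best_p >= entry_p:
            break
        selected.append(best_var)
        pool.remove(best_var)
        fit = sm.OLS(y, sm.add_constant(z[selected])).fit()
        steps.append(StepwiseStep(
            variable=best_var,
            beta_std=float(fit.params[best_var]),
            adj_r2=float(fit.rsquared_adj),
            p_enter=best_p,
        ))
        # backward pass: drop predictors whose partial p rose above removal_p
        changed = True
        while changed and len(selected) > 1:
            fit = sm.OLS(y, sm.add_constant(z[selected])).fit()
            worst = max(selected, key=lambda v: float(fit.pvalues[v]))
            if float(fit.pvalues[worst]) > removal_p:
                selected.remove(worst)
                pool.append(worst)
            else:
                changed = False

    if selected:
        fit = sm.OLS(y, sm.add_constant(z[selected])).fit()
        final_adj, final_r2 = float(fit.rsquared_adj), float(fit.rsquared)
    else:
        final_adj = final_r2 = 0.0
    return StepwiseResult(tuple(steps), tuple(selected), final_adj, final_r2, n)
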