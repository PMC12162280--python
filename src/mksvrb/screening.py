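"""Baseline and feature-selection statistics for binary clinical cohorts.

Implements the screening pipeline of the study protocol: normality-gated
two-group comparisons (Shapiro-Wilk per group, then Welch t-test or
Mann-Whitney U), Pearson chi-square for categorical covariates, a pairwise
correlation/collinearity filter that drops the less significant member of any
highly correlated pair, and univariate/multivariate logistic regression with
odds ratios and Wald 95% confidence intervals.  The logistic fitter is a
plain maximum-likelihood IRLS; tests cross-check it against an independent
reference implementation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort import Cohort

log = logging.getLogger(__name__)

NORMALITY_ALPHA = 0.05


class SeparationError(RuntimeError):
    """Quasi-complete separation: the logistic MLE diverges."""


@dataclass
class GroupComparison:
    variable: str
    test_used: str  # "t_test" | "mann_whitney" | "chi_square"
    statistic: float
    p_value: float
    summaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def compare_groups(
    values,
    group,
    kind: str,
    variable: str = "",
    yates: bool = False,
) -> GroupComparison:
    """Two-group comparison with a normality gate for continuous variables.

    Continuous: Shapiro-Wilk per group at α=0.05; both normal → Welch t-test,
    otherwise Mann-Whitney U (tie-corrected normal approximation).  Groups with
    fewer than 3 observations skip the normality test and fall back to
    Mann-Whitney with a logged warning.  Categorical: Pearson chi-square on the
    contingency table (Yates continuity correction by flag).
    """
    group = np.asarray(group)
    if not ((group == 1).any() and (group == -1).any()):
        raise ValueError("both groups must be non-empty")
    if kind == "categorical":
        values = np.asarray(values, dtype=object)
        table = pd.crosstab(pd.Series(values, name="v"), pd.Series(group, name="g"))
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=yates)
        return GroupComparison(variable, "chi_square", float(chi2), float(p), {"counts": table})

    values = np.asarray(values, dtype=float)
    x = values[group == 1]
    y = values[group == -1]
    if min(len(x), len(y)) < 3:
        log.warning("group below 3 observations for %r; falling back to Mann-Whitney", variable)
        normal = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = stats.shapiro(x).pvalue > NORMALITY_ALPHA and stats.shapiro(y).pvalue > NORMALITY_ALPHA
    if normal:
        res = stats.ttest_ind(x, y, equal_var=False)
        summ = {
            "relapse": (float(np.mean(x)), float(np.std(x, ddof=1))),
            "no_relapse": (float(np.mean(y)), float(np.std(y, ddof=1))),
        }
        return GroupComparison(variable, "t_test", float(res.statistic), float(res.pvalue), summ)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    summ = {
        "relapse": (float(np.median(x)), float(np.percentile(x, 75) - np.percentile(x, 25))),
        "no_relapse": (float(np.median(y)), float(np.percentile(y, 75) - np.percentile(y, 25))),
    }
    return GroupComparison(variable, "mann_whitney", float(res.statistic), float(res.pvalue), summ)


def collinearity_filter(
    cohort: Cohort,
    candidates: list[str],
    r_threshold: float = 0.7,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Drop the less significant member of each highly correlated pair.

    Computes the Pearson correlation matrix of the candidate continuous
    columns; for every pair with |r| ≥ ``r_threshold`` (strongest first), the
    member whose two-group comparison p-value is larger is dropped.  Returns
    (retained, dropped, correlation matrix).
    """
    if not candidates:
        return [], [], pd.DataFrame()
    data = cohort.frame[candidates].astype(float)
    corr = data.corr(method="pearson")
    pvals = {
        name: compare_groups(data[name].to_numpy(), cohort.labels, "continuous", name).p_value
        for name in candidates
    }
    pairs = [
        (abs(corr.iloc[i, j]), candidates[i], candidates[j])
        for i in range(len(candidates))
        for j in range(i + 1, len(candidates))
        if abs(corr.iloc[i, j]) >= r_threshold
    ]
    dropped: list[str] = []
    for _, a, b in sorted(pairs, reverse=True):
        if a in dropped or b in dropped:
            continue
        loser = a if pvals[a] > pvals[b] else b
        dropped.append(loser)
    retained = [c for c in candidates if c not in dropped]
    return retained, dropped, corr


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    Odds ratios exp(β) with 95% CI exp(β ± 1.96·SE); the intercept carries no
    odds ratio.  Reference categorical levels are absent (absorbed in the
    intercept via reference-drop coding).
    """

    names: list[str]  # without intercept
    intercept: float
    coef: np.ndarray
    se: np.ndarray  # aligned to [intercept] + names
    p_values: np.ndarray  # aligned to [intercept] + names
    loglik: float
    converged: bool
    iterations: int

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - 1.96 * self.se[1:])

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + 1.96 * self.se[1:])

    def term_p(self, name: str) -> float:
        return float(self.p_values[1 + self.names.index(name)])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "OR": self.odds_ratios,
                "ci_low": self.ci_lower,
                "ci_high": self.ci_upper,
                "p": self.p_values[1:],
            }
        )


def logistic_fit(
    design: np.ndarray,
    labels: np.ndarray,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Binary logistic regression by iteratively reweighted least squares.

    ``design`` has no intercept column (one is prepended internally); labels
    are ±1.  Columns that are identically zero carry no information and are
    excluded (an all-zero design therefore yields the intercept-only model).
    Non-convergence or |coefficient| > 15 raises :class:`SeparationError`
    naming the offending column.
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    labels = np.asarray(labels)
    y = (labels == 1).astype(float)
    n = len(y)
    if design.shape[0] != n:
        raise ValueError("design and labels disagree in length")
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("both classes must be present")
    if names is None:
        names = [f"x{j}" for j in range(design.shape[1])]
    keep = [j for j in range(design.shape[1]) if np.any(design[:, j] != 0.0)]
    names_kept = [names[j] for j in keep]
    X = np.column_stack([np.ones(n)] + [design[:, j] for j in keep])
    if n <= X.shape[1]:
        raise ValueError("need more rows than fitted coefficients")

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        w = p * (1.0 - p)
        # Newton step via weighted least squares
        XtW = X.T * w
        H = XtW @ X
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(_offender(beta, names_kept)) from exc
        beta = beta + step
        if np.abs(beta).max() > 15.0:
            raise SeparationError(_offender(beta, names_kept))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    if not converged:
        raise SeparationError(_offender(beta, names_kept))
    eta = X @ beta
    p = expit(eta)
    w = p * (1.0 - p)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return LogisticFit(
        names=names_kept,
        intercept=float(beta[0]),
        coef=beta[1:].copy(),
        se=se,
        p_values=pvals,
        loglik=ll,
        converged=True,
        iterations=it,
    )


def _offender(beta: np.ndarray, names: list[str]) -> str:
    if len(beta) > 1:
        j = int(np.argmax(np.abs(beta[1:])))
        return f"separation suspected: coefficient diverging for column {names[j]!r}"
    return "separation suspected: intercept diverging"


def _column_design(cohort: Cohort, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Regression design on the natural scale: raw labs, reference-drop dummies."""
    cols: list[np.ndarray] = []
    terms: list[str] = []
    by_name = {c.name: c for c in cohort.schema}
    for name in names:
        col = by_name[name]
        if col.kind == "continuous":
            cols.append(cohort.frame[name].to_numpy(dtype=float))
            terms.append(name)
        else:
            vals = cohort.frame[name].astype(str).to_numpy()
            for lvl in col.categories[1:]:
                cols.append((vals == lvl).astype(float))
                terms.append(f"{name}={lvl}")
    design = np.column_stack(cols) if cols else np.zeros((cohort.n, 0))
    return design, terms


def univariate_screen(
    cohort: Cohort,
    alpha: float = 0.05,
    candidates: list[str] | None = None,
) -> tuple[dict[str, LogisticFit], list[str]]:
    """One single-variable logistic fit per candidate; select by any-term p ≤ α.

    A categorical variable is selected when ANY of its non-reference levels
    reaches p ≤ α, so a variable can enter the multivariate stage through one
    significant level.
    """
    if candidates is None:
        candidates = [c.name for c in cohort.schema]
    fits: dict[str, LogisticFit] = {}
    selected: list[str] = []
    for name in candidates:
        design, terms = _column_design(cohort, [name])
        fit = logistic_fit(design, cohort.labels, terms)
        fits[name] = fit
        if any(fit.term_p(t) <= alpha for t in fit.names):
            selected.append(name)
    return fits, selected


def multivariate_select(
    cohort: Cohort,
    entered: list[str],
    alpha: float = 0.05,
) -> tuple[LogisticFit, list[str]]:
    """Backward elimination at level α with categorical variables as blocks.

    Repeatedly refits the multivariable logistic model and drops the variable
    with the largest Wald p-value above α; a categorical variable is judged by
    the minimum p over its non-reference levels and is dropped (or kept) as a
    whole block.  Returns the final fit and the ordered elimination trace.
    """
    current = list(entered)
    trace: list[str] = []
    while True:
        design, terms = _column_design(cohort, current)
        fit = logistic_fit(design, cohort.labels, terms)
        worst_name, worst_p = None, alpha
        for name in current:
            term_ps = [fit.term_p(t) for t in fit.names if t == name or t.startswith(f"{name}=")]
            block_p = min(term_ps) if term_ps else 1.0
            if block_p > worst_p:
                worst_name, worst_p = name, block_p
        if worst_name is None:
            return fit, trace
        current.remove(worst_name)
        trace.append(worst_name)
        if not current:
            design, terms = _column_design(cohort, current)
            return logistic_fit(design, cohort.labels, terms), trace
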