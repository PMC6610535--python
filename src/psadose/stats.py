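"""Classical statistics used by the surrogacy evaluation.

Kaplan-Meier estimation with restricted mean survival, the log-rank test,
Mann-Whitney, Kruskal-Wallis, one-way ANOVA, Pearson correlation and a
logistic model for recurrence.  Every routine returns a structured result
record so the pipeline can serialize the full evidence trail behind each
surrogacy verdict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "TestResult",
    "KmEstimate",
    "CoefficientResult",
    "LogisticFitResult",
    "StatError",
    "SeparationError",
    "km_estimate",
    "log_rank_test",
    "mann_whitney",
    "kruskal_wallis",
    "one_way_anova",
    "logistic_fit",
    "pearson_r",
]

# exact Mann-Whitney enumeration is used up to this product of sample sizes
EXACT_MW_LIMIT = 400


class StatError(ValueError):
    """A statistic is undefined on the given input."""


class SeparationError(StatError):
    """Logistic MLE does not exist (perfect or quasi separation)."""


@dataclass(frozen=True)
class TestResult:
    """A hypothesis-test outcome: statistic, degrees of freedom, p-value."""

    name: str
    statistic: float
    p_value: float
    df: Optional[float] = None
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "note": self.note,
        }


@dataclass(frozen=True)
class KmEstimate:
    """Product-limit estimate with Greenwood variances and restricted mean.

    ``mean_survival`` is the area under the survival curve truncated at the
    largest observed time (the usual statistics-package convention for the
    "mean survival time"); its CI is mean +/- 1.96 * sqrt(variance) with the
    variance derived from the Greenwood formula.
    """

    times: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    mean_survival: float
    mean_ci: tuple[float, float]
    truncation_time: float
    n: int
    n_events: int
    all_censored: bool = False

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise StatError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise StatError(f"{name} contains non-finite values")
    return arr


def km_estimate(
    times: Sequence[float],
    events: Sequence[bool],
    truncation_time: Optional[float] = None,
) -> KmEstimate:
    """Kaplan-Meier product-limit estimate of the survival function.

    Parameters
    ----------
    times : durations (months), one per subject, > 0.
    events : True where the event (recurrence) was observed, False = censored.
    truncation_time : upper limit for the restricted-mean integral; defaults
        to the largest observed time.
    """
    t = _as_1d(times, "times")
    e = np.asarray(events, dtype=bool).ravel()
    if t.shape != e.shape:
        raise StatError("times and events differ in length")
    if np.any(t <= 0):
        raise StatError("survival times must be positive")

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    # Greenwood variance of S(t); lifelines stores the CI, recompute directly
    var = _greenwood_variance(t, e, timeline, surv)

    tau = float(truncation_time) if truncation_time is not None else float(t.max())
    all_censored = not bool(e.any())
    if all_censored:
        mean, mean_var = tau, 0.0
    else:
        with warnings.catch_warnings():
            # quadrature over the survival step function is exact but noisy
            warnings.simplefilter("ignore")
            mean, mean_var = restricted_mean_survival_time(
                kmf, t=tau, return_variance=True
            )
    se = float(np.sqrt(max(mean_var, 0.0)))
    return KmEstimate(
        times=timeline,
        survival=surv,
        greenwood_var=var,
        mean_survival=float(mean),
        mean_ci=(float(mean - 1.96 * se), float(mean + 1.96 * se)),
        truncation_time=tau,
        n=int(t.size),
        n_events=int(e.sum()),
        all_censored=all_censored,
    )


def _greenwood_variance(
    t: np.ndarray, e: np.ndarray, timeline: np.ndarray, surv: np.ndarray
) -> np.ndarray:
    cumulative = 0.0
    out = np.zeros_like(timeline)
    for k, ti in enumerate(timeline):
        d = float(np.sum((t == ti) & e))
        n_at_risk = float(np.sum(t >= ti))
        if d > 0 and n_at_risk > d:
            cumulative += d / (n_at_risk * (n_at_risk - d))
        elif d > 0 and n_at_risk == d:
            cumulative = np.inf
        out[k] = surv[k] ** 2 * cumulative if surv[k] > 0 else 0.0
    return out


def log_rank_test(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> TestResult:
    """k-sample log-rank test (hypergeometric variance, ties pooled)."""
    t = _as_1d(times, "times")
    e = np.asarray(events, dtype=bool).ravel()
    g = np.asarray(groups).ravel()
    if not (t.size == e.size == g.size):
        raise StatError("times, events and groups differ in length")
    labels = pd.unique(g)
    if labels.size < 2:
        raise StatError("log-rank test needs at least two groups")
    if not e.any():
        raise StatError("log-rank test undefined: no events observed")
    res = multivariate_logrank_test(t, g, e)
    df = labels.size - 1
    return TestResult(
        name="log-rank",
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=float(df),
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U test (two-sided).

    Exact null distribution when n_x * n_y <= 400 and there are no ties;
    otherwise the tie-corrected normal approximation.
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    has_ties = np.unique(np.concatenate([xa, ya])).size < xa.size + ya.size
    small = xa.size * ya.size <= EXACT_MW_LIMIT
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return TestResult(
        name="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        note=method,
    )


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with midranks and tie correction."""
    groups = [_as_1d(s, f"group {i}") for i, s in enumerate(samples)]
    if len(groups) < 2:
        raise StatError("Kruskal-Wallis needs at least two groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # fully tied data carry no rank information
        return TestResult(
            name="kruskal-wallis",
            statistic=0.0,
            p_value=1.0,
            df=float(len(groups) - 1),
            note="all observations identical",
        )
    res = sps.kruskal(*groups)
    return TestResult(
        name="kruskal-wallis",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(len(groups) - 1),
    )


def one_way_anova(samples: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA, F = MS_between / MS_within."""
    groups = [_as_1d(s, f"group {i}") for i, s in enumerate(samples)]
    k = len(groups)
    if k < 2:
        raise StatError("ANOVA needs at least two groups")
    n_total = sum(g.size for g in groups)
    if n_total <= k:
        raise StatError("ANOVA needs more observations than groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise StatError("ANOVA undefined: zero variance within and between groups")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.f_oneway(*groups)
    if not np.isfinite(res.statistic):
        raise StatError("ANOVA undefined: zero within-group variance")
    return TestResult(
        name="anova",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(k - 1),
        note=f"df=({k - 1},{n_total - k})",
    )


@dataclass(frozen=True)
class CoefficientResult:
    name: str
    coef: float
    se: float
    p_value: float


@dataclass(frozen=True)
class LogisticFitResult:
    """Maximum-likelihood logistic regression fit (intercept included)."""

    coefficients: tuple[CoefficientResult, ...]
    converged: bool
    n: int
    log_likelihood: float

    def coef(self, name: str) -> CoefficientResult:
        for c in self.coefficients:
            if c.name == name:
                return c
        raise KeyError(name)

    def as_records(self) -> list[dict]:
        return [
            {"term": c.name, "coef": c.coef, "se": c.se, "p_value": c.p_value}
            for c in self.coefficients
        ]


def logistic_fit(
    outcome: Sequence[bool],
    covariates: pd.DataFrame | np.ndarray,
    names: Optional[Sequence[str]] = None,
) -> LogisticFitResult:
    """Fit P(event) = logit^-1(b0 + X b) by maximum likelihood.

    Raises
    ------
    SeparationError
        when the outcome is perfectly (or quasi-) separated by the
        covariates, in which case the MLE does not exist.
    StatError
        when only one outcome class is present.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    if y.size == 0 or not set(np.unique(y)) <= {0.0, 1.0}:
        raise StatError("outcome must be binary and non-empty")
    if np.unique(y).size < 2:
        raise StatError("both outcome classes must be present")
    if isinstance(covariates, pd.DataFrame):
        X = covariates.to_numpy(dtype=float)
        cov_names = list(covariates.columns)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        cov_names = list(names) if names else [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] != y.size:
        raise StatError("outcome and covariates differ in length")

    Xd = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, Xd).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        except (PerfectSeparationWarning, PerfectSeparationError) as exc:
            raise SeparationError(f"logistic model separation detected: {exc}") from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"logistic fit failed (singular information matrix): {exc}"
            ) from exc
    params = np.asarray(fit.params, dtype=float)
    if not fit.mle_retvals.get("converged", False) or np.any(np.abs(params) > 1e3):
        raise SeparationError(
            "logistic fit did not converge to finite coefficients; "
            "likely separation"
        )
    all_names = ["intercept"] + cov_names
    coefs = tuple(
        CoefficientResult(
            name=nm,
            coef=float(params[i]),
            se=float(fit.bse[i]),
            p_value=float(fit.pvalues[i]),
        )
        for i, nm in enumerate(all_names)
    )
    return LogisticFitResult(
        coefficients=coefs,
        converged=True,
        n=int(y.size),
        log_likelihood=float(fit.llf),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson product-moment correlation with t-reference p-value."""
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if xa.size != ya.size:
        raise StatError("x and y differ in length")
    if xa.size < 3:
        raise StatError("Pearson correlation needs n >= 3")
    if np.var(xa) == 0 or np.var(ya) == 0:
        raise StatError("Pearson correlation undefined: zero variance")
    res = sps.pearsonr(xa, ya)
    return TestResult(
        name="pearson", statistic=float(res.statistic), p_value=float(res.pvalue)
    )
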