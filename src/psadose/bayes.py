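"""Bayesian dose-response model for the PSA slope, fitted by Gibbs sampling.

Model
-----
Let slope_ij be the PSA slope of patient j in dose group i (i = 1..k
ordered by total dose, k = 4 in the study design):

    slope_ij | mu_i, sigma2_slope  ~  Normal(mu_i, sigma2_slope)
    mu_i | mu_{i-1}, sigma2_mu     ~  Normal(mu_{i-1}, d_i * sigma2_mu)
    mu_0                           ~  Normal(m0, 1 / p0)        (diffuse)
    1 / sigma2_slope               ~  Gamma(a_s, b_s)
    1 / sigma2_mu                  ~  Gamma(a_m, b_m)

d_i is the square root of the distance between dose level i and the
previous level (the reference dose below level 1 defines d_1), so the
random walk linking mean responses at adjacent dose levels loosens with
the dose gap.  All full conditionals are conjugate, so a systematic-scan
Gibbs sampler draws exactly from them; no Metropolis steps are needed.

Priors default to the diffuse Gamma(0.001, 0.001) on both precisions and
Normal(0, variance 1e4) on the latent reference mean mu_0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GammaPrior",
    "DoseResponsePriors",
    "McmcConfig",
    "McmcChains",
    "ParamSummary",
    "DoseResponsePosterior",
    "build_distances",
    "gibbs_fit",
    "gelman_rubin",
    "summarize_posterior",
    "credible_overlap",
]


@dataclass(frozen=True)
class GammaPrior:
    shape: float = 0.001
    rate: float = 0.001

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("Gamma prior needs positive shape and rate")


@dataclass(frozen=True)
class DoseResponsePriors:
    """Hyperparameters: precision priors and the diffuse reference mean."""

    slope_precision: GammaPrior = field(default_factory=GammaPrior)
    rw_precision: GammaPrior = field(default_factory=GammaPrior)
    mu0_mean: float = 0.0
    mu0_precision: float = 1e-4  # variance 1e4


@dataclass(frozen=True)
class McmcConfig:
    """Sampler plan: ``n_iterations`` are the kept draws per chain."""

    n_chains: int = 3
    n_iterations: int = 12000
    n_burnin: int = 2000
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for the Gelman-Rubin diagnostic")
        if self.n_iterations <= 0 or self.n_burnin < 0 or self.thin <= 0:
            raise ValueError("iteration counts must be positive (burn-in >= 0)")


class McmcError(RuntimeError):
    """Non-finite state encountered during sampling."""


def build_distances(
    representative_doses: Sequence[float], reference_dose: float = 0.0
) -> np.ndarray:
    """Dose-distance factors d_i = sqrt(dose_i - dose_{i-1}).

    The first level is measured from ``reference_dose`` (the dose at which
    the latent baseline mean mu_0 lives), which must lie below it.
    """
    doses = np.asarray(representative_doses, dtype=float)
    if doses.ndim != 1 or doses.size < 1:
        raise ValueError("need at least one representative dose")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("representative doses must be strictly increasing")
    if reference_dose >= doses[0]:
        raise ValueError("reference dose must be below the first dose level")
    gaps = np.diff(np.concatenate([[reference_dose], doses]))
    return np.sqrt(gaps)


@dataclass(frozen=True)
class McmcChains:
    """Post-burn-in samples: array (n_chains, n_kept, n_params)."""

    parameters: tuple
    samples: np.ndarray
    config: McmcConfig

    def get(self, name: str) -> np.ndarray:
        """Samples of one parameter, shape (n_chains, n_kept)."""
        return self.samples[:, :, self.parameters.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).ravel()

    def to_frame(self) -> pd.DataFrame:
        n_chains, n_kept, _ = self.samples.shape
        frames = []
        for c in range(n_chains):
            df = pd.DataFrame(self.samples[c], columns=list(self.parameters))
            df.insert(0, "chain", c)
            df.insert(1, "draw", np.arange(n_kept))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _group_stats(slopes_by_group):
    groups = []
    for i, g in enumerate(slopes_by_group):
        arr = np.asarray(g, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError(f"dose group {i + 1} is empty; every group needs data")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"dose group {i + 1} contains non-finite slopes")
        groups.append(arr)
    return groups


def gibbs_fit(
    slopes_by_group: Sequence[Sequence[float]],
    distances: Sequence[float],
    priors: DoseResponsePriors = DoseResponsePriors(),
    config: McmcConfig = McmcConfig(),
    fix_sigma2_slope: Optional[float] = None,
    fix_sigma2_mu: Optional[float] = None,
) -> McmcChains:
    """Draw from the posterior of (mu_0..mu_k, sigma2_slope, sigma2_mu).

    Parameters
    ----------
    slopes_by_group : per-dose-group collections of PSA slopes, ordered by
        increasing dose; every group must be non-empty.
    distances : the k dose-distance factors from :func:`build_distances`.
    fix_sigma2_slope, fix_sigma2_mu : hold a variance fixed instead of
        sampling its precision (used by the limiting-case oracles).

    Chains start from overdispersed states (group mean +/- 2 group sd) and
    are fully reproducible from ``config.seed``.
    """
    groups = _group_stats(slopes_by_group)
    k = len(groups)
    d = np.asarray(distances, dtype=float)
    if d.size != k or np.any(d <= 0):
        raise ValueError(f"need {k} positive distance factors, got {d}")

    n_g = [g.size for g in groups]
    sum_g = [float(g.sum()) for g in groups]
    ss_g = [float(np.dot(g, g)) for g in groups]
    ybar = [s / n for s, n in zip(sum_g, n_g)]
    sd_g = [float(g.std(ddof=1)) if g.size > 1 else 0.0 for g in groups]
    pooled = np.concatenate(groups)
    pooled_var = float(pooled.var(ddof=1)) if pooled.size > 1 else 1.0
    pooled_var = max(pooled_var, 1e-8)
    n_total = int(sum(n_g))

    a_s, b_s = priors.slope_precision.shape, priors.slope_precision.rate
    a_m, b_m = priors.rw_precision.shape, priors.rw_precision.rate
    m0, p0 = priors.mu0_mean, priors.mu0_precision

    n_keep = config.n_iterations
    n_total_iter = config.n_burnin + n_keep * config.thin
    params = (
        ["mu0"] + [f"mu{i}" for i in range(1, k + 1)] + ["sigma2_slope", "sigma2_mu"]
    )
    out = np.empty((config.n_chains, n_keep, k + 3))

    # overdispersed starting offsets, cycled over chains
    offsets = [-2.0, 2.0, 0.0, -1.0, 1.0]
    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(config.n_chains)

    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        off = offsets[c % len(offsets)]
        mu = np.empty(k + 1)
        mu[0] = m0 + off * math.sqrt(pooled_var)
        for i in range(1, k + 1):
            spread = sd_g[i - 1] if sd_g[i - 1] > 0 else math.sqrt(pooled_var)
            mu[i] = ybar[i - 1] + off * spread
        tau_s = (
            1.0 / fix_sigma2_slope
            if fix_sigma2_slope is not None
            else math.exp(off / 2.0) / pooled_var
        )
        tau_m = (
            1.0 / fix_sigma2_mu
            if fix_sigma2_mu is not None
            else math.exp(-off / 2.0) / pooled_var
        )

        kept = 0
        for it in range(n_total_iter):
            # mu_0 | rest: prior + link to mu_1
            lk = tau_m / d[0]
            prec = p0 + lk
            mean = (p0 * m0 + lk * mu[1]) / prec
            mu[0] = mean + rng.standard_normal() / math.sqrt(prec)
            # mu_i | rest: data + link below + link above (when present)
            for i in range(1, k + 1):
                prec = n_g[i - 1] * tau_s + tau_m / d[i - 1]
                mean_num = tau_s * sum_g[i - 1] + (tau_m / d[i - 1]) * mu[i - 1]
                if i < k:
                    up = tau_m / d[i]
                    prec += up
                    mean_num += up * mu[i + 1]
                mu[i] = mean_num / prec + rng.standard_normal() / math.sqrt(prec)
            # precision of the slopes
            if fix_sigma2_slope is None:
                sse = 0.0
                for i in range(k):
                    sse += ss_g[i] - 2.0 * mu[i + 1] * sum_g[i] + n_g[i] * mu[i + 1] ** 2
                sse = max(sse, 0.0)
                tau_s = rng.gamma(a_s + 0.5 * n_total, 1.0 / (b_s + 0.5 * sse))
            # precision of the random walk
            if fix_sigma2_mu is None:
                rw = 0.0
                for i in range(1, k + 1):
                    rw += (mu[i] - mu[i - 1]) ** 2 / d[i - 1]
                tau_m = rng.gamma(a_m + 0.5 * k, 1.0 / (b_m + 0.5 * rw))
            state_sum = mu.sum() + tau_s + tau_m
            if not math.isfinite(state_sum):
                raise McmcError(f"non-finite state at chain {c}, iteration {it}")
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                out[c, kept, : k + 1] = mu
                out[c, kept, k + 1] = 1.0 / tau_s
                out[c, kept, k + 2] = 1.0 / tau_m
                kept += 1
        assert kept == n_keep
    return McmcChains(parameters=tuple(params), samples=out, config=config)


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Computes
    sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance and
    B = n * variance of the chain means.  Degenerate cases: all chains
    constant and equal -> 1.0; constant chains at different values -> inf.
    Note the (n-1)/n factor lets the statistic dip slightly below 1 when
    the between-chain variance is essentially zero.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    m, n = arr.shape
    if n < 10:
        raise ValueError("need >= 10 draws per chain")
    if np.all(arr == arr[:, :1]):  # every chain constant
        first = arr[:, 0]
        return 1.0 if np.all(first == first[0]) else float("inf")
    w = float(arr.var(axis=1, ddof=1).mean())
    b = float(n * arr.mean(axis=1).var(ddof=1))
    if w == 0.0:
        return 1.0 if b == 0.0 else float("inf")
    return math.sqrt(((n - 1) / n * w + b / n) / w)


@dataclass(frozen=True)
class ParamSummary:
    mean: float
    sd: float
    q2_5: float
    median: float
    q97_5: float
    rhat: float

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "2.5%": self.q2_5,
            "median": self.median,
            "97.5%": self.q97_5,
            "gelman_rubin": self.rhat,
        }


@dataclass(frozen=True)
class DoseResponsePosterior:
    """Posterior summaries per dose level plus the variance components."""

    dose_labels: tuple
    mu: tuple                      # ParamSummary per dose level, low to high
    mu0: ParamSummary
    sigma2_slope: ParamSummary
    sigma2_mu: ParamSummary

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, s in zip(self.dose_labels, self.mu):
            rows.append({"dose_level": label, **s.as_dict()})
        rows.append({"dose_level": "sigma2_slope", **self.sigma2_slope.as_dict()})
        rows.append({"dose_level": "sigma2_mu", **self.sigma2_mu.as_dict()})
        return pd.DataFrame(rows)

    def credible_interval(self, i: int) -> tuple[float, float]:
        return (self.mu[i].q2_5, self.mu[i].q97_5)


def _summarize_param(chains_2d: np.ndarray) -> ParamSummary:
    pooled = chains_2d.ravel()
    q = np.percentile(pooled, [2.5, 50.0, 97.5])
    return ParamSummary(
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)),
        q2_5=float(q[0]),
        median=float(q[1]),
        q97_5=float(q[2]),
        rhat=gelman_rubin(chains_2d),
    )


def summarize_posterior(
    chains: McmcChains, dose_labels: Optional[Sequence[str]] = None
) -> DoseResponsePosterior:
    """Pool chains into per-parameter mean/sd/percentiles/R-hat."""
    k = len(chains.parameters) - 3  # mu0 + k mus + 2 variances
    if dose_labels is None:
        dose_labels = [f"level {i}" for i in range(1, k + 1)]
    if len(dose_labels) != k:
        raise ValueError(f"expected {k} dose labels")
    mu_summaries = tuple(
        _summarize_param(chains.get(f"mu{i}")) for i in range(1, k + 1)
    )
    return DoseResponsePosterior(
        dose_labels=tuple(dose_labels),
        mu=mu_summaries,
        mu0=_summarize_param(chains.get("mu0")),
        sigma2_slope=_summarize_param(chains.get("sigma2_slope")),
        sigma2_mu=_summarize_param(chains.get("sigma2_mu")),
    )


def credible_overlap(posterior: DoseResponsePosterior) -> pd.DataFrame:
    """Pairwise 95% credible-interval overlap across dose levels."""
    rows = []
    k = len(posterior.mu)
    for i, j in combinations(range(k), 2):
        lo_i, hi_i = posterior.credible_interval(i)
        lo_j, hi_j = posterior.credible_interval(j)
        width = min(hi_i, hi_j) - max(lo_i, lo_j)
        rows.append(
            {
                "level_a": posterior.dose_labels[i],
                "level_b": posterior.dose_labels[j],
                "overlap": width >= 0,
                "overlap_width": max(width, 0.0),
            }
        )
    return pd.DataFrame(rows)
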