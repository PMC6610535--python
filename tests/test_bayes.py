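"""Gibbs sampler correctness against exact-posterior oracles, diagnostics."""

import numpy as np
import pytest

from psadose.bayes import (
    GammaPrior,
    McmcConfig,
    build_distances,
    credible_overlap,
    gelman_rubin,
    gibbs_fit,
    summarize_posterior,
)


def exact_gaussian_posterior(groups, d, s2_slope, s2_mu, m0=0.0, p0=1e-4):
    """Closed-form posterior of (mu_0..mu_k) with both variances fixed.

    The model is then jointly Gaussian: assemble the precision matrix of
    the chain prior plus the per-group likelihood terms and solve.  This is
    an independent route (dense linear algebra, no sampling) against which
    the Gibbs scan is checked.
    """
    k = len(groups)
    P = np.zeros((k + 1, k + 1))
    b = np.zeros(k + 1)
    P[0, 0] += p0
    b[0] += p0 * m0
    for i in range(1, k + 1):
        lam = 1.0 / (d[i - 1] * s2_mu)
        P[i, i] += lam
        P[i - 1, i - 1] += lam
        P[i, i - 1] -= lam
        P[i - 1, i] -= lam
        g = np.asarray(groups[i - 1], float)
        P[i, i] += g.size / s2_slope
        b[i] += g.sum() / s2_slope
    cov = np.linalg.inv(P)
    return cov @ b, cov


def mc_se(chains_2d):
    """Monte-Carlo standard error via effective sample size."""
    import arviz

    ess = float(arviz.ess(np.asarray(chains_2d)))
    return np.asarray(chains_2d).std(ddof=1) / np.sqrt(max(ess, 1.0))


class TestDistances:
    def test_stated_rule(self):
        d = build_distances((45, 60, 70, 75), reference_dose=0.0)
        assert d == pytest.approx(np.sqrt([45, 15, 10, 5]))

    def test_equal_spacing_gives_equal_factors(self):
        d = build_distances((50, 60, 70, 80), reference_dose=40)
        assert np.allclose(d, d[0])

    def test_unit_gaps_identity(self):
        d = build_distances((2, 3, 4, 5), reference_dose=1)
        assert np.allclose(d, 1.0)

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            build_distances((45, 45, 70, 75))
        with pytest.raises(ValueError):
            build_distances((45, 60), reference_dose=50)


class TestGelmanRubin:
    def test_identical_chains_unity(self):
        # B = 0 exactly; the (n-1)/n factor gives sqrt((n-1)/n) ~ 1
        c = np.tile(np.linspace(0, 1, 100), (3, 1))
        assert gelman_rubin(c) == pytest.approx(np.sqrt(99 / 100), abs=1e-12)
        assert gelman_rubin(c) == pytest.approx(1.0, abs=0.01)

    def test_constant_equal_chains_defined_as_one(self):
        assert gelman_rubin(np.full((2, 50), 3.14)) == 1.0

    def test_constant_disjoint_chains_infinite(self):
        c = np.vstack([np.zeros(50), np.ones(50)])
        assert gelman_rubin(c) == np.inf

    def test_converged_chains_near_one(self, rng):
        c = rng.normal(size=(2, 10000))
        assert gelman_rubin(c) < 1.01

    def test_disjoint_supports_much_greater_than_one(self, rng):
        c = np.vstack(
            [rng.normal(0, 0.1, 2000), rng.normal(10, 0.1, 2000)]
        )
        assert gelman_rubin(c) > 10


class TestGibbsOracles:
    def test_single_group_matches_quadrature(self):
        """Tiny one-group instance vs dense numerical integration.

        With both variances fixed the exact posterior density of
        (mu_0, mu_1) is known up to a constant; integrating it over a fine
        grid gives E[mu_1] without any sampling.
        """
        data = np.array([-0.2, -0.4])
        s2_slope, s2_mu = 1.0, 1.0
        d = np.array([1.0])
        mu0g = np.linspace(-40, 40, 1201)
        mu1g = np.linspace(-6, 6, 1201)
        M0, M1 = np.meshgrid(mu0g, mu1g, indexing="ij")
        logp = (
            -0.5 * 1e-4 * M0**2
            - 0.5 * (M1 - M0) ** 2 / (d[0] * s2_mu)
            - 0.5 * np.sum((data[:, None, None] - M1[None]) ** 2, axis=0) / s2_slope
        )
        w = np.exp(logp - logp.max())
        mu1_exact = float((w * M1).sum() / w.sum())

        cfg = McmcConfig(n_chains=2, n_iterations=8000, n_burnin=1000, seed=11)
        ch = gibbs_fit([data], d, config=cfg, fix_sigma2_slope=s2_slope,
                       fix_sigma2_mu=s2_mu)
        est = ch.pooled("mu1").mean()
        assert abs(est - mu1_exact) < 3 * mc_se(ch.get("mu1"))

    def test_multi_group_matches_closed_form(self):
        groups = [[-0.2, -0.4, -0.1], [-0.3, -0.25], [-0.15, -0.2, -0.35], [-0.4]]
        d = build_distances((45, 60, 70, 75))
        mean, _ = exact_gaussian_posterior(groups, d, s2_slope=0.02, s2_mu=0.05)
        cfg = McmcConfig(n_chains=2, n_iterations=6000, n_burnin=1000, seed=5)
        ch = gibbs_fit(groups, d, config=cfg, fix_sigma2_slope=0.02,
                       fix_sigma2_mu=0.05)
        for i in range(1, 5):
            est = ch.pooled(f"mu{i}").mean()
            assert abs(est - mean[i]) < 3 * mc_se(ch.get(f"mu{i}"))

    def test_flat_link_recovers_group_means(self, rng):
        """With the random walk flattened, each mu_i tracks its group mean."""
        groups = [rng.normal(m, 0.15, size=30)
                  for m in (-0.1, -0.25, -0.2, -0.35)]
        d = build_distances((45, 60, 70, 75))
        cfg = McmcConfig(n_chains=2, n_iterations=20000, n_burnin=2000, seed=7)
        ch = gibbs_fit(groups, d, config=cfg, fix_sigma2_mu=1e8)
        for i, g in enumerate(groups, start=1):
            est = ch.pooled(f"mu{i}").mean()
            assert abs(est - g.mean()) < 2 * max(mc_se(ch.get(f"mu{i}")), 1e-4)

    def test_tight_link_shrinks_group_means_monotonically(self, rng):
        groups = [rng.normal(m, 0.1, size=10)
                  for m in (-0.1, -0.4, -0.2, -0.5)]
        d = build_distances((45, 60, 70, 75))
        spreads = []
        for s2_mu in (1.0, 1e-2, 1e-4, 1e-6):
            cfg = McmcConfig(n_chains=2, n_iterations=3000, n_burnin=500, seed=3)
            ch = gibbs_fit(groups, d, config=cfg, fix_sigma2_mu=s2_mu)
            means = [ch.pooled(f"mu{i}").mean() for i in range(1, 5)]
            spreads.append(max(means) - min(means))
        # smoothing limit: dispersion shrinks as the link tightens
        for a, b in zip(spreads, spreads[1:]):
            assert b <= a + 1e-3

    def test_seeded_determinism(self):
        groups = [[-0.2, -0.3], [-0.25], [-0.1, -0.15], [-0.4, -0.2]]
        d = build_distances((45, 60, 70, 75))
        cfg = McmcConfig(n_chains=2, n_iterations=200, n_burnin=50, seed=42)
        a = gibbs_fit(groups, d, config=cfg)
        b = gibbs_fit(groups, d, config=cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="group 2"):
            gibbs_fit([[-0.1], [], [-0.2], [-0.3]],
                      build_distances((45, 60, 70, 75)))

    def test_parameter_recovery_synthetic(self):
        """Posterior means recover known group means at n=60/group."""
        rng = np.random.default_rng(99)
        mu_true = (-0.1543, -0.2733, -0.2203, -0.332)
        groups = [rng.normal(m, 0.17, size=60) for m in mu_true]
        d = build_distances((45, 60, 70, 75))
        cfg = McmcConfig(n_chains=2, n_iterations=2000, n_burnin=500, seed=12)
        post = summarize_posterior(gibbs_fit(groups, d, config=cfg))
        for s, m in zip(post.mu, mu_true):
            assert abs(s.mean - m) < 3 * s.sd


class TestSummaries:
    def make_chains(self, rng):
        groups = [rng.normal(-0.2, 0.15, size=25) for _ in range(4)]
        d = build_distances((45, 60, 70, 75))
        cfg = McmcConfig(n_chains=3, n_iterations=1500, n_burnin=300, seed=2)
        return gibbs_fit(groups, d, config=cfg)

    def test_quantile_ordering_and_rhat(self, rng):
        post = summarize_posterior(self.make_chains(rng))
        for s in post.mu + (post.sigma2_slope, post.sigma2_mu):
            assert s.q2_5 <= s.median <= s.q97_5
            assert s.rhat >= 1 - 1e-3  # (n-1)/n floor at n=1500 draws
        frame = post.to_frame()
        assert len(frame) == 6  # 4 dose levels + 2 variance components

    def test_constant_chains_collapse(self):
        import psadose.bayes as b

        chains = b.McmcChains(
            parameters=("mu0", "mu1", "sigma2_slope", "sigma2_mu"),
            samples=np.full((2, 50, 4), 1.5),
            config=McmcConfig(n_chains=2, n_iterations=50, n_burnin=0, seed=0),
        )
        s = b._summarize_param(chains.get("mu1"))
        assert s.mean == s.median == s.q2_5 == s.q97_5 == 1.5
        assert s.sd == 0.0
        assert s.rhat == 1.0

    def test_credible_overlap_report(self, rng):
        post = summarize_posterior(self.make_chains(rng))
        rep = credible_overlap(post)
        assert len(rep) == 6  # all dose-level pairs
        # identical data-generating process: intervals overlap heavily
        assert rep["overlap"].all()
        widths = rep["overlap_width"]
        assert (widths >= 0).all()

    def test_disjoint_intervals_not_overlapping(self):
        from psadose.bayes import DoseResponsePosterior, ParamSummary

        def ps(lo, hi):
            mid = (lo + hi) / 2
            return ParamSummary(mid, (hi - lo) / 4, lo, mid, hi, 1.0)

        post = DoseResponsePosterior(
            dose_labels=("a", "b"),
            mu=(ps(-0.29, -0.03), ps(-2.0, -1.5)),
            mu0=ps(-1, 1),
            sigma2_slope=ps(0.01, 0.02),
            sigma2_mu=ps(0.01, 0.02),
        )
        rep = credible_overlap(post)
        assert not rep.loc[0, "overlap"]
        assert rep.loc[0, "overlap_width"] == 0.0

    def test_priors_validate(self):
        with pytest.raises(ValueError):
            GammaPrior(shape=0.0)
        with pytest.raises(ValueError):
            McmcConfig(n_chains=1)
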