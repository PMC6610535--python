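"""Classical statistics against hand-computed and brute-force oracles."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps

from psadose.stats import (
    SeparationError,
    StatError,
    km_estimate,
    kruskal_wallis,
    log_rank_test,
    logistic_fit,
    mann_whitney,
    one_way_anova,
    pearson_r,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def logrank_by_hand(times, events, groups):
    """Textbook O-E chi-square over pooled event times (2 groups)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        d = (events & (times == t)).sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d1 = (events & (times == t) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, sps.chi2.sf(chi2, 1)


def mann_whitney_enumeration(x, y):
    """Exact two-sided p by enumerating every labeling of the pooled data."""
    pooled = np.concatenate([x, y])
    nx = len(x)

    def u_stat(xs, ys):
        return sum(np.sum(a > np.asarray(ys)) + 0.5 * np.sum(a == np.asarray(ys))
                   for a in xs)

    u_obs = min(u_stat(x, y), len(x) * len(y) - u_stat(x, y))
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        sel = np.zeros(len(pooled), bool)
        sel[list(idx)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        u = min(u, nx * (len(pooled) - nx) - u)
        if u <= u_obs + 1e-12:
            hits += 1
        total += 1
    return hits / total


def kruskal_by_hand(groups):
    """H from midranks with the tie-correction divisor."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_no_censoring_is_empirical_survival(self):
        est = km_estimate([1, 2, 3], [True, True, True])
        assert est.survival_at(1) == pytest.approx(2 / 3)
        assert est.survival_at(2) == pytest.approx(1 / 3)
        assert est.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        est = km_estimate([5, 10, 15], [False, False, False])
        assert est.all_censored
        assert np.all(est.survival == 1.0)
        assert est.mean_survival == pytest.approx(15.0)  # truncated mean

    def test_hand_product_limit_with_censoring(self):
        # times 1+, 2, 3, 4+, 5: S(2)=3/4, S(3)=1/2, S(5)=0
        est = km_estimate([1, 2, 3, 4, 5], [False, True, True, False, True])
        assert est.survival_at(2) == pytest.approx(3 / 4, abs=1e-10)
        assert est.survival_at(3) == pytest.approx(1 / 2, abs=1e-10)
        assert est.survival_at(5) == pytest.approx(0.0, abs=1e-10)
        # restricted mean = area under steps: 1*2 + .75*1 + .5*2 = 3.75
        assert est.mean_survival == pytest.approx(3.75, abs=1e-10)

    def test_greenwood_variance_by_hand(self):
        est = km_estimate([1, 2, 3], [True, True, True])
        # at t=1: S=2/3, var = S^2 * d/(n(n-d)) = (4/9)*(1/6)
        idx = list(est.times).index(1.0)
        assert est.greenwood_var[idx] == pytest.approx((4 / 9) * (1 / 6), abs=1e-10)

    def test_mean_ci_contains_mean(self):
        est = km_estimate([3, 6, 9, 12], [True, True, False, True])
        lo, hi = est.mean_ci
        assert lo <= est.mean_survival <= hi


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        e = [True] * 10
        g = ["a"] * 5 + ["b"] * 5
        res = log_rank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_tabulated_o_minus_e(self):
        t = [2, 4, 5, 7, 9, 3, 6, 8, 10, 12]
        e = [1, 1, 0, 1, 1, 1, 0, 1, 1, 0]
        g = ["a"] * 5 + ["b"] * 5
        chi2, p = logrank_by_hand(t, [bool(x) for x in e], g)
        res = log_rank_test(t, [bool(x) for x in e], g)
        assert res.statistic == pytest.approx(chi2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.df == 1

    def test_separated_groups_small_p(self):
        t = [1, 2, 3, 20, 21, 22, 23]
        e = [True] * 7
        g = ["early"] * 3 + ["late"] * 4
        assert log_rank_test(t, e, g).p_value < 0.05

    def test_no_events_undefined(self):
        with pytest.raises(StatError, match="no events"):
            log_rank_test([1, 2], [False, False], ["a", "b"])


class TestMannWhitney:
    def test_extreme_ordering(self):
        res = mann_whitney([1, 2], [3, 4])
        assert min(res.statistic, 4 - res.statistic) == 0

    def test_identical_samples_symmetric_u(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n_x n_y / 2

    @pytest.mark.parametrize(
        "x, y",
        [
            ([0.3, 1.1, 2.2], [0.7, 1.9, 2.5, 3.1]),
            ([5, 9, 11, 14], [1, 2, 3]),
            ([0.5, 4.5], [1.5, 2.5, 3.5]),
        ],
    )
    def test_exact_p_matches_enumeration(self, x, y):
        res = mann_whitney(x, y)
        assert res.note == "exact"
        assert res.p_value == pytest.approx(
            mann_whitney_enumeration(np.array(x, float), np.array(y, float)),
            abs=1e-10,
        )

    def test_ties_fall_back_to_asymptotic(self):
        res = mann_whitney([1, 2, 2], [2, 3, 4])
        assert res.note == "asymptotic"
        assert 0 <= res.p_value <= 1


class TestKruskalWallis:
    def test_all_identical_h_zero(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_ranked_toy_data(self):
        groups = [[1.0, 3.0, 5.0], [2.0, 4.0, 6.0], [7.0, 8.0]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(
            kruskal_by_hand([np.array(g) for g in groups]), abs=1e-10
        )

    def test_two_groups_equals_squared_standardized_u(self):
        """With two tie-free groups, H = z^2 of the Mann-Whitney statistic."""
        x = [1.2, 3.4, 5.1, 7.7]
        y = [2.2, 4.0, 6.6, 8.8, 9.9]
        h = kruskal_wallis([x, y]).statistic
        nx, ny = len(x), len(y)
        u = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
        z = (u - nx * ny / 2) / np.sqrt(nx * ny * (nx + ny + 1) / 12)
        assert h == pytest.approx(z**2, abs=1e-10)


class TestAnova:
    def test_hand_sums_of_squares(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [5.0, 6.0, 7.0]]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
        f_hand = (ssb / 2) / (ssw / 6)
        res = one_way_anova(groups)
        assert res.statistic == pytest.approx(f_hand, abs=1e-10)

    def test_equal_means_small_f(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 30)
        res = one_way_anova([base, base + 0.0, base * 1.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_null_p_uniform(self, rng):
        """Under H0 the ANOVA p-value is uniform (KS sanity, 300 reps)."""
        ps = []
        for _ in range(300):
            groups = [rng.normal(0, 1, 20) for _ in range(3)]
            ps.append(one_way_anova(groups).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_rejected(self):
        with pytest.raises(StatError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])


class TestLogistic:
    def test_two_by_two_log_odds_ratio(self):
        # binary covariate: 2x2 table a=8,b=2 (x=1), c=3,d=7 (x=0)
        x = np.array([1] * 10 + [0] * 10, float)
        y = np.array([1] * 8 + [0] * 2 + [1] * 3 + [0] * 7, float)
        fit = logistic_fit(y.astype(bool), x[:, None], names=["x"])
        lor = np.log((8 * 7) / (2 * 3))
        assert fit.coef("x").coef == pytest.approx(lor, abs=1e-6)

    def test_independent_covariate_near_zero(self, rng):
        n = 2000
        y = rng.uniform(size=n) < 0.5
        x = rng.normal(size=n)
        fit = logistic_fit(y, x[:, None], names=["x"])
        assert abs(fit.coef("x").coef) < 0.15
        assert fit.coef("x").p_value > 0.01

    def test_perfect_separation_raises(self):
        y = np.array([0, 0, 0, 1, 1, 1], bool)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        with pytest.raises(SeparationError):
            logistic_fit(y, x[:, None])

    def test_single_class_rejected(self):
        with pytest.raises(StatError):
            logistic_fit(np.ones(5, bool), np.arange(5.0)[:, None])


class TestPearson:
    def test_perfect_linear(self):
        res = pearson_r([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.statistic == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r_hand = np.sum((x - 3) * (y - 3)) / np.sqrt(
            np.sum((x - 3) ** 2) * np.sum((y - 3) ** 2)
        )
        assert pearson_r(x, y).statistic == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatError):
            pearson_r([1, 1, 1], [2, 3, 4])
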