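import numpy as np
import pytest
from scipy.stats import norm

from gmmdiag import (midrange_band, mixture_loglik, pct_change_deviation,
                     pointwise_loglik, prob_positive_slope,
                     slope_given_intercept, standardized_deviation_at_T,
                     trajectory_sd, waic)
from gmmdiag.draws import DrawsStore, params_to_row
from gmmdiag.params import ClassParams
from gmmdiag.summaries import heterogeneity_summary, loo

from .conftest import random_class_params, random_mixture


def cp_from_psi(psi11, psi12, psi22, beta=(1.0, 0.5, -0.05)):
    s1, s2 = np.sqrt(psi11), np.sqrt(psi22)
    rho = psi12 / (s1 * s2) if s1 > 0 and s2 > 0 else 0.0
    return ClassParams(*beta, sd_int=s1, sd_slope=s2, corr=rho)


class TestTrajectorySD:
    def test_at_time_zero(self):
        cp = cp_from_psi(0.49, 0.1, 0.04)
        assert trajectory_sd(cp, 0.0) == pytest.approx(0.7)

    def test_identity_psi_at_one(self):
        cp = cp_from_psi(1.0, 0.0, 1.0)
        assert trajectory_sd(cp, 1.0) == pytest.approx(np.sqrt(2))

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            cp = random_class_params(rng)
            t = rng.uniform(0, 4)
            zeta = rng.multivariate_normal(np.zeros(2), cp.psi, size=1_000_000)
            mc = (zeta[:, 0] + t * zeta[:, 1]).std()
            se = mc / np.sqrt(2 * 1_000_000)
            assert trajectory_sd(cp, t) == pytest.approx(mc, abs=4 * se)


class TestMidrangeBand:
    def test_zero_sd_collapses_to_mean(self):
        cp = cp_from_psi(0, 0, 0)
        lo, hi = midrange_band(cp, 2.0)
        assert lo == hi == pytest.approx(float(cp.mean(2.0)))

    def test_half_width_at_unit_sd(self):
        cp = cp_from_psi(1.0, 0.0, 0.0)
        lo, hi = midrange_band(cp, 0.0, coverage=0.5)
        assert (hi - lo) / 2 == pytest.approx(norm.ppf(0.75), abs=1e-12)
        assert (hi - lo) / 2 == pytest.approx(0.6745, abs=1e-4)

    def test_symmetric_about_mean(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            cp = random_class_params(rng)
            t = rng.uniform(0, 3)
            lo, hi = midrange_band(cp, t, coverage=rng.uniform(0.1, 0.9))
            assert (lo + hi) / 2 == pytest.approx(float(cp.mean(t)))


class TestConditionalSlopeSummaries:
    def test_slope_given_intercept(self):
        assert slope_given_intercept(cp_from_psi(1.0, 0.1, 0.2), 2.0) == \
            pytest.approx(0.2)
        assert slope_given_intercept(cp_from_psi(1.0, 0.0, 0.2), 5.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            slope_given_intercept(cp_from_psi(0.0, 0.0, 0.2), 1.0)

    def test_pct_change_formula(self):
        cp = cp_from_psi(1.0, 0.1, 0.2)
        assert pct_change_deviation(cp, 0.0, 8.0) == pytest.approx(80.0)
        assert pct_change_deviation(cp_from_psi(1, 0, 1), 0, 8) == 0.0

    def test_printed_147_percent_means_ratio_about_2_5(self):
        ratio = 1.0 + 147.0 / 100.0
        assert ratio == pytest.approx(2.47)
        assert round(ratio * 2) / 2 == 2.5  # "about 2.5 times as great"

    def test_standardized_deviation_identities(self):
        cp = cp_from_psi(1.0, 0.05, 0.01)
        assert standardized_deviation_at_T(cp, a0=-2, t0=1.0, T=1.0) == \
            pytest.approx(-2.0)
        flat = cp_from_psi(1.0, 0.0, 0.0)
        assert standardized_deviation_at_T(flat, a0=1.5, t0=0, T=8) == \
            pytest.approx(1.5)

    def test_standardized_deviation_matches_monte_carlo(self):
        cp = cp_from_psi(1.0, 0.05, 0.01)
        a0, t0, T = -2.0, 0.0, 8.0
        rng = np.random.default_rng(2)
        zeta = rng.multivariate_normal(np.zeros(2), cp.psi, size=1_000_000)
        z0 = zeta[:, 0] + t0 * zeta[:, 1]
        zT = zeta[:, 0] + T * zeta[:, 1]
        # E[deviation at T | deviation at t0 = a0 sd(t0)] via regression
        beta_hat = np.cov(z0, zT)[0, 1] / np.var(z0)
        mc = beta_hat * a0 * trajectory_sd(cp, t0) / trajectory_sd(cp, T)
        assert standardized_deviation_at_T(cp, a0, t0, T) == \
            pytest.approx(mc, rel=0.01)


class TestProbPositiveSlope:
    def test_independence_gives_half(self):
        for a0 in (-3, 0, 2):
            assert prob_positive_slope(0.0, a0) == pytest.approx(0.5)

    def test_published_class_two_example(self):
        # rho = 0.399, two SDs above the mean: an 81% chance of growing
        # faster than average
        p = prob_positive_slope(0.399, 2.0)
        assert round(100 * p) == 81

    def test_strong_negative_correlation_below_mean(self):
        p = prob_positive_slope(-0.742, -2.0)
        assert p == pytest.approx(norm.cdf(2.214), abs=5e-4)

    def test_monotone_in_rho_times_a0(self):
        vals = [prob_positive_slope(r, 1.5) for r in np.linspace(-0.9, 0.9, 7)]
        assert np.all(np.diff(vals) > 0)


class TestPointwiseAndWaic:
    @pytest.fixture()
    def three_draw_store(self):
        rng = np.random.default_rng(3)
        rows = [params_to_row(random_mixture(rng)) for _ in range(3)]
        return DrawsStore(n_classes=3, params=np.asarray(rows)[None],
                          lp=np.zeros((1, 3)))

    def test_rows_sum_to_mixture_loglik(self, three_draw_store,
                                        tiny_balanced_data):
        ll = pointwise_loglik(three_draw_store, tiny_balanced_data)
        assert ll.shape == (3, tiny_balanced_data.n_subjects)
        for s in range(3):
            assert ll[s].sum() == pytest.approx(
                mixture_loglik(three_draw_store.draw(0, s),
                               tiny_balanced_data))

    def test_single_draw_waic(self):
        ll = np.array([[-1.0, -2.0, -0.5]])
        elpd, p, w = waic(ll)
        assert p == 0.0
        assert elpd == pytest.approx(-3.5)
        assert w == pytest.approx(7.0)

    def test_duplicated_draws_unchanged(self):
        rng = np.random.default_rng(4)
        ll = rng.normal(-2, 0.3, size=(5, 8))
        a = waic(ll)
        b = waic(np.vstack([ll, ll]))
        assert b == pytest.approx(a, rel=1e-12)

    def test_two_by_two_hand_computation(self):
        ll = np.log(np.array([[0.2, 0.5], [0.4, 0.1]]))
        elpd, p, w = waic(ll)
        lppd = np.log(0.3) + np.log(0.3)
        p_hand = (np.var([np.log(0.2), np.log(0.4)])
                  + np.var([np.log(0.5), np.log(0.1)]))
        assert elpd == pytest.approx(lppd - p_hand)
        assert w == pytest.approx(-2 * (lppd - p_hand))

    def test_waic_agrees_with_arviz(self):
        import arviz as az
        import warnings

        rng = np.random.default_rng(5)
        ll = rng.normal(-2, 0.4, size=(40, 15))
        elpd, p, w = waic(ll)
        ds = az.from_dict(log_likelihood={"y": ll[None]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = az.waic(ds, scale="log")
        assert elpd == pytest.approx(float(ref.elpd_waic), rel=1e-9)
        assert p == pytest.approx(float(ref.p_waic), rel=1e-9)

    def test_loo_runs_and_is_close_to_waic(self):
        rng = np.random.default_rng(6)
        ll = rng.normal(-2, 0.2, size=(80, 12))
        elpd_loo, p_loo = loo(ll)
        elpd_waic, _, _ = waic(ll)
        assert elpd_loo == pytest.approx(elpd_waic, abs=0.5)


def test_heterogeneity_summary_structure():
    cp = cp_from_psi(0.5, 0.05, 0.02)
    h = heterogeneity_summary(cp, t0=0.0, T=3.0, a0=2.0)
    assert h["band_lower"].shape == h["grid"].shape
    assert np.all(h["band_upper"] >= h["band_lower"])
    assert np.all(h["sd"] >= 0)
    assert h["slope_on_intercept"] == pytest.approx(0.1)


@pytest.mark.slow
def test_waic_prefers_true_class_count():
    """On well-separated three-class data the mixed-predictive WAIC
    should pick K = 3 over K = 2 and K = 4 in most replicates."""
    from gmmdiag import GrowthMixtureModel, simulate_gmm
    from gmmdiag.simulate import well_separated_params

    truth = well_separated_params()
    wins = 0
    for rep in range(3):
        data = simulate_gmm(truth, n_subjects=200, seed=500 + rep).dataset
        waics = {}
        for K in (2, 3, 4):
            model = GrowthMixtureModel(data, n_classes=K)
            res = model.sample(n_chains=1, warmup=250, iters=250,
                               seed=9 + rep)
            waics[K] = res.waic()[2]
        if min(waics, key=waics.get) == 3:
            wins += 1
    assert wins >= 2
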