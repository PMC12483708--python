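import numpy as np
import pytest

from gmmdiag import GrowthMixtureModel, simulate_gmm
from gmmdiag.convergence import convergence_stats, ebfmi
from gmmdiag.draws import DrawsStore, param_names, params_to_row, row_to_params
from gmmdiag.inference import fit_ml, initialize_params, sample_posterior
from gmmdiag.params import ClassParams, MixtureParams, ModelSpec, PriorConfig

from ._reference import reference_rank_rhat


def make_store(x: np.ndarray, energy=None) -> DrawsStore:
    """Wrap a (chains, draws) scalar series as a one-class DrawsStore with
    the series in the beta0 slot."""
    n_chains, n_iter = x.shape
    P = 8  # K = 1
    params = np.zeros((n_chains, n_iter, P))
    params[:, :, 0] = 1.0            # pi.1
    params[:, :, 1] = x              # beta0.1
    params[:, :, 4] = 0.5            # sd_int
    params[:, :, 5] = 0.5            # sd_slope
    params[:, :, 7] = 1.0            # sigma
    return DrawsStore(n_classes=1, params=params,
                      lp=np.zeros((n_chains, n_iter)),
                      energy=energy)


class TestInitialization:
    def test_reproducible_given_seed(self):
        spec = ModelSpec(n_classes=3)
        a = initialize_params(spec, seed=4)
        b = initialize_params(spec, seed=4)
        c = initialize_params(spec, seed=5)
        assert np.array_equal(a.pi, b.pi)
        assert a.classes == b.classes
        assert not np.array_equal(a.pi, c.pi)

    def test_transformed_ranges(self):
        params = initialize_params(ModelSpec(n_classes=4), seed=0)
        assert params.pi.sum() == pytest.approx(1.0)
        for cp in params.classes:
            assert np.exp(-2) <= cp.sd_int <= np.exp(2)
            assert abs(cp.corr) <= np.tanh(2)


class TestEbfmi:
    def test_iid_energies_near_two(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=20_000)
        assert ebfmi(e) == pytest.approx(2.0, abs=0.06)

    def test_constant_energy_undefined(self):
        assert np.isnan(ebfmi(np.ones(50)))
        with pytest.raises(ValueError):
            ebfmi([1.0])

    def test_low_value_flagged_as_problematic(self):
        # slowly drifting energy: tiny jumps relative to total variance
        t = np.linspace(0, 4 * np.pi, 1000)
        e = np.sin(t)
        store = make_store(np.random.default_rng(1).normal(size=(2, 500)),
                           energy=np.vstack([e[:500], e[500:]]))
        stats = convergence_stats(store)
        assert stats.e_bfmi[0] < 0.3
        assert 0 in stats.low_ebfmi_chains


class TestConvergenceStats:
    def test_all_constant_chains_reported_infinite(self):
        store = make_store(np.full((4, 100), 3.14))
        stats = convergence_stats(store)
        j = stats.parameters.index("beta0.1")
        assert np.isinf(stats.rhat[j])
        assert np.isnan(stats.ess_bulk[j])
        assert "beta0.1" in stats.flagged

    def test_independent_chains_near_one(self):
        rng = np.random.default_rng(3)
        store = make_store(rng.normal(size=(4, 1000)))
        stats = convergence_stats(store)
        j = stats.parameters.index("beta0.1")
        assert 1.0 <= stats.rhat[j] <= 1.02

    def test_mean_shifted_chain_flagged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 500))
        x[0] += 5.0
        stats = convergence_stats(make_store(x))
        j = stats.parameters.index("beta0.1")
        assert stats.rhat[j] > 1.10
        assert "beta0.1" in stats.flagged

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        for shift in (0.0, 0.3, 2.0):
            x = rng.normal(size=(4, 300))
            x[1] += shift
            stats = convergence_stats(make_store(x))
            j = stats.parameters.index("beta0.1")
            assert stats.rhat[j] == pytest.approx(reference_rank_rhat(x),
                                                  abs=1e-8)


class TestFitML:
    @pytest.fixture(scope="class")
    def separated_two_class(self):
        truth = MixtureParams(
            pi=np.array([0.4, 0.6]),
            classes=(ClassParams(4.0, 1.0, -0.05, 0.3, 0.1, 0.0),
                     ClassParams(1.0, 0.2, 0.02, 0.3, 0.1, 0.0)),
            sigma_resid=0.4)
        return truth, simulate_gmm(truth, n_subjects=250, seed=21).dataset

    def test_loglik_at_least_truth(self, separated_two_class):
        truth, data = separated_two_class
        from gmmdiag import mixture_loglik

        best, llf, _ = fit_ml(data, ModelSpec(n_classes=2), n_starts=6, seed=1)
        assert llf >= mixture_loglik(truth, data)

    def test_recovers_class_probabilities(self, separated_two_class):
        truth, data = separated_two_class
        best, _, _ = fit_ml(data, ModelSpec(n_classes=2), n_starts=6, seed=1)
        se = np.sqrt(0.4 * 0.6 / 250)
        assert np.sort(best.pi) == pytest.approx(np.sort(truth.pi),
                                                 abs=4 * se)

    def test_canonical_labeling_of_output(self, separated_two_class):
        _, data = separated_two_class
        best, _, optima = fit_ml(data, ModelSpec(n_classes=2), n_starts=6,
                                 seed=2)
        assert np.all(np.diff(best.pi) >= 0)
        lls = [ll for ll, _ in optima]
        assert lls == sorted(lls, reverse=True)
        assert np.all(np.abs(np.diff(lls)) > 1e-4)


class TestSamplePosterior:
    @pytest.fixture(scope="class")
    def one_class_run(self):
        truth = MixtureParams(
            pi=np.array([1.0]),
            classes=(ClassParams(2.0, 1.0, -0.1, sd_int=0.0, sd_slope=0.0,
                                 corr=0.0),),
            sigma_resid=0.5)
        data = simulate_gmm(truth, n_subjects=120, seed=8).dataset
        draws = sample_posterior(data, ModelSpec(n_classes=1), PriorConfig(),
                                 n_chains=2, warmup=300, iters=300, seed=3,
                                 init="moments")
        return truth, data, draws

    def test_recovers_intercept_within_three_mcse(self, one_class_run):
        truth, _, draws = one_class_run
        b0 = draws.block("beta0").ravel()
        stats = convergence_stats(draws)
        j = stats.parameters.index("beta0.1")
        ess = stats.ess_bulk[j]
        mcse = b0.std(ddof=1) / np.sqrt(ess)
        # simulation noise in the sample mean of the data also enters
        se_data = 0.5 / np.sqrt(120 * 4)
        tol = 3 * np.sqrt(mcse**2 + se_data**2) + 0.05
        assert b0.mean() == pytest.approx(truth.classes[0].beta0, abs=tol)

    def test_pi_draws_on_simplex(self, one_class_run):
        _, _, draws = one_class_run
        assert np.allclose(draws.pi_draws().sum(axis=2), 1.0, atol=1e-8)

    def test_reproducible_given_seed(self, one_class_run):
        _, data, draws = one_class_run
        again = sample_posterior(data, ModelSpec(n_classes=1), PriorConfig(),
                                 n_chains=2, warmup=300, iters=300, seed=3,
                                 init="moments")
        assert np.array_equal(draws.params, again.params)
        assert np.array_equal(draws.energy, again.energy)


class TestDrawsStore:
    def test_row_param_roundtrip(self):
        rng = np.random.default_rng(11)
        from .conftest import random_mixture

        params = random_mixture(rng)
        row = params_to_row(params)
        assert len(row) == len(param_names(3))
        back = row_to_params(row, 3)
        assert np.allclose(back.pi, params.pi)
        assert back.classes == params.classes

    def test_save_load_identity(self, tmp_path, one_class_params):
        rng = np.random.default_rng(12)
        params = np.stack([
            np.stack([params_to_row(one_class_params)] * 5),
            np.stack([params_to_row(one_class_params)] * 5)])
        params[:, :, 1] += rng.normal(size=(2, 5))
        store = DrawsStore(n_classes=1, params=params,
                           lp=rng.normal(size=(2, 5)),
                           energy=rng.normal(size=(2, 5)),
                           divergent=rng.uniform(size=(2, 5)) < 0.2,
                           n_leapfrog=np.full((2, 5), 7),
                           at_max_leapfrog=np.zeros((2, 5), dtype=bool),
                           metadata={"seed": 1, "prior": "D10N50"})
        store.save(tmp_path / "draws")
        back = DrawsStore.load(tmp_path / "draws")
        assert np.allclose(back.params, store.params)
        assert np.allclose(back.lp, store.lp)
        assert np.array_equal(back.divergent, store.divergent)
        assert back.metadata["prior"] == "D10N50"
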