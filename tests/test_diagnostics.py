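import numpy as np
import pytest

from gmmdiag import (detect_miniscule, detect_stuck, detect_twinlike,
                     di_series, diagnostics_report, distinguishability_index,
                     moving_average, moving_sd, simulate_gmm)
from gmmdiag.diagnostics import DISeries, DiagnosticsConfig, _pair_di_from_logf
from gmmdiag.draws import DrawsStore, params_to_row
from gmmdiag.params import ClassParams, MixtureParams

from .conftest import random_mixture


class TestMovingStatistics:
    def test_constant_series_all_zero(self):
        assert np.all(moving_sd(np.full(50, 2.5)) == 0.0)

    def test_twenty_constant_iterations_give_eleven_zero_windows(self):
        rng = np.random.default_rng(0)
        series = rng.uniform(size=100)
        series[40:60] = 0.123  # constant for exactly 20 iterations
        zero = moving_sd(series, h=10) == 0.0
        assert zero.sum() == 11
        # windows fully inside the run: series[40:50] ... series[50:60]
        assert np.all(zero[40:51])

    def test_alternating_series_sd(self):
        series = np.tile([0.0, 1.0], 20)
        msd = moving_sd(series, h=10)
        expected = np.sqrt(10 * 0.25 / 9)
        assert np.allclose(msd, expected)

    def test_window_too_long_raises(self):
        with pytest.raises(ValueError, match="shorter than window"):
            moving_sd(np.ones(5), h=10)
        with pytest.raises(ValueError):
            moving_sd(np.ones(50), h=1)

    def test_moving_average_alignment(self):
        x = np.arange(20.0)
        ma = moving_average(x, h=10)
        assert len(ma) == 11
        assert ma[0] == pytest.approx(np.mean(x[:10]))

    @pytest.mark.parametrize("m", range(10, 41, 5))
    def test_constant_run_window_arithmetic(self, m):
        """A maximal constant run of m >= h iterations yields exactly
        m - h + 1 zero windows."""
        rng = np.random.default_rng(m)
        series = np.concatenate([rng.uniform(1, 2, 30), np.full(m, 0.5),
                                 rng.uniform(1, 2, 30)])
        zero = moving_sd(series, h=10) == 0.0
        assert zero.sum() == m - 10 + 1


class TestDetectStuck:
    def test_continuous_draws_no_findings(self):
        rng = np.random.default_rng(1)
        rep = detect_stuck(rng.normal(size=500))
        assert rep.runs == []
        assert not rep.persistently_stuck

    def test_fully_constant_chain_is_persistent(self):
        rep = detect_stuck(np.full(200, 0.01))
        assert rep.persistently_stuck
        assert rep.runs == [(0, 200)]

    def test_nineteen_iterations_below_min_run(self):
        rng = np.random.default_rng(2)
        series = rng.uniform(1, 2, size=100)
        series[30:49] = 0.7  # 19 consecutive identical values
        rep = detect_stuck(series, h=10, min_run=20)
        assert rep.runs == []
        rep2 = detect_stuck(np.concatenate([series[:30], [0.7], series[30:]]),
                            h=10, min_run=20)  # now 20
        assert len(rep2.runs) == 1
        assert rep2.runs[0][1] == 20


def separated_pair():
    a = ClassParams(0.0, 0.0, 0.0, sd_int=0, sd_slope=0, corr=0)
    b = ClassParams(1000.0, 0.0, 0.0, sd_int=0, sd_slope=0, corr=0)
    return a, b


class TestDistinguishabilityIndex:
    def test_identical_classes_give_zero(self, tiny_balanced_data):
        cp = ClassParams(2.0, 1.0, -0.1, 0.4, 0.2, 0.1)
        params = MixtureParams(pi=np.array([0.5, 0.5]), classes=(cp, cp),
                               sigma_resid=0.5)
        assert distinguishability_index(params, tiny_balanced_data,
                                        (0, 1)) == 0.0

    def test_fully_separated_classes_give_hundred(self, tiny_balanced_data):
        a, b = separated_pair()
        params = MixtureParams(pi=np.array([0.5, 0.5]), classes=(a, b),
                               sigma_resid=1.0)
        di = distinguishability_index(params, tiny_balanced_data, (0, 1))
        assert di == pytest.approx(100.0, abs=1e-9)

    def test_entropy_value_at_fixed_conditional_probability(self):
        # p = 0.9 for every subject: DI = 100 (1 - H(0.9)/log 2) ~ 53.1
        n = 25
        logf_k = np.zeros(n)
        logf_l = np.full(n, -np.log(9.0))
        di = _pair_di_from_logf(logf_k, logf_l)
        H = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        assert di == pytest.approx(100 * (1 - H / np.log(2)), abs=1e-10)
        assert di == pytest.approx(53.1, abs=0.05)

    def test_symmetric_and_bounded(self, tiny_balanced_data):
        rng = np.random.default_rng(3)
        for _ in range(5):
            params = random_mixture(rng)
            for pair in [(0, 1), (0, 2), (1, 2)]:
                d1 = distinguishability_index(params, tiny_balanced_data, pair)
                d2 = distinguishability_index(params, tiny_balanced_data,
                                              pair[::-1])
                assert d1 == pytest.approx(d2)
                assert 0.0 <= d1 <= 100.0

    def test_invalid_pair_rejected(self, tiny_balanced_data):
        rng = np.random.default_rng(4)
        params = random_mixture(rng)
        with pytest.raises(ValueError):
            distinguishability_index(params, tiny_balanced_data, (1, 1))
        with pytest.raises(ValueError):
            distinguishability_index(params, tiny_balanced_data, (0, 5))


class TestDetectTwinlike:
    def make_di(self, values):
        return DISeries(pairs=[(0, 1)], values=np.asarray(values)[None, None])

    def test_constant_high_di_no_findings(self):
        f = detect_twinlike(self.make_di(np.full(100, 50.0)))
        assert not f.persistent and not f.isolated

    def test_single_dip_is_isolated(self):
        v = np.full(100, 60.0)
        v[40] = 2.0
        f = detect_twinlike(self.make_di(v), threshold=5, min_run=2)
        assert not f.persistent
        assert len(f.isolated) == 1
        assert f.isolated[0]["iteration"] == 40

    def test_whole_chain_low_di_is_persistent(self):
        f = detect_twinlike(self.make_di(np.full(80, 1.0)))
        assert len(f.persistent) == 1
        assert f.persistent[0]["length"] == 80


class TestDetectMiniscule:
    def test_two_regime_chain_flagged_by_clustering(self):
        rng = np.random.default_rng(5)
        half = 300
        pi_min = np.concatenate([
            rng.normal(0.001, 0.0005, half).clip(1e-5),
            rng.normal(0.3, 0.05, half)])
        rep = detect_miniscule(pi_min, di_values=None)
        assert rep.segments_clustering
        assert rep.centroids is not None
        assert np.all(np.abs(rep.centroids[0]) < 0.05)
        # flagged windows live in the first half (within a window of slack)
        starts = [s for s, _ in rep.segments_clustering]
        ends = [s + l for s, l in rep.segments_clustering]
        assert min(starts) <= 15
        assert max(ends) <= half + 10

    def test_healthy_chain_clean(self):
        rng = np.random.default_rng(6)
        pi_min = rng.normal(0.25, 0.03, 400).clip(0.05)
        di = np.abs(rng.normal(60, 10, 400))
        rep = detect_miniscule(pi_min, di_values=di)
        assert not rep.any

    def test_di_rule_route(self):
        rng = np.random.default_rng(7)
        pi_min = rng.normal(0.25, 0.03, 100).clip(0.05)
        di = np.abs(rng.normal(60, 5, 100))
        di[50:53] = 99.0  # exactly three consecutive high-DI iterations
        rep = detect_miniscule(pi_min, di_values=di)
        assert rep.segments_di == [(50, 3)]
        assert "DI-rule" in rep.routes
        di[51] = 50.0   # broken run: no finding
        rep2 = detect_miniscule(pi_min, di_values=di)
        assert rep2.segments_di == []

    def test_persistently_stuck_excluded_from_di_route(self):
        pi_min = np.full(100, 0.001)
        di = np.full(100, 99.0)
        rep = detect_miniscule(pi_min, di_values=di, persistently_stuck=True)
        assert rep.segments_di == []
        assert rep.excluded_stuck


class TestDiagnosticsReport:
    def _store_from_rows(self, rows_per_chain):
        params = np.asarray(rows_per_chain)
        n_chains, n_iter, _ = params.shape
        return DrawsStore(n_classes=3, params=params,
                          lp=np.zeros((n_chains, n_iter)))

    def test_clean_posterior_fixture(self, tiny_balanced_data):
        rng = np.random.default_rng(8)
        base = random_mixture(rng)
        rows = []
        for c in range(2):
            chain = []
            for _ in range(60):
                row = params_to_row(base)
                noise = rng.normal(0, 0.01, size=row.shape)
                noise[:3] = 0.0
                row = row + noise
                row[:3] = rng.dirichlet(np.array([20, 30, 50.0]))
                chain.append(row)
            rows.append(chain)
        store = self._store_from_rows(rows)
        report = diagnostics_report(store, tiny_balanced_data,
                                    DiagnosticsConfig(window=10, min_run=20))
        assert report.persistently_stuck_chains == []
        assert report.chains_with_stuck_sequences == []
        assert not report.twinlike.any_persistent

    def test_persistently_stuck_fixture(self, tiny_balanced_data):
        rng = np.random.default_rng(9)
        base = random_mixture(rng)
        row = params_to_row(base)
        rows = [[row.copy() for _ in range(60)] for _ in range(2)]
        store = self._store_from_rows(rows)
        report = diagnostics_report(store, tiny_balanced_data)
        assert report.rhat_undefined
        assert report.persistently_stuck_chains == [0, 1]
        d = report.to_dict()
        assert d["step2"]["persistently_stuck_chains"] == [0, 1]


def test_di_series_matches_scalar_op(tiny_balanced_data):
    rng = np.random.default_rng(10)
    rows = [params_to_row(random_mixture(rng)) for _ in range(4)]
    store = DrawsStore(n_classes=3, params=np.asarray(rows)[None],
                       lp=np.zeros((1, 4)))
    di = di_series(store, tiny_balanced_data)
    for i in range(4):
        params = store.draw(0, i)
        for p, pair in enumerate(di.pairs):
            assert di.values[0, p, i] == pytest.approx(
                distinguishability_index(params, tiny_balanced_data, pair),
                abs=1e-9)
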