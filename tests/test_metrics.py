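import numpy as np
import pytest

from normnet import metrics
from normnet.simulator import SimulationResult
from normnet.v1 import SpikeRaster


def make_result(n_units=4, duration=2000.0, currents=None, spikes=None,
                burn_in=0.0):
    if spikes is None:
        spikes = (np.zeros(0), np.zeros(0, dtype=np.int32))
    t, ids = spikes
    order = np.argsort(t)
    raster = SpikeRaster(times=np.asarray(t, float)[order],
                         ids=np.asarray(ids, np.int32)[order],
                         n_neurons=n_units, duration=duration)
    if currents is None:
        n_samp = int(duration / 10.0)
        currents = {k: np.zeros((n_units, n_samp), dtype=np.float32)
                    for k in ("ff", "re", "ri")}
    return SimulationResult(spikes=raster, n_e=n_units, n_i=0,
                            duration=duration, dt=0.05, current_dt=10.0,
                            currents=currents, burn_in=burn_in)


class TestIndices:
    @pytest.mark.parametrize("fr1,fr2,frb,expected", [
        (10, 10, 20, 1.0),
        (15, 15, 20, 1.5),
        (5, 5, 20, 0.5),
    ])
    def test_normalization_index(self, fr1, fr2, frb, expected):
        assert metrics.normalization_index(fr1, fr2, frb) == expected

    def test_zero_denominator_excluded(self):
        assert np.isnan(metrics.normalization_index(1.0, 1.0, 0.0))

    @pytest.mark.parametrize("i1,i2,ib,expected", [
        (3, 3, 3, 2.0),
        (3, 5, 8, 1.0),
        (-3, -3, -4, 1.5),  # inhibitory currents: signs cancel
    ])
    def test_current_normalization_index(self, i1, i2, ib, expected):
        assert metrics.current_normalization_index(i1, i2, ib) == expected

    @pytest.mark.parametrize("fr1,fr2,expected", [
        (5, 5, 0.0), (7, 0, 1.0), (30, 10, 0.5), (0, 4, -1.0),
    ])
    def test_selectivity(self, fr1, fr2, expected):
        assert metrics.selectivity(fr1, fr2) == pytest.approx(expected)

    def test_selectivity_undefined_for_silent_unit(self):
        assert np.isnan(metrics.selectivity(0.0, 0.0))


class TestTuningSimilarity:
    def test_identical_and_negated(self):
        th = np.arange(18) * np.pi / 18
        c = np.exp(np.cos(2 * (th - 0.3)))
        r = metrics.tuning_similarity(np.vstack([c, c, -c]))
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_orthogonal_preferences_anticorrelated(self):
        th = np.arange(18) * np.pi / 18
        a = np.exp(np.cos(2 * th))
        b = np.exp(np.cos(2 * (th - np.pi / 2)))
        r = metrics.tuning_similarity(np.vstack([a, b]))
        assert r[0, 1] < 0

    def test_flat_curve_excluded(self):
        r = metrics.tuning_similarity(np.vstack([np.ones(18),
                                                 np.arange(18.0)]))
        assert np.isnan(r[0, 1])


class TestCounts:
    def test_sliding_counts_hand_check(self):
        # unit 0 spikes at 10, 60, 260 ms; window 200 step 50, no burn-in
        res = make_result(n_units=2, duration=400.0,
                          spikes=([10.0, 60.0, 260.0], [0, 0, 0]))
        res.burn_in = 0.0
        c = metrics.sliding_counts(res, units=np.array([0, 1]))
        # windows: [0,200) -> 2, [50,250) -> 1, [100,300) -> 1, ...
        assert c.shape[1] == 2
        assert c[0, 0] == 2 and c[1, 0] == 1 and c[2, 0] == 1
        assert np.all(c[:, 1] == 0)

    def test_burn_in_excluded(self):
        res = make_result(n_units=1, duration=2000.0,
                          spikes=([500.0, 1500.0], [0, 0]), burn_in=1000.0)
        c = metrics.sliding_counts(res, units=np.array([0]))
        assert c.sum() > 0
        # only the post-burn-in spike is counted: every window <= 1
        assert c.max() == 1

    def test_inclusion_mask(self):
        rates = np.array([[10, 10, 10, 100.0],
                          [10, 10, 10, 100.0],
                          [10, 10, 10, 100.0]])
        m = metrics.inclusion_mask(rates)
        assert list(m) == [True, True, True, False]


class TestSpikeCountCorrelations:
    def _poisson_result(self, rates, duration, seed, gain_sd=0.0):
        rng = np.random.default_rng(seed)
        n = len(rates)
        t_all, id_all = [], []
        n_ms = int(duration)
        gain = np.exp(gain_sd * rng.standard_normal(n_ms // 200)) \
            if gain_sd else np.ones(n_ms // 200)
        for i, r in enumerate(rates):
            for w in range(n_ms // 200):
                lam = r * gain[w] * 0.2
                k = rng.poisson(lam)
                t_all.extend(w * 200 + 200 * rng.random(k))
                id_all.extend([i] * k)
        return make_result(n_units=n, duration=duration,
                           spikes=(np.array(t_all), np.array(id_all)))

    def test_self_correlation_is_one(self):
        res = self._poisson_result([10.0, 10.0], 20000.0, 3)
        res.burn_in = 0.0
        r = metrics.spike_count_correlations([res], units=np.array([0, 1]))
        assert r[0, 0] == pytest.approx(1.0)

    def test_independent_units_uncorrelated(self):
        res = self._poisson_result([10.0, 10.0], 20000.0, 4)
        res.burn_in = 0.0
        r = metrics.spike_count_correlations([res], units=np.array([0, 1]))
        assert abs(r[0, 1]) < 0.1

    def test_shared_gain_positive_correlation(self):
        res = self._poisson_result([20.0, 20.0], 20000.0, 5, gain_sd=0.5)
        res.burn_in = 0.0
        r = metrics.spike_count_correlations([res], units=np.array([0, 1]))
        assert r[0, 1] > 0.2


class TestBinByNormalization:
    def test_heatmap_symmetric(self, rng):
        n = 60
        ni = rng.uniform(1.0, 3.0, n)
        corr = np.corrcoef(rng.standard_normal((n, 50)))
        out = metrics.bin_by_normalization(ni, corr)
        h = out["heatmap"]
        assert np.allclose(h, h.T, equal_nan=True)

    def test_structured_vs_shuffled_slope(self, rng):
        # correlations decaying with |dNI| -> negative slope; destroyed by
        # shuffling the NI labels
        n = 120
        ni = rng.uniform(1.0, 2.0, n)
        corr = 0.3 - 0.2 * np.abs(ni[:, None] - ni[None, :]) \
            + 0.01 * rng.standard_normal((n, n))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)

        def slope(nivec):
            out = metrics.bin_by_normalization(nivec, corr)
            x, y, c = out["dni"]
            ok = c > 0
            return np.polyfit(x[ok], y[ok], 1)[0]

        s_true = slope(ni)
        s_shuf = np.array([slope(rng.permutation(ni)) for _ in range(20)])
        assert s_true < np.percentile(s_shuf, 2.5)


class TestCovarianceDecomposition:
    def _result_with_currents(self, E_parts, I, duration=1000.0):
        ff, re = E_parts
        n, m = ff.shape
        cur = {"ff": ff.astype(np.float32), "re": re.astype(np.float32),
               "ri": I.astype(np.float32)}
        return make_result(n_units=n, duration=duration, currents=cur)

    def test_identity(self, rng):
        n, m = 5, 400
        ff = rng.random((n, m))
        re = rng.random((n, m))
        ri = -rng.random((n, m))
        res = self._result_with_currents((ff, re), ri)
        pairs = np.array([[0, 1], [2, 3], [1, 4]])
        df = metrics.covariance_decomposition([res], pairs)
        total = df[["cov_ee", "cov_ei", "cov_ie", "cov_ii"]].sum(axis=1)
        assert np.allclose(total, df["cov_total"],
                           rtol=1e-9, atol=1e-12)

    def test_independent_traces_near_zero(self, rng):
        n, m = 2, 20000
        res = self._result_with_currents(
            (rng.standard_normal((n, m)), np.zeros((n, m))),
            rng.standard_normal((n, m)), duration=10 * m)
        df = metrics.covariance_decomposition([res], np.array([[0, 1]]))
        bound = 4 / np.sqrt(m)
        for c in ("cov_ee", "cov_ei", "cov_ie", "cov_ii"):
            assert abs(df[c][0]) < bound

    def test_constructed_anticorrelation(self, rng):
        m = 500
        e1 = rng.standard_normal(m)
        ff = np.vstack([e1, np.zeros(m)])
        re = np.zeros((2, m))
        ri = np.vstack([np.zeros(m), -e1])  # I2 = -E1
        res = self._result_with_currents((ff, re), ri)
        df = metrics.covariance_decomposition([res], np.array([[0, 1]]))
        stored = e1.astype(np.float32).astype(float)  # trace storage dtype
        assert df["cov_ei"][0] == pytest.approx(-stored.var(ddof=1), rel=1e-9)


class TestContrastSensitivity:
    def test_zero_delta_is_degenerate(self, rng):
        r0 = rng.uniform(5, 20, 50)
        ni = rng.uniform(1, 3, 50)
        out = metrics.contrast_sensitivity({0.0: r0}, ni)
        assert np.allclose(out["mean_rel"], 1.0)
        assert np.allclose(out["sd_rel"], 0.0)

    def test_rates_zero_excluded(self):
        out = metrics.contrast_sensitivity(
            {0.0: np.array([0.0, 10.0, 12.0]),
             0.2: np.array([5.0, 12.0, 20.0])},
            np.array([1.2, 1.2, 1.2]))
        assert (out["n"] == 2).all()


class TestTrialConventions:
    def test_planted_outlier_removed(self, rng):
        counts = rng.poisson(10, size=(60, 3)).astype(float)
        counts[17, 1] = 10 + 10 * counts[:, 1].std() * 3
        tm = metrics.TrialCountMatrix(counts=counts,
                                      conditions=np.zeros(60, int))
        dev = metrics.deviant_trials(tm)
        assert dev[17, 1]
        assert dev.sum() <= 3  # essentially only the planted outlier

    def test_zero_sd_edge_case(self):
        counts = np.full((10, 1), 4.0)
        counts[3, 0] = 5.0
        tm = metrics.TrialCountMatrix(counts=counts,
                                      conditions=np.zeros(10, int))
        dev = metrics.deviant_trials(tm)
        assert dev[3, 0] and dev.sum() == 1
        tm2 = metrics.TrialCountMatrix(counts=np.full((10, 1), 4.0),
                                       conditions=np.zeros(10, int))
        assert not metrics.deviant_trials(tm2).any()

    def test_responsiveness_t_test(self, rng):
        n_tr = 100
        blank = rng.poisson(5, size=(n_tr, 2))
        driven = np.column_stack([
            rng.poisson(15, size=n_tr),  # responsive
            rng.poisson(5, size=n_tr),  # unresponsive
        ])
        tm = metrics.TrialCountMatrix(
            counts=np.vstack([blank, driven]),
            conditions=np.repeat([0, 1], n_tr))
        resp = metrics.responsive_units(tm, blank_label=0, driven_labels=[1])
        assert resp[0] and not resp[1]

    def test_same_electrode_pairs_dropped(self):
        tm = metrics.TrialCountMatrix(
            counts=np.zeros((4, 3)), conditions=np.zeros(4, int),
            electrode_ids=np.array([1, 1, 2]))
        ok = metrics.valid_pairs(tm, np.array([[0, 1], [0, 2]]))
        assert list(ok) == [False, True]
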