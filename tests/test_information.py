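import numpy as np
import pytest

from normnet import information as info
from normnet.stimuli import NoiseField, evolve_noise, gabor_image
from normnet.v1 import RF_CENTERS, build_v1_population, calibrate_gain


@pytest.fixture(scope="module")
def small_pop():
    p = build_v1_population(grid=(20, 10), seed=2)
    calibrate_gain(p)
    return p


class TestBiasCorrectedFisher:
    def test_equal_means_trivial_case(self, rng):
        x = rng.poisson(5.0, size=(100, 1)).astype(float)
        est = info.bias_corrected_fisher(x, x.copy(), dx=0.01)
        assert est.value == pytest.approx(-2 * 1 / (100 * 0.01**2))
        assert est.value == pytest.approx(-200.0)

    def test_gaussian_oracle_and_bias_direction(self, rng):
        n, n_tr, reps = 10, 600, 150
        a = rng.standard_normal((n, n))
        cov = a @ a.T / n + np.eye(n)
        fp = rng.standard_normal(n)
        truth = fp @ np.linalg.solve(cov, fp)
        dx = 0.1
        L = np.linalg.cholesky(cov)
        vals, naives = [], []
        for _ in range(reps):
            z1 = rng.standard_normal((n_tr, n)) @ L.T
            z2 = rng.standard_normal((n_tr, n)) @ L.T + fp * dx
            est = info.bias_corrected_fisher(z1, z2, dx)
            vals.append(est.value)
            naives.append(est.naive)
        vals = np.array(vals)
        naives = np.array(naives)
        se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() - truth) <= 2 * se
        # uncorrected estimator is biased upward relative to the truth
        frac_above = (naives > truth).mean()
        assert frac_above > 0.75

    def test_permutation_invariance(self, rng):
        x1 = rng.poisson(8, size=(200, 6)).astype(float)
        x2 = rng.poisson(9, size=(200, 6)).astype(float)
        perm = rng.permutation(6)
        a = info.bias_corrected_fisher(x1, x2, 0.05).value
        b = info.bias_corrected_fisher(x1[:, perm], x2[:, perm], 0.05).value
        assert a == pytest.approx(b, rel=1e-9)

    def test_dx_scaling_identity(self, rng):
        x1 = rng.poisson(8, size=(150, 4)).astype(float)
        x2 = rng.poisson(10, size=(150, 4)).astype(float)
        a = info.bias_corrected_fisher(x1, x2, 0.01).value
        b = info.bias_corrected_fisher(x1, x2, 0.1).value
        assert a == pytest.approx(100 * b, rel=1e-9)

    def test_estimability_guard(self, rng):
        x = rng.poisson(5, size=(5, 10)).astype(float)
        with pytest.raises(ValueError):
            info.bias_corrected_fisher(x, x, 0.01)

    def test_nonnegative_with_ample_trials_and_signal(self, rng):
        n, n_tr = 4, 50 * 4
        for _ in range(10):
            x1 = rng.poisson(10, size=(n_tr, n)).astype(float)
            x2 = rng.poisson(14, size=(n_tr, n)).astype(float)
            assert info.bias_corrected_fisher(x1, x2, 0.1).value > 0


class TestExtrapolation:
    def test_noiseless_recovery(self):
        a, i_inf = 2.0, 500.0
        n = np.array([8, 30, 100, 1000, 12000], float)
        i_n = 1.0 / (1.0 / (a * n) + 1.0 / i_inf)
        fit = info.extrapolate_info(n, i_n)
        assert fit.i_inf == pytest.approx(i_inf, abs=1e-9)
        assert fit.slope == pytest.approx(1.0 / a, abs=1e-12)

    def test_linear_information_does_not_saturate(self):
        n = np.array([10, 100, 1000.0, 5000.0])
        fit = info.extrapolate_info(n, 3.0 * n)
        assert fit.i_inf > 1e9  # intercept ~ 0: no saturation

    def test_noisy_recovery_within_ten_percent(self, rng):
        a, i_inf = 2.0, 500.0
        n = np.geomspace(8, 12000, 12)
        i_n = 1.0 / (1.0 / (a * n) + 1.0 / i_inf)
        est = []
        for _ in range(100):
            noisy = i_n * (1 + 0.05 * rng.standard_normal(n.size))
            est.append(info.extrapolate_info(n, noisy).i_inf)
        assert np.median(est) == pytest.approx(i_inf, rel=0.10)


class TestSamplingSchedule:
    def test_schedule_endpoints(self):
        s = info.sampling_schedule(np.array([1, 545, 8103]))
        assert s[0] == 200
        assert s[1] == 5 and s[2] == 5
        mid = info.sampling_schedule(np.array([100, 300, 544]))
        assert np.all(np.diff(mid) < 0)
        assert mid[-1] == 14


class TestInfoPerSpike:
    def _synthetic(self, rng, n_units=30, n_tr=400):
        ni = np.concatenate([np.full(n_units // 2, 1.2),
                             np.full(n_units - n_units // 2, 2.8)])
        base = 3.0
        labels = np.repeat([0, 1], n_tr // 2)
        counts = rng.poisson(base, size=(n_tr, n_units)).astype(float)
        # only high-NI units carry signal
        counts[labels == 1, n_units // 2:] += 2.0
        return counts, labels, ni

    def test_high_ni_stratum_carries_more_info_per_spike(self, rng):
        counts, labels, ni = self._synthetic(rng)
        kw = dict(dx=0.1, n_values=np.array([8]),
                  n_samples=np.array([20]), min_rate_hz=0.0)
        low = info.info_per_spike(counts, labels, ni, (1.0, 1.4), seed=1, **kw)
        high = info.info_per_spike(counts, labels, ni, (2.6, 3.0), seed=1, **kw)
        assert high["info_per_spike"].mean() > low["info_per_spike"].mean()

    def test_determinism(self, rng):
        counts, labels, ni = self._synthetic(rng)
        kw = dict(dx=0.1, n_values=np.array([4]),
                  n_samples=np.array([3]), min_rate_hz=0.0)
        a = info.info_per_spike(counts, labels, ni, (1.0, 1.4), seed=9, **kw)
        b = info.info_per_spike(counts, labels, ni, (1.0, 1.4), seed=9, **kw)
        assert np.array_equal(a["info"].to_numpy(), b["info"].to_numpy())

    def test_empty_stratum_warns(self, rng):
        counts, labels, ni = self._synthetic(rng)
        with pytest.warns(RuntimeWarning):
            out = info.info_per_spike(counts, labels, ni, (5.0, 6.0),
                                      dx=0.1, n_values=np.array([2]), seed=0)
        assert out.empty


class TestIntegratedNoiseVariance:
    def test_formula_against_brute_force_ou(self):
        """Var(xi_T) = sigma_n^2 [T - tau_n (1 - exp(-T/tau_n))] matches a
        direct OU integration."""
        tau, sig, T, dt = 40.0, 3.5, 200.0, 0.5
        state = NoiseField(xi=np.zeros(3000), tau_n=tau, sigma_n=sig, dt=dt)
        out, traj = evolve_noise(state, int(1600 / dt), seed=13, record=True)
        traj = traj[traj.shape[0] // 2:]  # stationary part
        n_win = traj.shape[0] // int(T / dt)
        xi_T = np.array([
            traj[k * int(T / dt):(k + 1) * int(T / dt)].sum(axis=0) * dt
            for k in range(n_win)])
        analytic = sig**2 * (T - tau * (1 - np.exp(-T / tau)))
        assert xi_T.var() == pytest.approx(analytic, rel=0.10)


class TestV1InputInformation:
    def test_diagonal_limit_matches_poisson_formula(self, small_pop):
        """With vanishing pixel noise the information reduces to the
        independent-Poisson form sum_i T f_i'^2 / f_i."""
        pop = small_pop
        T = 200.0
        c = 0.5
        # numerical derivative of rectified rates wrt contrast
        dc = 1e-4
        F = pop.filters[1]

        def counts(cc):
            img = gabor_image(cc, RF_CENTERS[1], np.pi / 2, pop.sigma,
                              pop.lambda_wave, pop.npix)
            mu = pop.image_response(1, img.pixels)
            return pop.gain / 1000.0 * np.maximum(mu, 0) * T

        f = counts(c)
        fp = (counts(c + dc) - counts(c - dc)) / (2 * dc)
        active = f > 1e-12
        expected = np.sum(fp[active] ** 2 / f[active])
        got = info.v1_input_information(pop, "contrast", T, c=c,
                                        noise_scale=1e-9)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_noise_reduces_information(self, small_pop):
        T = 200.0
        lo = info.v1_input_information(small_pop, "contrast", T,
                                       noise_scale=small_pop.noise_scale)
        hi = info.v1_input_information(small_pop, "contrast", T,
                                       noise_scale=1e-9)
        assert 0 < lo < hi

    def test_orientation_information_positive(self, small_pop):
        got = info.v1_input_information(small_pop, "orientation", 200.0)
        assert got > 0


class TestFisherTrials:
    def test_protocol_bookkeeping(self, tiny_model):
        counts, labels = info.fisher_trials(
            tiny_model.graph("default"), tiny_model.v1,
            kind="contrast", duration=5000.0, n_sims=1, seed=3)
        # 5 s of 500-ms cycles -> 10 ON intervals, first dropped
        assert counts.shape == (9, tiny_model.net_config.n_e)
        assert abs(labels.sum() - len(labels) / 2) <= 1

    def test_off_intervals_are_spontaneous(self, tiny_model):
        from normnet.information import _on_off_schedule
        from normnet.v1 import generate_v1_spikes
        labels = np.array([0, 1, 0, 1])
        segs = _on_off_schedule("contrast", 0.01, 2000.0, labels, 200.0,
                                300.0, 0.5, 0.0, 0.5, np.pi / 2, 5.0)
        ff = generate_v1_spikes(tiny_model.v1, segs, 2000.0, seed=8)
        pop2 = tiny_model.v1.idx[1]
        off_time = 4 * 300.0 / 1000.0
        in_off = (ff.times % 500.0) >= 200.0
        sel = in_off & np.isin(ff.ids, pop2)
        rate = sel.sum() / pop2.size / off_time
        assert rate == pytest.approx(5.0, abs=3 * np.sqrt(5 / (pop2.size * off_time)))
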