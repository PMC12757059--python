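import numpy as np
import pytest
from scipy.optimize import linprog

from normnet.capacity import (
    anchor_geometry,
    capacity_experiment_table,
    ensemble_geometry,
    manifold_capacity,
)


# ---------------------------------------------------------------------------
# brute-force linear-separability oracle

def separable(manifolds, labels):
    """LP feasibility: exists w with y_i (w . x) >= 1 for every point."""
    rows = []
    for pts, y in zip(manifolds, labels):
        rows.append(-y * np.asarray(pts, float))
    A = np.vstack(rows)
    b = -np.ones(A.shape[0])
    res = linprog(c=np.zeros(A.shape[1]), A_ub=A, b_ub=b,
                  bounds=[(None, None)] * A.shape[1], method="highs")
    return res.status == 0


def oracle_critical_load(make_manifolds, n_units, p_values, rng,
                         n_dichotomies=20):
    """Fraction-separable curve over P; returns the 50% crossing of P/N."""
    fracs = []
    for p in p_values:
        wins = 0
        for _ in range(n_dichotomies):
            mani = make_manifolds(p)
            labels = rng.choice([-1.0, 1.0], size=p)
            wins += separable(mani, labels)
        fracs.append(wins / n_dichotomies)
    fracs = np.array(fracs)
    return np.interp(0.5, fracs[::-1], np.array(p_values, float)[::-1]) / n_units


class TestPointManifolds:
    def test_point_manifold_radius_zero(self, rng):
        pt = rng.standard_normal(20)
        d, r, f = anchor_geometry(np.tile(pt, (5, 1)), n_t=100, seed=0)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_cover_limit_against_lp_oracle(self, rng):
        n = 25
        # mean-field capacity of point manifolds
        pts = [rng.standard_normal((1, n)) for _ in range(30)]
        alpha_mf = manifold_capacity(pts, n_t=1000, seed=2)
        assert alpha_mf == pytest.approx(2.0, rel=0.10)
        # LP oracle: 50% separable load for random points, homogeneous sep.
        alpha_lp = oracle_critical_load(
            lambda p: rng.standard_normal((p, 1, n)), n,
            p_values=[30, 40, 50, 60, 70], rng=rng)
        assert alpha_mf == pytest.approx(alpha_lp, rel=0.10)


class TestBallCalibration:
    def test_radius_recovered_for_ball_manifold(self, rng):
        n, d, m, r = 40, 5, 200, 0.4
        c = rng.standard_normal(n)
        c /= np.linalg.norm(c)
        basis, _ = np.linalg.qr(rng.standard_normal((n, d + 1)))
        basis = basis[:, :d]
        basis -= np.outer(c, c @ basis)
        basis, _ = np.linalg.qr(basis)
        u = rng.standard_normal((m, d))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = c[None, :] + r * (u @ basis.T)
        dm, rad, f = anchor_geometry(pts, n_t=2000, seed=3)
        assert np.sqrt(rad) == pytest.approx(r, rel=0.10)
        assert 0 < dm <= d + 1

    def test_same_seed_identical(self, rng):
        pts = rng.standard_normal((12, 30))
        a = anchor_geometry(pts, n_t=50, seed=7)
        b = anchor_geometry(pts, n_t=50, seed=7)
        assert a == b


class TestEnsembles:
    def _blobs(self, rng, p, n, m=8, spread=0.2):
        centers = rng.standard_normal((p, n))
        return [c + spread * rng.standard_normal((m, n)) for c in centers]

    def test_dilation_reduces_capacity_both_routes(self, rng):
        n, p = 30, 40
        mani = self._blobs(rng, p, n, spread=0.25)
        dilated = []
        for pts in mani:
            c = pts.mean(axis=0)
            dilated.append(c + 2.0 * (pts - c))
        a1 = manifold_capacity(mani, n_t=300, seed=4)
        a2 = manifold_capacity(dilated, n_t=300, seed=4)
        assert a2 < a1
        # oracle agrees in direction at fixed P: dilated less often separable
        wins1 = wins2 = 0
        for k in range(15):
            labels = rng.choice([-1.0, 1.0], size=p)
            wins1 += separable(mani, labels)
            wins2 += separable(dilated, labels)
        assert wins2 <= wins1

    def test_mean_field_tracks_oracle_for_blobs(self, rng):
        n, m, spread = 30, 6, 0.3
        alphas_mf, alphas_lp = [], []
        for seed in range(3):
            r = np.random.default_rng(100 + seed)
            mani = self._blobs(r, 50, n, m=m, spread=spread)
            alphas_mf.append(manifold_capacity(mani, n_t=400, seed=seed))
            alphas_lp.append(oracle_critical_load(
                lambda p: self._blobs(r, p, n, m=m, spread=spread), n,
                p_values=[20, 30, 40, 50, 60], rng=r, n_dichotomies=12))
        mf = np.mean(alphas_mf)
        lp = np.mean(alphas_lp)
        assert mf == pytest.approx(lp, rel=0.20)

    def test_rotation_invariance(self, rng):
        n, p = 20, 10
        mani = self._blobs(rng, p, n)
        q, _ = np.linalg.qr(rng.standard_normal((n, n)))
        rotated = [m @ q.T for m in mani]
        g1 = ensemble_geometry(mani, n_t=100, seed=5)
        g2 = ensemble_geometry(rotated, n_t=100, seed=5)
        assert g1.capacity == pytest.approx(g2.capacity, rel=1e-6)
        assert g1.radius == pytest.approx(g2.radius, rel=1e-6)
        assert g1.dimension == pytest.approx(g2.dimension, rel=1e-6)

    def test_radius_scale_covariance(self, rng):
        mani = self._blobs(rng, 8, 15)
        g1 = ensemble_geometry(mani, n_t=100, seed=6)
        g2 = ensemble_geometry([3.0 * m for m in mani], n_t=100, seed=6)
        assert g1.radius == pytest.approx(g2.radius, rel=1e-9)

    def test_needs_two_manifolds(self, rng):
        with pytest.raises(ValueError):
            ensemble_geometry([rng.standard_normal((4, 10))])


class TestExperimentTable:
    def test_schedule_and_shapes(self, rng):
        resp = rng.poisson(4, size=(6, 12, 60)).astype(float)
        df = capacity_experiment_table(resp, sample_sizes=(30, 50),
                                       n_subsamples=3, n_t=40, seed=1)
        assert set(df["n_units"]) == {30, 50}
        assert (df.groupby("n_units").size() == 3).all()
        assert (df["capacity"] > 0).all()

    def test_insufficient_units_raises(self, rng):
        resp = rng.poisson(4, size=(3, 10, 20)).astype(float)
        with pytest.raises(ValueError):
            capacity_experiment_table(resp, sample_sizes=(50,),
                                      n_subsamples=2)
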