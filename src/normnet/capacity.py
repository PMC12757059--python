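"""Manifold capacity, dimension and radius of population responses.

Each object manifold is the set of population response vectors (spike counts
in 100-ms windows) evoked by one image across trials.  Following the replica
mean-field theory of linear classification of general manifolds, each
manifold is embedded in the affine span of its own points: the center is the
trial mean (after global mean subtraction), the coordinates are an
orthonormal basis of the centered trials scaled by the center norm, and the
center direction is appended as a constant (D+1)-th coordinate.  For a
Gaussian vector (t, t0) the anchor point s~ is the unique solution of

    min ||v - t||^2   s.t.   v . s_j + kappa <= 0  for every manifold point,

a projection solved here in its dual form as a nonnegative least-squares
problem.  The mean-field quantities are

    capacity   alpha^{-1} = < || v - t ||^2 >            (per manifold,
                combined over manifolds by the inverse mean),
    dimension  D_M = < (t . s_hat)^2 >,
    radius     R_M = sqrt(< ||s~||^2 >)   (relative to the center norm),

averaged over ``n_t`` Gaussian samples.  Capacity alpha = P/N is the maximal
number of linearly separable manifolds per neuron; for point manifolds it
approaches the Cover limit alpha = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.optimize import nnls

from ._rng import child_rng, child_seed

__all__ = [
    "ManifoldGeometry",
    "anchor_geometry",
    "manifold_capacity",
    "ensemble_geometry",
    "capacity_experiment_table",
]


@dataclass
class ManifoldGeometry:
    capacity: float  # alpha, manifolds per unit
    dimension: float  # D_M
    radius: float  # R_M
    n_manifolds: int
    n_t: int
    kappa: float


def _embed_manifolds(manifolds, center_global: bool = True):
    """Center and project each manifold into its own affine span.

    Returns a list of (D+1, m) arrays whose last row is constant 1; the first
    D rows are coordinates relative to the norm of the manifold center.  The
    ensemble (global) mean is subtracted first when ``center_global``.
    """
    X = [np.asarray(m, float) for m in manifolds]
    gmean = np.vstack(X).mean(axis=0) if center_global else 0.0
    out = []
    for pts in X:
        pts = pts - gmean
        center = pts.mean(axis=0)
        centered = pts - center
        cnorm = np.linalg.norm(center)
        if cnorm == 0:
            cnorm = 1.0
        if np.allclose(centered, 0):
            coords = np.zeros((1, pts.shape[0]))
        else:
            u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
            rank = int(np.sum(s > s[0] * 1e-10))
            rank = min(rank, pts.shape[0] - 1) if pts.shape[0] > 1 else rank
            rank = max(rank, 1)
            coords = (u[:, :rank].T @ centered.T) / cnorm
            # deterministic sign convention: the coordinates (not the basis)
            # are what the Gaussian samples see, so make them invariant to
            # global rotations of the response space
            for row in coords:
                j = int(np.argmax(np.abs(row)))
                if row[j] < 0:
                    row *= -1.0
        out.append(np.vstack([coords, np.ones((1, pts.shape[0]))]))
    return out


def _anchor_solve(S, t, kappa):
    """Anchor point and squared distance for one Gaussian sample.

    S is (d, m) manifold points (rows: coordinates incl. the center
    coordinate), t the (d,) Gaussian.  Returns (s_tilde, f) with
    f = ||v - t||^2.
    """
    proj = t @ S
    gmax = proj.max()
    if gmax + kappa < 0:
        # interior sample: v = t; anchor is the touching (max-projection) point
        return S[:, int(np.argmax(proj))], 0.0
    # dual NNQP: min 1/2 lam' G lam - lam' b, lam >= 0, G = S'S, b = proj + kappa
    G = S.T @ S
    m = G.shape[0]
    b = proj + kappa
    jitter = 1e-10 * max(np.trace(G) / m, 1.0)
    for _ in range(6):
        try:
            R = cholesky(G + jitter * np.eye(m), lower=False)
            break
        except np.linalg.LinAlgError:
            jitter *= 100
    y = np.linalg.solve(R.T, b)
    lam, _ = nnls(R, y)
    delta = S @ lam  # = t - v
    lam_sum = lam.sum()
    if lam_sum <= 0:
        return S[:, int(np.argmax(proj))], float(delta @ delta)
    s_tilde = delta / lam_sum
    return s_tilde, float(delta @ delta)


def anchor_geometry(manifold_points: np.ndarray, n_t: int = 200,
                    kappa: float = 0.0, seed: int = 0,
                    t_samples: np.ndarray | None = None) -> tuple:
    """Mean-field geometry of a single manifold: (D_M, R_M, mean F).

    ``manifold_points`` is (m, N) of response vectors (assumed already
    globally centered if part of an ensemble; single-manifold use centers
    only locally).  ``t_samples`` optionally supplies the Gaussian samples
    (n_t, >= D+1) for variance reduction across manifolds.
    """
    if np.asarray(manifold_points).shape[0] < 1:
        raise ValueError("need at least one point")
    S = _embed_manifolds([manifold_points], center_global=False)[0]
    return _geometry_of_embedded(S, n_t, kappa, seed, t_samples)


def _geometry_of_embedded(S, n_t, kappa, seed, t_samples=None):
    d = S.shape[0]
    if t_samples is None:
        rng = child_rng(seed, "capacity-t")
        t_samples = rng.standard_normal((n_t, d))
    dim_acc = 0.0
    rad_acc = 0.0
    f_acc = 0.0
    for k in range(n_t):
        t = t_samples[k, :d]
        s_tilde, f = _anchor_solve(S, t, kappa)
        norm = np.linalg.norm(s_tilde)
        if norm > 0:
            dim_acc += (t @ (s_tilde / norm)) ** 2
        rad_acc += float(s_tilde[:-1] @ s_tilde[:-1])  # exclude center coord
        f_acc += f
    return dim_acc / n_t, rad_acc / n_t, f_acc / n_t


def ensemble_geometry(manifolds, n_t: int = 200, kappa: float = 0.0,
                      seed: int = 0) -> ManifoldGeometry:
    """Capacity, dimension and radius of an ensemble of manifolds.

    ``manifolds`` is a sequence of (m_i, N) arrays (trials x units per
    image).  The same Gaussian samples are reused across manifolds."""
    if len(manifolds) < 2:
        raise ValueError("need at least two manifolds")
    embedded = _embed_manifolds(manifolds)
    dmax = max(S.shape[0] for S in embedded)
    rng = child_rng(seed, "capacity-t")
    t_samples = rng.standard_normal((n_t, dmax))
    dims, rads, fs = [], [], []
    for S in embedded:
        dm, r2, f = _geometry_of_embedded(S, n_t, kappa, seed, t_samples)
        dims.append(dm)
        rads.append(r2)
        fs.append(f)
    mean_f = float(np.mean(fs))
    alpha = np.inf if mean_f == 0 else 1.0 / mean_f
    return ManifoldGeometry(
        capacity=alpha,
        dimension=float(np.mean(dims)),
        radius=float(np.sqrt(np.mean(rads))),
        n_manifolds=len(manifolds),
        n_t=n_t,
        kappa=kappa,
    )


def manifold_capacity(manifolds, kappa: float = 0.0, n_t: int = 200,
                      seed: int = 0) -> float:
    """Mean-field capacity alpha of an ensemble of manifolds."""
    return ensemble_geometry(manifolds, n_t=n_t, kappa=kappa, seed=seed).capacity


def capacity_experiment_table(
    responses: np.ndarray,
    sample_sizes=(200, 400, 800, 1600, 3200),
    n_subsamples: int = 20,
    trial_fraction: float = 0.2,
    n_t: int = 200,
    kappa: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Capacity/dimension/radius vs number of sampled units.

    ``responses`` is (P images, M_max trials, N_units) of spike counts.  For
    each N in ``sample_sizes``, ``n_subsamples`` random unit subsets are
    drawn and M = round(trial_fraction * N) trials per image are used.
    Returns one row per (N, subsample).
    """
    responses = np.asarray(responses)
    P, m_max, n_units = responses.shape
    rows = []
    for n in sample_sizes:
        if n > n_units:
            raise ValueError(f"cannot sample {n} of {n_units} units")
        m = max(int(round(trial_fraction * n)), 2)
        if m > m_max:
            raise ValueError(f"need {m} trials per image, have {m_max}")
        for s in range(n_subsamples):
            rng = child_rng(seed, f"capacity-sub-{n}-{s}")
            units = rng.choice(n_units, size=n, replace=False)
            trials = rng.choice(m_max, size=m, replace=False)
            manifolds = [responses[p][np.ix_(trials, units)].astype(float)
                         for p in range(P)]
            geo = ensemble_geometry(manifolds, n_t=n_t, kappa=kappa,
                                    seed=child_seed(seed, f"geo-{n}-{s}"))
            rows.append({"n_units": n, "subsample": s,
                         "capacity": geo.capacity,
                         "dimension": geo.dimension,
                         "radius": geo.radius})
    return pd.DataFrame(rows)
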