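"""Linear Fisher information of stimulus contrast and orientation.

The linear Fisher information I_F(s) = f'(s)^T Sigma^{-1}(s) f'(s) measures
the precision of the optimal linear decoder of a stimulus parameter s from
population spike counts.  From finite trials it is estimated with the
bias-corrected form

    I_bc = d'^T [ (Q1 + Q2)/2 ]^{-1} d' * (2 N_tr - N - 3)/(2 N_tr - 2)
           - 2 N / (N_tr dx^2),            d' = (f2 - f1)/dx

where f_i, Q_i are the empirical class means and covariances at the two
parameter values separated by dx, N the number of units and N_tr the trials
per class.

Trials follow an ON/OFF protocol: stimulus 1 is present throughout; stimulus
2 appears during 200-ms ON intervals separated by 300-ms OFF intervals, with
its contrast (c +/- dc/2, c = 0.5, dc = 0.01) or orientation
(theta +/- dtheta/2, theta = pi/2, dtheta = 0.02 rad) randomized per ON
interval.  During OFF intervals the V1_2 population fires as independent
Poisson processes at the 5-Hz spontaneous rate.  Spike counts of excitatory
V4/MT units in the ON windows are the trials; the first count of each
simulation is dropped.

The information available in the V1 input is computed analytically from the
filter model: the count covariance combines the filtered OU pixel noise,
Var(xi_T) = sigma_n^2 [T - tau_n (1 - exp(-T/tau_n))], with the Poisson
point-process variance.  Saturation of the network information with
population size is summarized by fitting 1/I_N = (1/a)(1/N) + 1/I_inf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .circuit import ConnectivityGraph
from .simulator import integrate
from .stimuli import pixel_lattice
from .v1 import Condition, LocationStimulus, RF_CENTERS, V1Population, \
    generate_v1_spikes
from ._rng import child_rng, child_seed

__all__ = [
    "FisherEstimate",
    "InfoCurve",
    "fisher_trials",
    "bias_corrected_fisher",
    "info_per_spike",
    "sampling_schedule",
    "extrapolate_info",
    "v1_input_information",
]


@dataclass
class FisherEstimate:
    value: float  # bias-corrected estimate, parameter^-2
    n_units: int
    n_trials: int  # per class
    dx: float
    naive: float  # uncorrected quadratic-form estimate
    ridge: float = 0.0


@dataclass
class InfoCurve:
    n: np.ndarray
    info: np.ndarray
    slope: float  # 1/a
    intercept: float  # 1/I_inf
    i_inf: float
    i_inf_ci: tuple


# ---------------------------------------------------------------------------
# ON/OFF trial protocol

def _on_off_schedule(kind, delta, duration, labels, t_on, t_off,
                     c1, theta1, c2, theta2, off_rate):
    cycle = t_on + t_off
    loc1 = LocationStimulus.gabors([(c1, theta1)])
    segs = []
    for k, lab in enumerate(labels):
        t0 = k * cycle
        sign = 0.5 if lab else -0.5
        if kind == "contrast":
            stim2 = LocationStimulus.gabors([(c2 + sign * delta, theta2)])
        elif kind == "orientation":
            stim2 = LocationStimulus.gabors([(c2, theta2 + sign * delta)])
        else:
            raise ValueError("kind must be 'contrast' or 'orientation'")
        segs.append((t0, t0 + t_on, Condition(loc1, stim2, f"on-{lab}")))
        t1 = min(t0 + cycle, duration)
        if t1 > t0 + t_on:
            segs.append((t0 + t_on, t1,
                         Condition(loc1, LocationStimulus.flat(off_rate), "off")))
    return segs


def fisher_trials(
    network: ConnectivityGraph,
    pop: V1Population,
    kind: str = "contrast",
    delta: float | None = None,
    duration: float = 20000.0,
    n_sims: int = 1,
    seed: int = 0,
    t_on: float = 200.0,
    t_off: float = 300.0,
    c1: float = 0.5,
    theta1: float = 0.0,
    c2: float = 0.5,
    theta2: float = np.pi / 2,
    off_rate: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the ON/OFF protocol and return (counts, labels).

    counts: (n_trials, N_e) spike counts of excitatory units in ON windows
    (first window of each simulation excluded); labels: 0/1 for the
    minus/plus parameter class, balanced to within one per simulation.  The
    connectivity is fixed; the membrane initial state is re-randomized each
    simulation.
    """
    if delta is None:
        delta = 0.01 if kind == "contrast" else 0.02
    if delta <= 0:
        raise ValueError("delta must be positive")
    cycle = t_on + t_off
    n_on = int(duration // cycle)
    all_counts, all_labels = [], []
    for s in range(n_sims):
        rng = child_rng(seed, f"fisher-labels-{s}")
        labels = np.zeros(n_on, dtype=int)
        labels[: n_on // 2] = 1
        labels = rng.permutation(labels)
        segs = _on_off_schedule(kind, delta, duration, labels, t_on, t_off,
                                c1, theta1, c2, theta2, off_rate)
        ff = generate_v1_spikes(pop, segs, duration,
                                seed=child_seed(seed, f"fisher-v1-{s}"))
        res = integrate(network, ff, duration,
                        seed=child_seed(seed, f"fisher-net-{s}"), n_record=0)
        ids = res.spikes.ids
        times = res.spikes.times
        e_sel = ids < res.n_e
        ids = ids[e_sel]
        times = times[e_sel]
        on_index = (times % cycle) < t_on
        trial = (times // cycle).astype(np.int64)
        counts = np.zeros((n_on, res.n_e), dtype=np.int64)
        np.add.at(counts, (trial[on_index], ids[on_index]), 1)
        all_counts.append(counts[1:])  # drop the first count
        all_labels.append(labels[1:])
    return np.vstack(all_counts), np.concatenate(all_labels)


# ---------------------------------------------------------------------------
# estimators

def bias_corrected_fisher(x1: np.ndarray, x2: np.ndarray, dx: float,
                          allow_ridge: bool = True) -> FisherEstimate:
    """Bias-corrected linear Fisher information from two classes of counts.

    ``x1``, ``x2`` are (trials, units).  When the classes have unequal trial
    counts, N_tr is their mean.  A small ridge (1e-6 * trace/N) is added only
    if the pooled covariance is numerically singular.
    """
    x1 = np.atleast_2d(np.asarray(x1, float))
    x2 = np.atleast_2d(np.asarray(x2, float))
    n_units = x1.shape[1]
    n_tr = 0.5 * (x1.shape[0] + x2.shape[0])
    if 2 * n_tr - 2 <= n_units + 1:
        raise ValueError(
            f"estimability requires 2*N_tr - 2 > N + 1 (N={n_units}, N_tr={n_tr})")
    f1 = x1.mean(axis=0)
    f2 = x2.mean(axis=0)
    q = 0.5 * (np.cov(x1, rowvar=False) + np.cov(x2, rowvar=False))
    q = np.atleast_2d(q)
    dp = (f2 - f1) / dx
    ridge = 0.0
    try:
        sol = np.linalg.solve(q, dp)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        if not allow_ridge:
            raise
        ridge = 1e-6 * np.trace(q) / n_units
        if ridge <= 0:
            ridge = 1e-12
        warnings.warn("singular pooled covariance; applying ridge "
                      f"{ridge:.3e}", RuntimeWarning)
        sol = np.linalg.solve(q + ridge * np.eye(n_units), dp)
    naive = float(dp @ sol)
    value = naive * (2 * n_tr - n_units - 3) / (2 * n_tr - 2) \
        - 2 * n_units / (n_tr * dx**2)
    return FisherEstimate(value=value, n_units=n_units, n_trials=int(n_tr),
                          dx=dx, naive=naive, ridge=ridge)


def sampling_schedule(n_values: np.ndarray, full: np.ndarray | None = None
                      ) -> np.ndarray:
    """Number of random unit samples per population size N: decreases from
    200 to 14 proportionally with log(N) up to N = 545, then 5."""
    n_values = np.asarray(n_values)
    n_samp = np.where(
        n_values >= 545, 5,
        np.round(200 + (14 - 200) * np.log(np.maximum(n_values, 1))
                 / np.log(545)).astype(int))
    return np.maximum(n_samp.astype(int), 1)


def info_per_spike(
    counts: np.ndarray,
    labels: np.ndarray,
    ni: np.ndarray,
    ni_range: tuple,
    dx: float,
    n_values: np.ndarray,
    seed: int = 0,
    min_rate_hz: float = 1.0,
    window_ms: float = 200.0,
    n_samples: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fisher information per spike for units in a normalization-index range.

    Units are those with NI inside ``ni_range`` and mean rate at least
    ``min_rate_hz``; for each population size N in ``n_values`` the units are
    randomly sampled ``n_samples`` times (default: the log-proportional
    schedule) and the bias-corrected information is divided by the mean total
    spike count of the sampled group in the counting window.
    """
    counts = np.asarray(counts)
    labels = np.asarray(labels)
    ni = np.asarray(ni, float)
    mean_rate = counts.mean(axis=0) / (window_ms / 1000.0)
    stratum = np.flatnonzero(
        np.isfinite(ni) & (ni >= ni_range[0]) & (ni < ni_range[1])
        & (mean_rate >= min_rate_hz))
    if stratum.size == 0:
        warnings.warn(f"empty NI stratum {ni_range}; skipped", RuntimeWarning)
        return pd.DataFrame()
    rng = child_rng(seed, "info-sampling")
    if n_samples is None:
        n_samples = sampling_schedule(np.asarray(n_values))
    rows = []
    x1_all = counts[labels == 0]
    x2_all = counts[labels == 1]
    for n, ns in zip(n_values, n_samples):
        if n > stratum.size:
            continue
        for s in range(int(ns)):
            units = rng.choice(stratum, size=int(n), replace=False)
            est = bias_corrected_fisher(x1_all[:, units], x2_all[:, units], dx)
            total = counts[:, units].sum(axis=1).mean()
            rows.append({"n_units": int(n), "sample": s,
                         "total_spikes": total, "info": est.value,
                         "info_per_spike": est.value / total if total > 0
                         else np.nan})
    return pd.DataFrame(rows)


def extrapolate_info(n_values, info_values) -> InfoCurve:
    """Estimate the asymptotic information I_inf from the linear relation
    1/I_N = (1/a)(1/N) + 1/I_inf (ordinary least squares).

    A non-positive intercept is reported as I_inf = inf (information does not
    saturate)."""
    n = np.asarray(n_values, float)
    i = np.asarray(info_values, float)
    if n.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(i <= 0):
        raise ValueError("information values must be positive")
    x = 1.0 / n
    y = 1.0 / i
    coef, cov = np.polyfit(x, y, 1, cov=True)
    slope, intercept = coef
    se = np.sqrt(max(cov[1, 1], 0.0))
    lo, hi = intercept - 1.96 * se, intercept + 1.96 * se
    i_inf = np.inf if intercept <= 0 else 1.0 / intercept
    ci = (1.0 / hi if hi > 0 else np.inf, 1.0 / lo if lo > 0 else np.inf)
    return InfoCurve(n=n, info=i, slope=slope, intercept=intercept,
                     i_inf=i_inf, i_inf_ci=ci)


# ---------------------------------------------------------------------------
# analytic V1 input information

def _gabor_and_derivative(kind, c, theta, center, sigma, lam, npix):
    xx, yy = pixel_lattice(center, npix)
    dx = xx - center[0]
    dy = yy - center[1]
    env = np.exp(-(dx**2 + dy**2) / (2 * sigma**2))
    psi = (2 * np.pi / lam) * (dx * np.cos(theta) + dy * np.sin(theta))
    m = c * env * np.cos(psi)
    if kind == "contrast":
        dm = env * np.cos(psi)
    elif kind == "orientation":
        dm = -c * env * np.sin(psi) * (2 * np.pi / lam) \
            * (-dx * np.sin(theta) + dy * np.cos(theta))
    else:
        raise ValueError("kind must be 'contrast' or 'orientation'")
    return m, dm


def v1_input_information(
    pop: V1Population,
    kind: str = "contrast",
    window_ms: float = 200.0,
    c: float = 0.5,
    theta: float = np.pi / 2,
    location: int = 1,
    noise_scale: float | None = None,
) -> float:
    """Analytic linear Fisher information about the contrast or orientation
    of the image at one location, carried by that location's V1 population
    over a counting window.

    Count statistics follow the linear filter model: the mean is the
    rectified filter response, the covariance combines the filtered OU pixel
    noise (integrated variance Var(xi_T) = sigma_n^2 [T - tau_n
    (1 - e^{-T/tau_n})]) with independent Poisson variance.  Units whose
    noise-free response is rectified to zero carry no signal derivative.
    """
    if not np.isfinite(pop.gain):
        raise RuntimeError("population must be calibrated")
    kappa = pop.noise_scale if noise_scale is None else noise_scale
    g = pop.gain / 1000.0  # spikes per ms per response unit
    T = window_ms
    F = pop.filters[location]
    area = pop.cell_area
    m, dm = _gabor_and_derivative(kind, c, theta, RF_CENTERS[location],
                                  pop.sigma, pop.lambda_wave, pop.npix)
    mu = area * (F @ m.ravel(order="C"))
    dmu = area * (F @ dm.ravel(order="C"))
    active = mu > 0
    fprime = g * T * dmu * active
    var_xi = pop.sigma_n**2 * (T - pop.tau_n * (1 - np.exp(-T / pop.tau_n)))
    cov = (g * kappa * area) ** 2 * (F @ F.T) * var_xi
    # Poisson point-process variance, with the mean of the rectified response
    sd = kappa * pop.filter_noise_std(location)
    z = np.divide(mu, sd, out=np.full_like(mu, np.inf), where=sd > 0)
    mean_resp = mu * norm.cdf(z) + sd * norm.pdf(z)
    cov[np.diag_indices_from(cov)] += g * T * mean_resp
    try:
        sol = np.linalg.solve(cov, fprime)
    except np.linalg.LinAlgError:
        ridge = 1e-6 * np.trace(cov) / cov.shape[0]
        warnings.warn(f"singular input covariance; ridge {ridge:.3e}",
                      RuntimeWarning)
        sol = np.linalg.solve(cov + ridge * np.eye(cov.shape[0]), fprime)
    return float(fprime @ sol)
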