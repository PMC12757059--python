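"""Rate and correlation statistics.

The central quantity is the normalization index of a neuron,

    NI = (FR_stim1 + FR_stim2) / FR_both,

the sum of its firing rates to each image presented alone divided by its rate
when both images are presented together; NI = 1 is linear summation, NI > 1
sublinear (normalizing) summation.  The same index applied to the
time-averaged synaptic current of one type (feedforward E, recurrent E,
recurrent I) is the current normalization index.

Spike-count correlations are Pearson correlations of counts in 200-ms windows
slid by 50 ms (pooled across simulations of one condition, the first second
of each simulation excluded).  Units enter the correlation analyses when
their rate is within one population SD of the population-mean rate in all
three stimulus conditions.

The covariance between the total input currents of a pair decomposes by
bilinearity as

    Cov(T1, T2) = Cov(E1, E2) + Cov(E1, I2) + Cov(I1, E2) + Cov(I1, I2)

with E = feedforward + recurrent excitation and I = recurrent inhibition.

Also provided are the generic single-unit / pairwise conventions used for
trial-based recordings (3-SD outlier-trial exclusion, responsiveness t-test,
same-electrode pair exclusion), operating on a trials x units count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulator import SimulationResult

__all__ = [
    "normalization_index",
    "current_normalization_index",
    "selectivity",
    "tuning_similarity",
    "sliding_counts",
    "pooled_counts",
    "inclusion_mask",
    "spike_count_correlations",
    "normalization_table",
    "bin_by_normalization",
    "covariance_decomposition",
    "bin_covariance_fixed_ni1",
    "bin_covariance_similar_ni",
    "contrast_sensitivity",
    "TrialCountMatrix",
    "deviant_trials",
    "responsive_units",
    "valid_pairs",
]

CONDITIONS = ("stim1", "stim2", "both")


# ---------------------------------------------------------------------------
# elementary indices

def normalization_index(fr1, fr2, fr_both):
    """(FR1 + FR2) / FR_both; NaN where FR_both <= 0 (unit excluded)."""
    fr1 = np.asarray(fr1, dtype=float)
    fr2 = np.asarray(fr2, dtype=float)
    fr_both = np.asarray(fr_both, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ni = (fr1 + fr2) / fr_both
    return np.where(fr_both > 0, ni, np.nan)


def current_normalization_index(i1, i2, i_both):
    """(I1 + I2) / I_both on time-averaged signed currents; NaN where
    I_both == 0.  For inhibitory currents the signs cancel, so the index is
    positive, as for rates."""
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    i_both = np.asarray(i_both, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ni = (i1 + i2) / i_both
    return np.where(i_both != 0, ni, np.nan)


def selectivity(fr1, fr2):
    """(FR1 - FR2)/(FR1 + FR2) in [-1, 1]; NaN where both rates are zero."""
    fr1 = np.asarray(fr1, dtype=float)
    fr2 = np.asarray(fr2, dtype=float)
    tot = fr1 + fr2
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (fr1 - fr2) / tot
    return np.where(tot > 0, s, np.nan)


def tuning_similarity(curves: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of orientation tuning curves.

    ``curves`` is (n_units, n_orientations); rows with zero variance yield
    NaN against every partner.
    """
    curves = np.asarray(curves, dtype=float)
    sd = curves.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(curves)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    return r


# ---------------------------------------------------------------------------
# spike counts and correlations

def sliding_counts(result: SimulationResult, window: float = 200.0,
                   step: float = 50.0, units: np.ndarray | None = None,
                   exclude_burn_in: bool = True) -> np.ndarray:
    """Spike counts in sliding windows: (n_windows, n_units).

    Windows of ``window`` ms advance by ``step`` ms; only windows fully after
    the burn-in are returned.  ``units`` defaults to the excitatory
    population.
    """
    if window % step > 1e-9:
        raise ValueError("step must divide window")
    t0 = result.burn_in if exclude_burn_in else 0.0
    raster = result.spikes
    units = np.arange(result.n_e) if units is None else np.asarray(units)
    n_steps_win = int(round(window / step))
    n_bins = int(np.floor((result.duration - t0) / step))
    sel = raster.times >= t0
    ids = raster.ids[sel]
    bins = ((raster.times[sel] - t0) / step).astype(np.int64)
    keep = bins < n_bins
    remap = -np.ones(raster.n_neurons, dtype=np.int64)
    remap[units] = np.arange(units.size)
    uid = remap[ids[keep]]
    b = bins[keep]
    ok = uid >= 0
    fine = np.zeros((n_bins, units.size), dtype=np.int64)
    np.add.at(fine, (b[ok], uid[ok]), 1)
    c = np.cumsum(fine, axis=0)
    n_win = n_bins - n_steps_win + 1
    if n_win <= 0:
        return np.zeros((0, units.size), dtype=np.int64)
    out = np.empty((n_win, units.size), dtype=np.int64)
    out[0] = c[n_steps_win - 1]
    out[1:] = c[n_steps_win:] - c[:-n_steps_win]
    return out


def pooled_counts(results: list[SimulationResult], **kw) -> np.ndarray:
    """Sliding counts pooled (stacked) across simulations of one condition."""
    return np.vstack([sliding_counts(r, **kw) for r in results])


def inclusion_mask(rates_by_condition: np.ndarray) -> np.ndarray:
    """Units whose rate is within one population SD of the population mean in
    every condition.  ``rates_by_condition`` is (n_conditions, n_units)."""
    r = np.asarray(rates_by_condition, dtype=float)
    mu = r.mean(axis=1, keepdims=True)
    sd = r.std(axis=1, keepdims=True)
    return np.all(np.abs(r - mu) <= sd, axis=0)


def spike_count_correlations(results: list[SimulationResult],
                             units: np.ndarray | None = None,
                             window: float = 200.0, step: float = 50.0
                             ) -> np.ndarray:
    """Pairwise Pearson correlation of sliding spike counts, pooled across
    simulations.  Pairs involving a zero-variance unit are NaN; the diagonal
    is 1 for units with variance."""
    counts = pooled_counts(results, window=window, step=step, units=units)
    sd = counts.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(counts.T.astype(float))
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    return r


# ---------------------------------------------------------------------------
# normalization table

def normalization_table(results_by_condition: dict,
                        units: np.ndarray | None = None) -> pd.DataFrame:
    """Per-unit rates, normalization / selectivity indices and current
    normalization indices from the three stimulus conditions.

    ``results_by_condition`` maps "stim1" / "stim2" / "both" to lists of
    :class:`SimulationResult` (matched seeds across conditions).  Rates and
    currents are averaged over the post-burn-in epoch and across simulations.
    """
    for c in CONDITIONS:
        if c not in results_by_condition:
            raise ValueError(f"missing condition {c!r}")
    first = results_by_condition["both"][0]
    units = np.arange(first.n_e) if units is None else np.asarray(units)

    rates = {}
    currents = {}
    for c in CONDITIONS:
        rs = results_by_condition[c]
        rates[c] = np.mean([r.rates()[units] for r in rs], axis=0)
        mc = [r.mean_currents() for r in rs]
        currents[c] = {k: np.mean([m[k][units] for m in mc], axis=0)
                       for k in ("ff", "re", "ri")}

    ni = normalization_index(rates["stim1"], rates["stim2"], rates["both"])
    sel = selectivity(rates["stim1"], rates["stim2"])
    pop_rates = np.vstack([rates[c] for c in CONDITIONS])
    include = inclusion_mask(pop_rates) & np.isfinite(ni)
    df = pd.DataFrame({
        "unit": units,
        "fr_stim1": rates["stim1"],
        "fr_stim2": rates["stim2"],
        "fr_both": rates["both"],
        "norm_index": ni,
        "selectivity": sel,
        "include": include,
    })
    for k in ("ff", "re", "ri"):
        df[f"ni_{k}"] = current_normalization_index(
            currents["stim1"][k], currents["stim2"][k], currents["both"][k])
    return df


# ---------------------------------------------------------------------------
# correlation vs normalization binning

def _pair_arrays(ni, corr):
    iu = np.triu_indices(len(ni), k=1)
    return ni[iu[0]], ni[iu[1]], corr[iu]


def bin_by_normalization(ni: np.ndarray, corr: np.ndarray,
                         tuning: np.ndarray | None = None,
                         edges: np.ndarray | None = None,
                         mean_ni_center: float = 1.5,
                         mean_ni_halfwidth: float = 0.25,
                         similar_dni: float = 0.5,
                         distinct_dni: float = 1.0) -> dict:
    """Summaries of pairwise correlations as a function of the pair's
    normalization indices.

    Returns a dict with:
      - ``heatmap``: mean r over (NI1, NI2) bins (symmetrized), with
        ``edges`` (default 1 to 3 in steps of 0.25); empty bins are NaN
      - ``dni``: mean r vs |NI1 - NI2| for pairs of mean NI near
        ``mean_ni_center``
      - ``mean_ni``: mean r vs pair-mean NI for pairs with |dNI| < 0.5
      - ``tuning_bins``: mean r for similar (|dNI| < 0.5) vs distinct
        (|dNI| > 1) pairs per tuning-similarity bin (if ``tuning`` given)
    """
    edges = np.arange(1.0, 3.01, 0.25) if edges is None else np.asarray(edges)
    ni1, ni2, r = _pair_arrays(np.asarray(ni, float), np.asarray(corr, float))
    ok = np.isfinite(ni1) & np.isfinite(ni2) & np.isfinite(r)
    ni1, ni2, r = ni1[ok], ni2[ok], r[ok]

    nb = edges.size - 1
    b1 = np.digitize(ni1, edges) - 1
    b2 = np.digitize(ni2, edges) - 1
    inb = (b1 >= 0) & (b1 < nb) & (b2 >= 0) & (b2 < nb)
    hsum = np.zeros((nb, nb))
    hcnt = np.zeros((nb, nb))
    np.add.at(hsum, (b1[inb], b2[inb]), r[inb])
    np.add.at(hcnt, (b1[inb], b2[inb]), 1)
    hsum = hsum + hsum.T - np.diag(np.diag(hsum))
    hcnt = hcnt + hcnt.T - np.diag(np.diag(hcnt))
    with np.errstate(invalid="ignore"):
        heatmap = np.where(hcnt > 0, hsum / np.maximum(hcnt, 1), np.nan)

    dni = np.abs(ni1 - ni2)
    mni = 0.5 * (ni1 + ni2)

    def curve(x, mask, xedges):
        xb = np.digitize(x[mask], xedges) - 1
        m = (xb >= 0) & (xb < xedges.size - 1)
        s = np.zeros(xedges.size - 1)
        c = np.zeros(xedges.size - 1)
        np.add.at(s, xb[m], r[mask][m])
        np.add.at(c, xb[m], 1)
        centers = 0.5 * (xedges[:-1] + xedges[1:])
        with np.errstate(invalid="ignore"):
            return centers, np.where(c > 0, s / np.maximum(c, 1), np.nan), c

    dni_edges = np.arange(0.0, 2.01, 0.25)
    at_center = np.abs(mni - mean_ni_center) <= mean_ni_halfwidth
    out = {
        "heatmap": heatmap,
        "edges": edges,
        "dni": curve(dni, at_center, dni_edges),
        "mean_ni": curve(mni, dni < similar_dni, edges),
    }
    if tuning is not None:
        t1, t2, tv = _pair_arrays(np.asarray(ni, float),
                                  np.asarray(tuning, float))
        tv = tv[ok]
        tedges = np.linspace(-1, 1, 9)
        tb = np.digitize(tv, tedges) - 1
        rows = []
        for b in range(tedges.size - 1):
            m = tb == b
            sim = m & (dni < similar_dni)
            dis = m & (dni > distinct_dni)
            rows.append({
                "tuning_bin": 0.5 * (tedges[b] + tedges[b + 1]),
                "r_similar": r[sim].mean() if sim.any() else np.nan,
                "n_similar": int(sim.sum()),
                "r_distinct": r[dis].mean() if dis.any() else np.nan,
                "n_distinct": int(dis.sum()),
            })
        out["tuning_bins"] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# current covariance decomposition

def covariance_decomposition(results: list[SimulationResult],
                             pairs: np.ndarray) -> pd.DataFrame:
    """Covariance components of the total input currents of neuron pairs.

    ``pairs`` is (n_pairs, 2) of recorded-neuron indices.  E = feedforward +
    recurrent excitatory current, I = recurrent inhibitory current, sampled
    on the 10-ms cadence, pooled across simulations, burn-in excluded.
    """
    pairs = np.asarray(pairs)
    Es, Is = [], []
    for res in results:
        sel = res.current_times >= res.burn_in
        E = (res.currents["ff"][:, sel] + res.currents["re"][:, sel]).astype(float)
        I = res.currents["ri"][:, sel].astype(float)
        Es.append(E)
        Is.append(I)
    E = np.hstack(Es)
    I = np.hstack(Is)
    if E.shape[1] < 2:
        raise ValueError("not enough current samples")

    def cov(a, b):
        am = a - a.mean(axis=1, keepdims=True)
        bm = b - b.mean(axis=1, keepdims=True)
        return (am * bm).sum(axis=1) / (a.shape[1] - 1)

    i1, i2 = pairs[:, 0], pairs[:, 1]
    out = pd.DataFrame({
        "unit1": i1, "unit2": i2,
        "cov_ee": cov(E[i1], E[i2]),
        "cov_ei": cov(E[i1], I[i2]),
        "cov_ie": cov(I[i1], E[i2]),
        "cov_ii": cov(I[i1], I[i2]),
        "cov_total": cov(E[i1] + I[i1], E[i2] + I[i2]),
    })
    return out


def bin_covariance_fixed_ni1(cov_df: pd.DataFrame, ni: np.ndarray,
                             ni1_range=(1.0, 1.5),
                             edges: np.ndarray | None = None) -> pd.DataFrame:
    """Mean covariance components vs NI of neuron 2, for pairs whose neuron 1
    has NI in ``ni1_range`` (pairs are used in both orientations)."""
    edges = np.arange(1.0, 3.01, 0.25) if edges is None else np.asarray(edges)
    ni = np.asarray(ni, float)
    rows = []
    a = cov_df.copy()
    b = cov_df.rename(columns={
        "unit1": "unit2", "unit2": "unit1",
        "cov_ei": "cov_ie", "cov_ie": "cov_ei"})
    both = pd.concat([a, b], ignore_index=True)
    n1 = ni[both["unit1"].to_numpy()]
    n2 = ni[both["unit2"].to_numpy()]
    sel = (n1 >= ni1_range[0]) & (n1 <= ni1_range[1]) & np.isfinite(n2)
    sub = both[sel]
    n2 = n2[sel]
    for k in range(edges.size - 1):
        m = (n2 >= edges[k]) & (n2 < edges[k + 1])
        if not m.any():
            continue
        rows.append({
            "ni2": 0.5 * (edges[k] + edges[k + 1]),
            "n": int(m.sum()),
            **{c: sub[c][m].mean() for c in
               ("cov_ee", "cov_ei", "cov_ie", "cov_ii", "cov_total")},
        })
    return pd.DataFrame(rows)


def bin_covariance_similar_ni(cov_df: pd.DataFrame, ni: np.ndarray,
                              max_dni: float = 0.6,
                              edges: np.ndarray | None = None) -> pd.DataFrame:
    """Mean covariance components vs pair-mean NI for similar pairs
    (|dNI| < ``max_dni``)."""
    edges = np.arange(1.0, 3.01, 0.25) if edges is None else np.asarray(edges)
    ni = np.asarray(ni, float)
    n1 = ni[cov_df["unit1"].to_numpy()]
    n2 = ni[cov_df["unit2"].to_numpy()]
    ok = np.isfinite(n1) & np.isfinite(n2) & (np.abs(n1 - n2) < max_dni)
    mni = 0.5 * (n1 + n2)
    rows = []
    for k in range(edges.size - 1):
        m = ok & (mni >= edges[k]) & (mni < edges[k + 1])
        if not m.any():
            continue
        rows.append({
            "mean_ni": 0.5 * (edges[k] + edges[k + 1]),
            "n": int(m.sum()),
            **{c: cov_df[c][m].mean() for c in
               ("cov_ee", "cov_ei", "cov_ie", "cov_ii", "cov_total")},
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contrast sensitivity

def contrast_sensitivity(rates_by_dc: dict, ni: np.ndarray,
                         ni_edges: np.ndarray | None = None) -> pd.DataFrame:
    """Spread of relative rate changes r/r0 versus contrast difference.

    ``rates_by_dc`` maps the contrast offset dc (images at contrasts
    0.5 + dc and 0.5 - dc) to per-unit rates; dc = 0 must be present and
    provides r0.  Units with r0 <= 0 or undefined NI are excluded.  Returns
    SD (and mean) of r/r0 per (dc, NI bin).
    """
    if 0.0 not in rates_by_dc:
        raise ValueError("the dc = 0 condition is required")
    ni_edges = np.array([1.0, 1.5, 2.0, 3.0]) if ni_edges is None \
        else np.asarray(ni_edges)
    r0 = np.asarray(rates_by_dc[0.0], float)
    ni = np.asarray(ni, float)
    ok = (r0 > 0) & np.isfinite(ni)
    rows = []
    for dc in sorted(rates_by_dc):
        rel = np.asarray(rates_by_dc[dc], float)[ok] / r0[ok]
        nio = ni[ok]
        for k in range(ni_edges.size - 1):
            m = (nio >= ni_edges[k]) & (nio < ni_edges[k + 1])
            if m.sum() < 2:
                continue
            rows.append({
                "dc": dc,
                "ni_bin": 0.5 * (ni_edges[k] + ni_edges[k + 1]),
                "ni_lo": ni_edges[k], "ni_hi": ni_edges[k + 1],
                "n": int(m.sum()),
                "mean_rel": rel[m].mean(),
                "sd_rel": rel[m].std(ddof=1),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conventions for trial-based count matrices

@dataclass
class TrialCountMatrix:
    """Trials x units spike counts with per-trial condition labels."""

    counts: np.ndarray  # (n_trials, n_units), nonnegative
    conditions: np.ndarray  # (n_trials,) labels
    window: tuple = (0.0, 200.0, 200.0)  # (start, length, step) ms
    unit_ids: np.ndarray | None = None
    electrode_ids: np.ndarray | None = None  # (n_units,)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.conditions = np.asarray(self.conditions)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.conditions.shape[0] != self.counts.shape[0]:
            raise ValueError("every trial needs a condition label")


def deviant_trials(tm: TrialCountMatrix, n_sd: float = 3.0) -> np.ndarray:
    """Boolean (n_trials, n_units): unit's count is more than ``n_sd`` SDs
    from its per-condition mean.  When a unit's per-condition SD is zero, any
    nonzero deviation is deviant."""
    dev = np.zeros(tm.counts.shape, dtype=bool)
    for c in np.unique(tm.conditions):
        rows = tm.conditions == c
        x = tm.counts[rows].astype(float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        d = np.abs(x - mu)
        dev[rows] = np.where(sd > 0, d > n_sd * sd, d > 0)
    return dev


def responsive_units(tm: TrialCountMatrix, blank_label, driven_labels,
                     alpha: float = 0.01) -> np.ndarray:
    """Units whose response to the blank (0%-contrast) condition differs from
    the pooled high-contrast conditions (two-sample t-test, p < alpha)."""
    blank = tm.counts[tm.conditions == blank_label].astype(float)
    driven = tm.counts[np.isin(tm.conditions, driven_labels)].astype(float)
    if blank.shape[0] < 2 or driven.shape[0] < 2:
        raise ValueError("need >= 2 trials per group for the t-test")
    _, p = stats.ttest_ind(blank, driven, axis=0, equal_var=False)
    return p < alpha


def valid_pairs(tm: TrialCountMatrix, pairs: np.ndarray) -> np.ndarray:
    """Drop pairs recorded on the same electrode (requires electrode_ids)."""
    pairs = np.asarray(pairs)
    if tm.electrode_ids is None:
        return np.ones(pairs.shape[0], dtype=bool)
    e = np.asarray(tm.electrode_ids)
    return e[pairs[:, 0]] != e[pairs[:, 1]]
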