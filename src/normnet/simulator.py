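"""Forward-Euler integration of the V4/MT exponential integrate-and-fire
network with current-based double-exponential synapses.

Membrane dynamics (per neuron j of population a in {e, i}):

    C_m dV/dt = -g_L (V - E_L) + g_L Delta_T exp((V - V_T)/Delta_T) + I_j(t)

A spike is recorded when V crosses V_th; the membrane is clamped for the
refractory period tau_ref and then reset to V_re.  Synaptic currents are the
weighted sum of normalized double-exponential kernels

    eta(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / (tau_d - tau_r),  t >= 0

per presynaptic spike; feedforward synapses mix a fast and a slow component,
eta_F = p_f * eta_e + p_s * eta_s.  Kernel states are advanced by exact
exponential updates; the membrane by forward Euler with dt = 0.05 ms.  There
are no transmission delays.  Currents are expressed as I/C_m in mV/ms and
each type (feedforward E, recurrent E, recurrent I) is sampled every 10 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .circuit import ConnectivityGraph
from .v1 import SpikeRaster
from ._rng import child_rng

__all__ = [
    "EIFParams",
    "SynapticKernel",
    "SimulationResult",
    "E_PARAMS",
    "I_PARAMS",
    "KERNEL_E",
    "KERNEL_I",
    "KERNEL_SLOW",
    "kernel_filter",
    "integrate",
]


@dataclass(frozen=True)
class EIFParams:
    tau_m: float  # ms (= C_m / g_L)
    E_L: float = -60.0  # mV
    V_T: float = -50.0  # mV
    V_th: float = -10.0  # mV
    delta_T: float = 2.0  # mV
    V_re: float = -65.0  # mV
    tau_ref: float = 1.5  # ms

    def __post_init__(self):
        if not (self.V_re < self.V_T < self.V_th):
            raise ValueError("require V_re < V_T < V_th")
        if self.delta_T <= 0 or self.tau_ref <= 0:
            raise ValueError("delta_T and tau_ref must be positive")


E_PARAMS = EIFParams(tau_m=15.0, delta_T=2.0, tau_ref=1.5)
I_PARAMS = EIFParams(tau_m=10.0, delta_T=0.5, tau_ref=0.5)


@dataclass(frozen=True)
class SynapticKernel:
    tau_r: float
    tau_d: float

    def __post_init__(self):
        if not (self.tau_d > self.tau_r > 0):
            raise ValueError("require tau_d > tau_r > 0 (degenerate kernel)")

    def peak_time(self) -> float:
        r, d = self.tau_r, self.tau_d
        return r * d * np.log(d / r) / (d - r)


KERNEL_E = SynapticKernel(1.0, 5.0)
KERNEL_I = SynapticKernel(1.0, 8.0)
KERNEL_SLOW = SynapticKernel(2.0, 100.0)
P_FAST = 0.2
P_SLOW = 0.8


@njit(cache=True)
def _filter_kernel(spike_bins, n_bins, dt, tau_r, tau_d, out):
    dr = np.exp(-dt / tau_r)
    dd = np.exp(-dt / tau_d)
    inv = 1.0 / (tau_d - tau_r)
    xr = 0.0
    xd = 0.0
    m = 0
    n_spk = spike_bins.shape[0]
    for b in range(n_bins):
        xr *= dr
        xd *= dd
        while m < n_spk and spike_bins[m] == b:
            xr += 1.0
            xd += 1.0
            m += 1
        out[b] = (xd - xr) * inv


def kernel_filter(spike_times, kernel: SynapticKernel, duration: float,
                  dt: float = 0.05) -> np.ndarray:
    """Causal convolution of a spike train with a double-exponential kernel,
    via exact per-step exponential updates.  Returns the trace sampled at
    every dt."""
    spike_times = np.sort(np.asarray(spike_times, dtype=np.float64))
    n_bins = int(round(duration / dt))
    bins = np.round(spike_times / dt).astype(np.int64)
    out = np.empty(n_bins)
    _filter_kernel(bins, n_bins, dt, kernel.tau_r, kernel.tau_d, out)
    return out


@njit(cache=True)
def _integrate_kernel(
    n_e, n, dt, n_steps,
    taum_e, dT_e, tref_e, taum_i, dT_i, tref_i,
    EL, VT, Vth, Vre,
    de_r, de_d, di_r, di_d, ds_r, ds_d,
    pf, ps, inv_e, inv_i, inv_s,
    rec_indptr, rec_post, rec_w,
    ff_indptr, ff_post, ff_w,
    ff_bins, ff_ids,
    V, ext_drive,
    rec_every, n_rec, cur_ff, cur_re, cur_ri,
    spk_bins, spk_ids,
):
    xr_e = np.zeros(n)
    xd_e = np.zeros(n)
    xr_i = np.zeros(n)
    xd_i = np.zeros(n)
    xr_f = np.zeros(n)
    xd_f = np.zeros(n)
    xr_s = np.zeros(n)
    xd_s = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)
    cap = spk_bins.shape[0]
    n_spk = 0
    prev_lo = 0
    ffp = 0
    n_ff = ff_bins.shape[0]
    sample = 0
    for step in range(n_steps):
        # exact exponential decay of all kernel states
        for i in range(n):
            xr_e[i] *= de_r
            xd_e[i] *= de_d
            xr_i[i] *= di_r
            xd_i[i] *= di_d
            xr_f[i] *= de_r
            xd_f[i] *= de_d
            xr_s[i] *= ds_r
            xd_s[i] *= ds_d
        # feedforward spikes arriving at this step
        while ffp < n_ff and ff_bins[ffp] == step:
            pre = ff_ids[ffp]
            for e in range(ff_indptr[pre], ff_indptr[pre + 1]):
                tgt = ff_post[e]
                w = ff_w[e]
                xr_f[tgt] += w
                xd_f[tgt] += w
                xr_s[tgt] += w
                xd_s[tgt] += w
            ffp += 1
        # recurrent spikes from the previous step
        for s in range(prev_lo, n_spk):
            pre = spk_ids[s]
            if pre < n_e:
                for e in range(rec_indptr[pre], rec_indptr[pre + 1]):
                    tgt = rec_post[e]
                    w = rec_w[e]
                    xr_e[tgt] += w
                    xd_e[tgt] += w
            else:
                for e in range(rec_indptr[pre], rec_indptr[pre + 1]):
                    tgt = rec_post[e]
                    w = rec_w[e]
                    xr_i[tgt] += w
                    xd_i[tgt] += w
        prev_lo = n_spk
        # record currents
        if rec_every > 0 and step % rec_every == 0:
            for i in range(n_rec):
                cur_ff[i, sample] = pf * (xd_f[i] - xr_f[i]) * inv_e \
                    + ps * (xd_s[i] - xr_s[i]) * inv_s
                cur_re[i, sample] = (xd_e[i] - xr_e[i]) * inv_e
                cur_ri[i, sample] = (xd_i[i] - xr_i[i]) * inv_i
            sample += 1
        # membrane update
        for i in range(n):
            if refr[i] > 0:
                refr[i] -= 1
                if refr[i] == 0:
                    V[i] = Vre
                continue
            I = pf * (xd_f[i] - xr_f[i]) * inv_e \
                + ps * (xd_s[i] - xr_s[i]) * inv_s \
                + (xd_e[i] - xr_e[i]) * inv_e \
                + (xd_i[i] - xr_i[i]) * inv_i \
                + ext_drive[i]
            if i < n_e:
                taum = taum_e
                dT = dT_e
                tref = tref_e
            else:
                taum = taum_i
                dT = dT_i
                tref = tref_i
            arg = (V[i] - VT) / dT
            if arg > 20.0:
                # spike initiation is effectively instantaneous this deep
                # into the exponential regime (exact for the LIF limit)
                V[i] = Vth
            else:
                V[i] += dt * (-(V[i] - EL) / taum
                              + dT * np.exp(arg) / taum + I)
            if V[i] >= Vth:
                if n_spk >= cap:
                    return -1, step, 0
                spk_bins[n_spk] = step
                spk_ids[n_spk] = i
                n_spk += 1
                V[i] = Vth
                refr[i] = tref
            elif V[i] < -300.0 or V[i] != V[i]:
                # current-based synapses have no reversal potential, so deep
                # transient hyperpolarization during synchronized inhibitory
                # barrages is physical; only divergence is an error
                return -2, step, i
    return n_spk, n_steps, 0


@dataclass
class SimulationResult:
    """Spikes and per-type synaptic current traces of one simulation."""

    spikes: SpikeRaster  # V4/MT spikes, ids 0..N_e+N_i-1 (E first)
    n_e: int
    n_i: int
    duration: float  # ms
    dt: float
    current_dt: float  # ms, sampling cadence of current traces
    currents: dict  # {"ff", "re", "ri"} -> (n_rec, n_samples) float32, mV/ms
    burn_in: float = 1000.0
    seed: int = -1
    meta: dict = field(default_factory=dict)

    @property
    def current_times(self) -> np.ndarray:
        n = next(iter(self.currents.values())).shape[1]
        return np.arange(n) * self.current_dt

    def _epoch_start(self, exclude_burn_in: bool) -> float:
        t0 = self.burn_in if exclude_burn_in else 0.0
        if t0 >= self.duration:
            raise ValueError(
                f"duration {self.duration} ms leaves no data after the "
                f"{self.burn_in} ms burn-in")
        return t0

    def e_rates(self, exclude_burn_in: bool = True) -> np.ndarray:
        return self.spikes.rates_hz(self._epoch_start(exclude_burn_in))[: self.n_e]

    def rates(self, exclude_burn_in: bool = True) -> np.ndarray:
        return self.spikes.rates_hz(self._epoch_start(exclude_burn_in))

    def mean_currents(self, exclude_burn_in: bool = True) -> dict:
        """Time-averaged current of each type per recorded neuron (mV/ms)."""
        sel = self.current_times >= self._epoch_start(exclude_burn_in)
        return {k: v[:, sel].mean(axis=1) for k, v in self.currents.items()}


class IntegrationError(RuntimeError):
    pass


def integrate(
    network: ConnectivityGraph,
    ffwd: SpikeRaster,
    duration: float,
    seed: int,
    dt: float = 0.05,
    current_dt: float = 10.0,
    n_record: int | None = None,
    params_e: EIFParams = E_PARAMS,
    params_i: EIFParams = I_PARAMS,
    ext_drive: np.ndarray | None = None,
    v_init: np.ndarray | None = None,
    spike_rate_cap: float = 150.0,
) -> SimulationResult:
    """Simulate the V4/MT network driven by a feedforward spike raster.

    Initial membrane potentials are uniform in [V_re, V_T] (from ``seed``).
    ``n_record`` limits current recording to the first ``n_record`` neurons
    (default: all excitatory neurons).  ``spike_rate_cap`` (Hz) sizes the
    spike buffer.
    """
    cfg = network.config
    n_e, n_i = cfg.n_e, cfg.n_i
    n = n_e + n_i
    if current_dt % dt > 1e-9 and abs(current_dt % dt - dt) > 1e-9:
        raise ValueError("dt must divide current_dt")
    if np.any(ffwd.times >= duration) or np.any(ffwd.times < 0):
        raise ValueError("feedforward spikes outside [0, duration)")
    n_steps = int(round(duration / dt))
    rec_every = int(round(current_dt / dt))
    n_record = n_e if n_record is None else min(n_record, n)
    n_samples = (n_steps + rec_every - 1) // rec_every

    rec_indptr, rec_post, rec_w = network.recurrent_csr()
    ff_indptr, ff_post, ff_w = network.ffwd_csr()
    ff_bins = np.round(ffwd.times / dt).astype(np.int64)
    ff_ids = ffwd.ids.astype(np.int64)

    rng = child_rng(seed, "v-init")
    if v_init is None:
        v_init = rng.uniform(params_e.V_re, params_e.V_T, size=n)
    V = np.array(v_init, dtype=np.float64)
    if ext_drive is None:
        ext_drive = np.zeros(n)

    cap = int(n * duration / 1000.0 * spike_rate_cap) + 1000
    spk_bins = np.empty(cap, dtype=np.int64)
    spk_ids = np.empty(cap, dtype=np.int32)
    cur_ff = np.zeros((n_record, n_samples), dtype=np.float64)
    cur_re = np.zeros((n_record, n_samples), dtype=np.float64)
    cur_ri = np.zeros((n_record, n_samples), dtype=np.float64)

    out = _integrate_kernel(
        n_e, n, dt, n_steps,
        params_e.tau_m, params_e.delta_T, int(round(params_e.tau_ref / dt)),
        params_i.tau_m, params_i.delta_T, int(round(params_i.tau_ref / dt)),
        params_e.E_L, params_e.V_T, params_e.V_th, params_e.V_re,
        np.exp(-dt / KERNEL_E.tau_r), np.exp(-dt / KERNEL_E.tau_d),
        np.exp(-dt / KERNEL_I.tau_r), np.exp(-dt / KERNEL_I.tau_d),
        np.exp(-dt / KERNEL_SLOW.tau_r), np.exp(-dt / KERNEL_SLOW.tau_d),
        P_FAST, P_SLOW,
        1.0 / (KERNEL_E.tau_d - KERNEL_E.tau_r),
        1.0 / (KERNEL_I.tau_d - KERNEL_I.tau_r),
        1.0 / (KERNEL_SLOW.tau_d - KERNEL_SLOW.tau_r),
        rec_indptr, rec_post, rec_w,
        ff_indptr, ff_post, ff_w,
        ff_bins, ff_ids,
        V, np.asarray(ext_drive, dtype=np.float64),
        rec_every if n_record > 0 else 0, n_record, cur_ff, cur_re, cur_ri,
        spk_bins, spk_ids,
    )
    n_spk, step, info = out
    if n_spk == -1:
        raise IntegrationError(f"spike buffer overflow at step {step}; "
                               f"raise spike_rate_cap")
    if n_spk == -2:
        raise IntegrationError(f"numerical blow-up at step {step}, neuron {info}")

    raster = SpikeRaster(times=spk_bins[:n_spk] * dt, ids=spk_ids[:n_spk],
                         n_neurons=n, duration=duration)
    return SimulationResult(
        spikes=raster, n_e=n_e, n_i=n_i, duration=duration, dt=dt,
        current_dt=current_dt,
        currents={"ff": np.asarray(cur_ff, dtype=np.float32),
                  "re": np.asarray(cur_re, dtype=np.float32),
                  "ri": np.asarray(cur_ri, dtype=np.float32)},
        seed=seed,
        meta={"variant": network.variant, "current_units": "I/C_m in mV/ms",
              "final_v": V},
    )
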