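"""Linear-nonlinear-Poisson V1 front end.

Each V1 neuron filters the (noisy) image at its population's location with a
Gabor receptive field at its own preferred orientation,

    r_i(t) = gain * [ sum_xy F_i(x, y) * (m(x, y) + noise_scale * xi(x, y, t)) ]_+

and emits spikes as an inhomogeneous Poisson process.  Neurons on the left
half of the domain ([0,1) in x) form population V1_1 with receptive fields on
image location 1 (center (0.5, 0.5)); the right half forms V1_2 (center
(1.5, 0.5)).

Calibration fixes two scale factors -- the rate ``gain`` and an effective
``noise_scale`` multiplying the OU noise -- so that, at the reference
contrast, the driven population's mean rate is 10 Hz while the mean rate with
noise alone (no image) is 5 Hz.  Spontaneous activity therefore arises
entirely from rectified responses to the pixel noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import brentq
from scipy.stats import norm

from .orientation_map import OrientationMap, generate_pinwheel_map
from .stimuli import (
    PATCH_SIDE,
    gabor_image,
    pixel_area,
    plaid_image,
)
from ._rng import child_seed

__all__ = [
    "SpikeRaster",
    "LocationStimulus",
    "Condition",
    "V1Population",
    "build_v1_population",
    "calibrate_gain",
    "poisson_spikes",
    "generate_v1_spikes",
    "natural_image_rates",
]


@dataclass
class SpikeRaster:
    """Spike times (ms) and neuron ids, sorted by time."""

    times: np.ndarray  # float64, ms, sorted
    ids: np.ndarray  # int32
    n_neurons: int
    duration: float  # ms
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.ids = np.asarray(self.ids, dtype=np.int32)

    def counts(self, t0: float = 0.0, t1: float | None = None) -> np.ndarray:
        """Spike count per neuron in the window [t0, t1)."""
        t1 = self.duration if t1 is None else t1
        sel = (self.times >= t0) & (self.times < t1)
        return np.bincount(self.ids[sel], minlength=self.n_neurons)

    def rates_hz(self, t0: float = 0.0, t1: float | None = None) -> np.ndarray:
        t1 = self.duration if t1 is None else t1
        return self.counts(t0, t1) / ((t1 - t0) / 1000.0)


# ---------------------------------------------------------------------------
# stimulus conditions

@dataclass
class LocationStimulus:
    """What is shown at one image location.

    kind:
      - "gabors": sum of Gabor components ``[(contrast, theta), ...]``
      - "none": no image; rectified noise gives the spontaneous rate
      - "flat": bypass the filter model, homogeneous Poisson at ``rate`` Hz
    """

    kind: str = "none"
    components: tuple = ()
    rate: float = 0.0

    @classmethod
    def gabors(cls, components) -> "LocationStimulus":
        return cls(kind="gabors", components=tuple(components))

    @classmethod
    def none(cls) -> "LocationStimulus":
        return cls(kind="none")

    @classmethod
    def flat(cls, rate: float) -> "LocationStimulus":
        return cls(kind="flat", rate=rate)


@dataclass
class Condition:
    """Stimulus at the two image locations."""

    loc1: LocationStimulus
    loc2: LocationStimulus
    name: str = ""

    @classmethod
    def images(cls, comps1=None, comps2=None, name: str = "") -> "Condition":
        l1 = LocationStimulus.gabors(comps1) if comps1 else LocationStimulus.none()
        l2 = LocationStimulus.gabors(comps2) if comps2 else LocationStimulus.none()
        return cls(l1, l2, name)


# ---------------------------------------------------------------------------
# population

RF_CENTERS = ((0.5, 0.5), (1.5, 0.5))


@dataclass
class V1Population:
    positions: np.ndarray  # (n, 2)
    theta: np.ndarray  # (n,)
    pop_id: np.ndarray  # (n,) 0 for V1_1, 1 for V1_2
    filters: list  # [F1 (n1, npix^2), F2 (n2, npix^2)] row-major flattened
    idx: list  # [idx1, idx2] global indices per population
    npix: int = 25
    sigma: float = 0.2
    lambda_wave: float = 0.6
    gain: float = np.nan  # Hz per filter-response unit
    noise_scale: float = np.nan  # multiplies the OU noise field
    tau_n: float = 40.0
    sigma_n: float = 3.5
    reference_contrast: float = 0.5

    @property
    def n_neurons(self) -> int:
        return self.theta.shape[0]

    @property
    def cell_area(self) -> float:
        return pixel_area(self.npix)

    def filter_noise_std(self, k: int) -> np.ndarray:
        """SD of the filtered OU noise (per unit noise_scale) for pop k."""
        stat = self.sigma_n / np.sqrt(2.0 * self.tau_n)
        return self.cell_area * np.linalg.norm(self.filters[k], axis=1) * stat

    def image_response(self, k: int, pixels: np.ndarray) -> np.ndarray:
        """Noise-free filter response of population k to a pixel patch."""
        if pixels.shape != (self.npix, self.npix):
            raise ValueError(
                f"patch shape {pixels.shape} does not match ({self.npix}, {self.npix})"
            )
        return self.cell_area * (self.filters[k] @ pixels.ravel(order="C"))

    def stimulus_pixels(self, k: int, stim: LocationStimulus) -> np.ndarray:
        if stim.kind == "gabors":
            return plaid_image(list(stim.components), RF_CENTERS[k],
                               self.sigma, self.lambda_wave, self.npix)
        return np.zeros((self.npix, self.npix))


def build_v1_population(
    omap: OrientationMap | None = None,
    grid: tuple[int, int] = (100, 50),
    seed: int = 0,
    npix: int = 25,
    sigma: float = 0.2,
    lambda_wave: float = 0.6,
) -> V1Population:
    """Build the V1 population from an orientation map (generated from
    ``seed`` if not given)."""
    if omap is None:
        omap = generate_pinwheel_map(grid, seed=child_seed(seed, "v1-map"))
    pos = omap.positions
    theta = omap.theta
    pop_id = (pos[:, 0] >= 1.0).astype(np.int32)
    filters = []
    idx = []
    for k in (0, 1):
        sel = np.flatnonzero(pop_id == k)
        F = np.empty((sel.size, npix * npix))
        for row, i in enumerate(sel):
            F[row] = gabor_image(1.0, RF_CENTERS[k], theta[i], sigma,
                                 lambda_wave, npix).pixels.ravel(order="C")
        filters.append(F)
        idx.append(sel)
    return V1Population(
        positions=pos, theta=theta, pop_id=pop_id, filters=filters, idx=idx,
        npix=npix, sigma=sigma, lambda_wave=lambda_wave,
    )


def v1_rates(pop: V1Population, patches: list[np.ndarray]) -> np.ndarray:
    """Instantaneous rates (Hz) of all V1 neurons for given noisy patches
    (one ``npix x npix`` pixel array per location, noise already included).
    Requires a calibrated population."""
    _require_calibrated(pop)
    r = np.empty(pop.n_neurons)
    for k in (0, 1):
        resp = pop.image_response(k, patches[k])
        r[pop.idx[k]] = pop.gain * np.maximum(resp, 0.0)
    return r


def _require_calibrated(pop: V1Population) -> None:
    if not np.isfinite(pop.gain) or not np.isfinite(pop.noise_scale):
        raise RuntimeError("V1 population is not calibrated; run calibrate_gain")


def calibrate_gain(
    pop: V1Population,
    reference_contrast: float = 0.5,
    theta_ref: float = 0.0,
    driven_target: float = 10.0,
    spontaneous_target: float = 5.0,
) -> tuple[float, float]:
    """Jointly calibrate ``gain`` and ``noise_scale`` (in place).

    Uses the closed form for the mean of a rectified Gaussian,
    E[(mu + s Z)_+] = mu * Phi(mu/s) + s * phi(mu/s), so that with the image
    at the reference contrast the driven population's mean rate equals the
    driven target and with noise alone it equals the spontaneous target.
    """
    if spontaneous_target <= 0 or driven_target <= spontaneous_target:
        raise ValueError("targets must satisfy 0 < spontaneous < driven")
    img = gabor_image(reference_contrast, RF_CENTERS[0], theta_ref,
                      pop.sigma, pop.lambda_wave, pop.npix)
    mu = pop.image_response(0, img.pixels)
    s_unit = pop.filter_noise_std(0)
    if not np.any(s_unit > 0):
        raise RuntimeError("calibration error: zero filtered-noise variance "
                           "(sigma_n = 0 makes spontaneous activity impossible)")
    ratio_target = driven_target / spontaneous_target

    def driven_mean(kappa: float) -> float:
        s = kappa * s_unit
        z = mu / s
        return float(np.mean(mu * norm.cdf(z) + s * norm.pdf(z)))

    def spont_mean(kappa: float) -> float:
        return float(kappa * np.mean(s_unit) / np.sqrt(2 * np.pi))

    def f(log_kappa: float) -> float:
        k = np.exp(log_kappa)
        return driven_mean(k) / spont_mean(k) - ratio_target

    lo, hi = np.log(1e-6), np.log(1e6)
    if f(lo) < 0 or f(hi) > 0:
        raise RuntimeError("calibration error: target rate ratio unattainable")
    log_kappa = brentq(f, lo, hi, xtol=1e-12)
    kappa = float(np.exp(log_kappa))
    gain = spontaneous_target / spont_mean(kappa)
    pop.gain = gain
    pop.noise_scale = kappa
    pop.reference_contrast = reference_contrast
    return gain, kappa


# ---------------------------------------------------------------------------
# Poisson spike generation

@njit(cache=True)
def _poisson_kernel(rates_khz, block_bins, dt, n_bins, seed, out_bins, out_ids):
    """Bernoulli thinning, one draw per neuron per dt bin, simulated exactly
    with geometric skips within each constant-rate block."""
    np.random.seed(seed)
    n_blocks, n = rates_khz.shape
    m = 0
    for blk in range(n_blocks):
        b0 = blk * block_bins
        b1 = min(b0 + block_bins, n_bins)
        if b1 <= b0:
            continue
        for i in range(n):
            p = rates_khz[blk, i] * dt
            if p <= 0.0:
                continue
            if p >= 1.0:
                raise ValueError("rate * dt >= 1; refine dt")
            log1mp = np.log(1.0 - p)
            pos = b0 - 1
            while True:
                u = np.random.random()
                pos += 1 + int(np.floor(np.log(u) / log1mp))
                if pos >= b1:
                    break
                out_bins[m] = pos
                out_ids[m] = i
                m += 1
    return m


def poisson_spikes(
    rates: np.ndarray,
    dt: float,
    duration: float,
    seed: int,
    block_dt: float | None = None,
) -> SpikeRaster:
    """Inhomogeneous Poisson spikes via per-bin Bernoulli thinning.

    ``rates`` is in Hz, either ``(n,)`` (constant) or ``(n_blocks, n)``
    piecewise constant on blocks of ``block_dt`` ms.  ``dt`` is the thinning
    bin (ms); spike times are bin times.
    """
    rates = np.asarray(rates, dtype=np.float64)
    if rates.ndim == 1:
        rates = rates[None, :]
        block_dt = duration
    if block_dt is None:
        raise ValueError("block_dt required for time-varying rates")
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    n_bins = int(round(duration / dt))
    block_bins = max(int(round(block_dt / dt)), 1)
    rates_khz = rates / 1000.0
    cap = int(rates.mean() / 1000.0 * duration * rates.shape[1] * 3 + 1000)
    out_bins = np.empty(cap, dtype=np.int64)
    out_ids = np.empty(cap, dtype=np.int32)
    m = _poisson_kernel(rates_khz, block_bins, dt, n_bins,
                        np.uint32(seed & 0x7FFFFFFF), out_bins, out_ids)
    order = np.argsort(out_bins[:m], kind="stable")
    return SpikeRaster(
        times=out_bins[:m][order] * dt,
        ids=out_ids[:m][order],
        n_neurons=rates.shape[1],
        duration=duration,
    )


def _segment_rates(pop, cond: Condition, xi_blocks: list, gain, kappa):
    """Rates (n_blocks, n_neurons) for one stimulus segment."""
    n_blocks = xi_blocks[0].shape[0]
    rates = np.empty((n_blocks, pop.n_neurons))
    for k, stim in enumerate((cond.loc1, cond.loc2)):
        cols = pop.idx[k]
        if stim.kind == "flat":
            rates[:, cols] = stim.rate
            continue
        base = pop.image_response(k, pop.stimulus_pixels(k, stim))
        proj = pop.cell_area * (xi_blocks[k] @ pop.filters[k].T)
        rates[:, cols] = gain * np.maximum(base[None, :] + kappa * proj, 0.0)
    return rates


def generate_v1_spikes(
    pop: V1Population,
    schedule,
    duration: float,
    seed: int,
    dt: float = 0.05,
    rate_dt: float = 2.0,
    burn_in_noise: float = 200.0,
) -> SpikeRaster:
    """Generate V1 spikes for a stimulus schedule.

    ``schedule`` is a :class:`Condition` (static stimulus) or a list of
    ``(t0, t1, Condition)`` segments covering ``[0, duration)``.  The OU pixel
    noise is evolved continuously on the ``rate_dt`` clock (exact OU
    discretization) and the rates are held constant within each ``rate_dt``
    block; Poisson spikes are drawn per ``dt`` bin.  ``burn_in_noise`` ms of
    noise evolution precede t = 0 so the noise starts stationary.
    """
    _require_calibrated(pop)
    if isinstance(schedule, Condition):
        schedule = [(0.0, duration, schedule)]
    rng = np.random.default_rng(child_seed(seed, "v1-noise"))
    npx = pop.npix
    a = np.exp(-rate_dt / pop.tau_n)
    stat = pop.sigma_n / np.sqrt(2 * pop.tau_n)
    b = stat * np.sqrt(1.0 - a * a)
    xi = [stat * rng.standard_normal((npx, npx)) for _ in (0, 1)]
    for _ in range(int(round(burn_in_noise / rate_dt))):
        for k in (0, 1):
            xi[k] = a * xi[k] + b * rng.standard_normal((npx, npx))

    n_blocks_total = int(round(duration / rate_dt))
    all_rates = np.empty((n_blocks_total, pop.n_neurons))
    for (t0, t1, cond) in schedule:
        b0 = int(round(t0 / rate_dt))
        b1 = int(round(t1 / rate_dt))
        nb = b1 - b0
        blocks = [np.empty((nb, npx * npx)) for _ in (0, 1)]
        for blk in range(nb):
            for k in (0, 1):
                xi[k] = a * xi[k] + b * rng.standard_normal((npx, npx))
                blocks[k][blk] = xi[k].ravel(order="C")
        all_rates[b0:b1] = _segment_rates(pop, cond, blocks, pop.gain,
                                          pop.noise_scale)
    return poisson_spikes(all_rates, dt, duration,
                          child_seed(seed, "v1-poisson"), block_dt=rate_dt)


# ---------------------------------------------------------------------------
# natural-image drive (manifold-capacity experiment)

def natural_image_rates(pop: V1Population, image: np.ndarray,
                        patch_pix: int = 15, mean_rate: float = 10.0) -> np.ndarray:
    """Mean V1 rates for a grayscale image tiled with stride-1 receptive fields.

    Each V1 neuron filters the ``patch_pix x patch_pix`` pixel patch at its
    grid position with its Gabor receptive field (sampled on the patch
    lattice); rates are rectified and normalized so the population mean is
    ``mean_rate`` Hz.  The image must have shape
    ``(ny + patch_pix - 1, nx + patch_pix - 1)`` for a ``(nx, ny)`` V1 grid.
    """
    xs = np.unique(pop.positions[:, 0])
    ys = np.unique(pop.positions[:, 1])
    nx, ny = xs.size, ys.size
    ny_img, nx_img = image.shape
    if (nx_img - patch_pix + 1, ny_img - patch_pix + 1) != (nx, ny):
        raise ValueError(
            f"image shape {image.shape} incompatible with V1 grid ({nx}, {ny})"
        )
    # Gabor filter on the patch lattice, one per neuron orientation
    filt = {  # cache by orientation value
    }
    col = np.searchsorted(xs, pop.positions[:, 0])
    row = np.searchsorted(ys, pop.positions[:, 1])
    rates = np.empty(pop.n_neurons)
    for i in range(pop.n_neurons):
        th = pop.theta[i]
        key = round(float(th), 9)
        F = filt.get(key)
        if F is None:
            F = gabor_image(1.0, (0.0, 0.0), th, pop.sigma, pop.lambda_wave,
                            patch_pix, side=PATCH_SIDE).pixels
            filt[key] = F
        patch = image[row[i]: row[i] + patch_pix, col[i]: col[i] + patch_pix]
        rates[i] = max(float((F * patch).sum()), 0.0)
    m = rates.mean()
    if m <= 0:
        raise ValueError("image evoked no positive filter responses")
    return rates * (mean_rate / m)
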