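"""End-to-end experiment recipes.

Builds the full model (orientation maps, calibrated V1 front end,
connectivity), runs the stimulus protocols, and returns analysis-ready
tables.  All randomness derives from one experiment seed through named
child seeds, so identical configurations reproduce identical results.

The reference protocol simulates the three stimulus conditions -- image 1
alone, image 2 alone, both images together -- with matched simulation seeds,
from which normalization indices, spike-count correlations and the current
covariance decomposition are computed.  Desk-scale runs shrink the network
(scale_factor < 1) and the number/duration of simulations proportionally.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import metrics
from .circuit import (
    ConnectivityGraph,
    NetworkConfig,
    NetworkLayout,
    build_layout,
    matched_indegree_network,
    random_network,
    sample_connections,
)
from .simulator import SimulationResult, integrate
from .v1 import (
    Condition,
    LocationStimulus,
    V1Population,
    build_v1_population,
    calibrate_gain,
    generate_v1_spikes,
    natural_image_rates,
    poisson_spikes,
)
from ._rng import child_seed

logger = logging.getLogger("normnet")

__all__ = [
    "ExperimentConfig",
    "Model",
    "build_model",
    "separated_conditions",
    "plaid_conditions",
    "run_condition",
    "run_normalization_experiment",
    "plaid_rotation_experiment",
    "contrast_experiment",
    "tuning_curve_experiment",
    "natural_image_responses",
    "make_fixtures",
]


@dataclass
class ExperimentConfig:
    """Reproducible description of one experiment run."""

    scale: float = 0.25
    variant: str = "default"
    seed: int = 0
    duration: float = 20000.0  # ms per simulation
    n_sims: int = 10
    contrast: float = 0.5
    theta1: float = 0.0
    theta2: float = float(np.pi / 2)
    stimulus_layout: str = "separated"  # or "superimposed"
    overlap: float = 1.0  # random-network control only

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Model:
    """Structural state shared by all conditions of one experiment."""

    net_config: NetworkConfig
    layout: NetworkLayout
    v1: V1Population
    seed: int
    graphs: dict = field(default_factory=dict)

    def graph(self, variant: str = "default") -> ConnectivityGraph:
        if variant not in self.graphs:
            t0 = time.perf_counter()
            if variant == "default":
                g = sample_connections(self.net_config, self.layout,
                                       child_seed(self.seed, "conn"))
            elif variant == "matched":
                g = matched_indegree_network(self.net_config, self.layout,
                                             child_seed(self.seed, "conn"))
            elif variant.startswith("random"):
                overlap = float(variant.split(":")[1]) if ":" in variant else 1.0
                g = random_network(self.net_config, overlap,
                                   child_seed(self.seed, "conn"), self.layout)
            else:
                raise ValueError(f"unknown variant {variant!r}")
            logger.info("built %s connectivity in %.1f s", variant,
                        time.perf_counter() - t0)
            self.graphs[variant] = g
        return self.graphs[variant]


def build_model(scale: float = 0.25, seed: int = 0,
                reference_contrast: float = 0.5) -> Model:
    """Build maps, the calibrated V1 population and the network layout."""
    cfg = NetworkConfig().scaled(scale) if scale != 1.0 else NetworkConfig()
    layout = build_layout(cfg, seed)
    pop = build_v1_population(layout.v1_map)
    gain, kappa = calibrate_gain(pop, reference_contrast=reference_contrast)
    logger.info("V1 calibration: gain=%.4g Hz/unit, noise_scale=%.4g",
                gain, kappa)
    return Model(net_config=cfg, layout=layout, v1=pop, seed=seed)


# ---------------------------------------------------------------------------
# stimulus conditions

def separated_conditions(contrast: float = 0.5, theta1: float = 0.0,
                         theta2: float = np.pi / 2) -> dict:
    """Two Gabor images of orthogonal orientations at separate locations."""
    return {
        "stim1": Condition.images([(contrast, theta1)], None, "stim1"),
        "stim2": Condition.images(None, [(contrast, theta2)], "stim2"),
        "both": Condition.images([(contrast, theta1)], [(contrast, theta2)],
                                 "both"),
    }


def plaid_conditions(contrast: float = 0.5, theta1: float = 0.0,
                     theta2: float = np.pi / 2) -> dict:
    """Superimposed (plaid) stimuli: each component is shown at both image
    locations, and the 'both' condition is the pixelwise plaid."""
    c1 = [(contrast, theta1)]
    c2 = [(contrast, theta2)]
    return {
        "stim1": Condition.images(c1, c1, "plaid-stim1"),
        "stim2": Condition.images(c2, c2, "plaid-stim2"),
        "both": Condition.images(c1 + c2, c1 + c2, "plaid-both"),
    }


def run_condition(model: Model, graph: ConnectivityGraph, cond: Condition,
                  duration: float, n_sims: int, seed: int,
                  n_record: int | None = None) -> list[SimulationResult]:
    """Simulate one stimulus condition ``n_sims`` times (fresh noise, spikes
    and initial state per simulation; fixed connectivity)."""
    out = []
    for s in range(n_sims):
        t0 = time.perf_counter()
        ff = generate_v1_spikes(model.v1, cond, duration,
                                seed=child_seed(seed, f"{cond.name}-v1-{s}"))
        res = integrate(graph, ff, duration,
                        seed=child_seed(seed, f"{cond.name}-net-{s}"),
                        n_record=n_record)
        logger.info("condition %s sim %d: %.1f s wall, mean E rate %.2f Hz",
                    cond.name or "?", s, time.perf_counter() - t0,
                    res.e_rates().mean())
        out.append(res)
    return out


def run_normalization_experiment(
    model: Model,
    variant: str = "default",
    duration: float = 20000.0,
    n_sims: int = 10,
    seed: int = 0,
    contrast: float = 0.5,
    theta1: float = 0.0,
    theta2: float = np.pi / 2,
    stimulus_layout: str = "separated",
) -> dict:
    """Three-condition protocol: returns per-condition results and the
    normalization table of the excitatory population."""
    maker = separated_conditions if stimulus_layout == "separated" \
        else plaid_conditions
    conds = maker(contrast, theta1, theta2)
    graph = model.graph(variant)
    results = {name: run_condition(model, graph, cond, duration, n_sims,
                                   child_seed(seed, name))
               for name, cond in conds.items()}
    table = metrics.normalization_table(results)
    return {"results": results, "table": table, "variant": variant}


def plaid_rotation_experiment(
    model: Model,
    variant: str = "default",
    rotation: float = np.pi / 4,
    duration: float = 10000.0,
    n_sims: int = 2,
    seed: int = 0,
    contrast: float = 0.5,
) -> dict:
    """Normalization indices with superimposed images at the base orientation
    pair and again with both orientations rotated; returns both index vectors
    and their Pearson correlation across units included in both."""
    base = run_normalization_experiment(
        model, variant, duration, n_sims, child_seed(seed, "plaid-base"),
        contrast, 0.0, np.pi / 2, stimulus_layout="superimposed")
    rot = run_normalization_experiment(
        model, variant, duration, n_sims, child_seed(seed, "plaid-rot"),
        contrast, rotation, np.pi / 2 + rotation,
        stimulus_layout="superimposed")
    tb, tr = base["table"], rot["table"]
    ok = (tb["include"] & tr["include"]).to_numpy()
    ni_b = tb["norm_index"].to_numpy()[ok]
    ni_r = tr["norm_index"].to_numpy()[ok]
    r = float(np.corrcoef(ni_b, ni_r)[0, 1])
    return {"base": base, "rotated": rot, "included": ok,
            "ni_base": ni_b, "ni_rotated": ni_r, "correlation": r}


def contrast_experiment(
    model: Model,
    deltas=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    variant: str = "default",
    duration: float = 10000.0,
    n_sims: int = 1,
    seed: int = 0,
    base_contrast: float = 0.5,
    theta1: float = 0.0,
    theta2: float = np.pi / 2,
) -> dict:
    """Contrast-difference sweep at fixed mean contrast: image 1 at
    base + dc, image 2 at base - dc.  Returns mean excitatory rates per dc."""
    graph = model.graph(variant)
    rates = {}
    for dc in deltas:
        cond = Condition.images([(base_contrast + dc, theta1)],
                                [(base_contrast - dc, theta2)], f"dc{dc:g}")
        rs = run_condition(model, graph, cond, duration, n_sims,
                           child_seed(seed, f"dc-{dc:g}"), n_record=0)
        rates[float(dc)] = np.mean([r.e_rates() for r in rs], axis=0)
    return {"rates_by_dc": rates}


def tuning_curve_experiment(
    model: Model,
    variant: str = "default",
    orientations: np.ndarray | None = None,
    duration: float = 4000.0,
    seed: int = 0,
    contrast: float = 0.5,
) -> np.ndarray:
    """Orientation tuning curves of excitatory units: mean rates for Gabor
    images at location 1, orientations 0..170 deg in 10-deg steps (18 points
    by default).  Returns (n_units, n_orientations)."""
    if orientations is None:
        orientations = np.arange(18) * np.pi / 18
    graph = model.graph(variant)
    curves = []
    for th in orientations:
        cond = Condition.images([(contrast, float(th))], None, f"ori{th:.3f}")
        rs = run_condition(model, graph, cond, duration, 1,
                           child_seed(seed, f"ori-{th:.4f}"), n_record=0)
        curves.append(rs[0].e_rates())
    return np.column_stack(curves)


def natural_image_responses(
    model: Model,
    images: np.ndarray,
    n_trials: int,
    variant: str = "default",
    window: float = 100.0,
    seed: int = 0,
    burn_in: float = 1000.0,
) -> np.ndarray:
    """Population responses to a set of images: (P, n_trials, N_e) spike
    counts in ``window``-ms windows.

    Each image drives the V1 grid through stride-1 Gabor receptive fields
    (rates normalized to a 10-Hz population mean); one continuous simulation
    per image provides the trials as consecutive windows after the burn-in.
    """
    graph = model.graph(variant)
    duration = burn_in + n_trials * window
    out = np.empty((images.shape[0], n_trials, model.net_config.n_e),
                   dtype=np.int64)
    for p in range(images.shape[0]):
        rates = natural_image_rates(model.v1, images[p])
        ff = poisson_spikes(rates, 0.05, duration,
                            child_seed(seed, f"nat-v1-{p}"))
        res = integrate(graph, ff, duration,
                        seed=child_seed(seed, f"nat-net-{p}"), n_record=0)
        sel = res.spikes.ids < res.n_e
        t = res.spikes.times[sel] - burn_in
        ids = res.spikes.ids[sel]
        keep = (t >= 0) & (t < n_trials * window)
        w = (t[keep] // window).astype(np.int64)
        cnt = np.zeros((n_trials, res.n_e), dtype=np.int64)
        np.add.at(cnt, (w, ids[keep]), 1)
        out[p] = cnt
    return out


def make_fixtures(seed: int = 0, scale: float = 0.02,
                  duration: float = 2000.0) -> dict:
    """Tiny end-to-end bundle for fast tests: a few-hundred-neuron network,
    2-s simulations of the three conditions, and the normalization table."""
    model = build_model(scale=scale, seed=seed)
    exp = run_normalization_experiment(model, duration=duration, n_sims=1,
                                       seed=child_seed(seed, "fixture"))
    return {"model": model, **exp}
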