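"""V4/MT network connectivity.

Connections are of two kinds.  Local connections are drawn from a
distance-dependent probability, p_ab(x1, x2) = pbar_ab * g(x1 - x2; sigma_b),
where g is a wrapped Gaussian periodic on the domain Gamma = [0,2] x [0,1].
For the excitatory projections onto excitatory neurons (recurrent E->E and
feedforward V1->E) a fraction (15%) of each neuron's out-degree is instead
long range: targets drawn uniformly from similarly tuned neurons,
cos(theta_i - theta_j) >= 0.6, independent of distance.  Inhibitory
projections and all projections onto inhibitory neurons are purely spatial.

Each presynaptic neuron makes exactly its configured out-degree of synapses,
sampled with replacement (multiple contacts onto one target are allowed and
stored as repeated edges).  Synaptic weights are J_ab / sqrt(N) with
N = N_e + N_i, so that single-synapse amplitudes stay physiological (about
0.5 mV for J_ee = 80 mV at the full network size) and the network operates in
the balanced regime.

Variants: the default spatial network, a matched-in-degree control in which
every neuron receives exactly the population-mean number of inputs of each
type, and a disordered (Erdos-Renyi) control whose two feedforward source
populations share a configurable fraction of their targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .orientation_map import GAMMA, generate_pinwheel_map
from ._rng import child_rng, child_seed

__all__ = [
    "NetworkConfig",
    "NetworkLayout",
    "ConnectivityGraph",
    "wrapped_gaussian",
    "build_layout",
    "sample_connections",
    "matched_indegree_network",
    "random_network",
]

PROJECTIONS = ("ee", "ie", "ei", "ii", "eF", "iF")
#: projection type -> (source population, target population)
PROJ_POPS = {
    "ee": ("e", "e"), "ie": ("e", "i"),
    "ei": ("i", "e"), "ii": ("i", "i"),
    "eF": ("F", "e"), "iF": ("F", "i"),
}


@dataclass
class NetworkConfig:
    """All structural parameters of the V4/MT layer (full scale defaults)."""

    grid_e: tuple[int, int] = (200, 100)
    grid_i: tuple[int, int] = (100, 50)
    grid_f: tuple[int, int] = (100, 50)
    weights_mv: dict = field(default_factory=lambda: {
        "ee": 80.0, "ei": -240.0, "ie": 40.0, "ii": -300.0,
        "eF": 160.0, "iF": 140.0,
    })
    pbar: dict = field(default_factory=lambda: {
        "ee": 0.01, "ei": 0.04, "ie": 0.03, "ii": 0.04,
        "eF": 0.05, "iF": 0.05,
    })
    sigma_e: float = 0.2
    sigma_i: float = 0.2
    sigma_ffwd: float = 0.1
    long_range_fraction: float = 0.15
    tuning_threshold: float = 0.6
    orientation_doubling: bool = False
    k_trunc: int = 5
    scale_factor: float = 1.0
    lambda_col: float = 0.125
    n_waves: int = 30

    @property
    def n_e(self) -> int:
        return self.grid_e[0] * self.grid_e[1]

    @property
    def n_i(self) -> int:
        return self.grid_i[0] * self.grid_i[1]

    @property
    def n_f(self) -> int:
        return self.grid_f[0] * self.grid_f[1]

    def n_pop(self, p: str) -> int:
        return {"e": self.n_e, "i": self.n_i, "F": self.n_f}[p]

    def k_out(self, proj: str) -> int:
        """Out-degree of a source neuron for a projection type:
        K_ab = pbar_ab * N_a (number of targets per source)."""
        src, tgt = PROJ_POPS[proj]
        return int(round(self.pbar[proj] * self.n_pop(tgt)))

    def k_in(self, proj: str) -> int:
        """Population-mean in-degree: pbar_ab * N_b."""
        src, tgt = PROJ_POPS[proj]
        return int(round(self.pbar[proj] * self.n_pop(src)))

    def sigma(self, proj: str) -> float:
        src, _ = PROJ_POPS[proj]
        return {"e": self.sigma_e, "i": self.sigma_i, "F": self.sigma_ffwd}[src]

    def weight(self, proj: str) -> float:
        """Effective synaptic weight J_ab / sqrt(N_e + N_i), in mV."""
        return self.weights_mv[proj] / np.sqrt(self.n_e + self.n_i)

    def scaled(self, s: float) -> "NetworkConfig":
        """Desk-scale variant: population sizes shrink by ~s (grid axes by
        sqrt(s)); pbar and J are unchanged, so out-degrees shrink by s and the
        per-synapse weight grows as 1/sqrt(N)."""
        if s <= 0:
            raise ValueError("scale factor must be positive")
        r = np.sqrt(s)

        def sg(grid):
            ny = max(int(round(grid[1] * r)), 2)
            return (grid[0] // grid[1] * ny, ny)

        return replace(self, grid_e=sg(self.grid_e), grid_i=sg(self.grid_i),
                       grid_f=sg(self.grid_f), scale_factor=self.scale_factor * s)

    def similarity(self, th_a, th_b):
        d = np.asarray(th_a) - np.asarray(th_b)
        return np.cos(2 * d) if self.orientation_doubling else np.cos(d)


@dataclass
class NetworkLayout:
    """Positions and preferred orientations of every neuron.

    The E and I grids sample one continuous V4/MT pinwheel field; the V1 map
    is generated independently.
    """

    config: NetworkConfig
    seed: int
    pos_e: np.ndarray
    theta_e: np.ndarray
    pos_i: np.ndarray
    theta_i: np.ndarray
    pos_f: np.ndarray
    theta_f: np.ndarray
    v1_map: object = None  # OrientationMap used for theta_f

    def pop(self, p: str) -> tuple[np.ndarray, np.ndarray]:
        return {
            "e": (self.pos_e, self.theta_e),
            "i": (self.pos_i, self.theta_i),
            "F": (self.pos_f, self.theta_f),
        }[p]

    def grid(self, p: str) -> tuple[int, int]:
        c = self.config
        return {"e": c.grid_e, "i": c.grid_i, "F": c.grid_f}[p]


def build_layout(config: NetworkConfig, seed: int) -> NetworkLayout:
    """Generate the V4/MT and V1 orientation maps and all grid positions."""
    rng = child_rng(seed, "map-v4")
    signs = rng.choice([-1.0, 1.0], size=config.n_waves)
    phases = rng.uniform(0, 2 * np.pi, size=config.n_waves)
    map_e = generate_pinwheel_map(config.grid_e, config.lambda_col,
                                  config.n_waves, seed=0, signs=signs,
                                  phases=phases)
    map_i = generate_pinwheel_map(config.grid_i, config.lambda_col,
                                  config.n_waves, seed=0, signs=signs,
                                  phases=phases)
    map_f = generate_pinwheel_map(config.grid_f, config.lambda_col,
                                  config.n_waves, seed=child_seed(seed, "map-v1"))
    return NetworkLayout(
        config=config, seed=seed,
        pos_e=map_e.positions, theta_e=map_e.theta,
        pos_i=map_i.positions, theta_i=map_i.theta,
        pos_f=map_f.positions, theta_f=map_f.theta,
        v1_map=map_f,
    )


def wrapped_gaussian(dx, dy, sigma: float, k_trunc: int = 5):
    """Wrapped-Gaussian connection density on Gamma (periods 2 in x, 1 in y).

    g(dx, dy) = [1/(2 pi sigma^2)] * sum_k exp(-(dx + 2k)^2 / (2 sigma^2))
                                   * sum_k exp(-(dy + k)^2 / (2 sigma^2))

    truncated at |k| <= k_trunc (error < 1e-12 for sigma <= 0.2).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    ks = np.arange(-k_trunc, k_trunc + 1)
    sx = np.exp(-(dx[..., None] + GAMMA[0] * ks) ** 2 / (2 * sigma**2)).sum(axis=-1)
    sy = np.exp(-(dy[..., None] + GAMMA[1] * ks) ** 2 / (2 * sigma**2)).sum(axis=-1)
    return sx * sy / (2 * np.pi * sigma**2)


@dataclass
class ConnectivityGraph:
    """Edge lists per projection type, with multiplicity.

    ``edges[proj] = (pre, post, long_range)`` with local (per-population)
    indices; repeated (pre, post) pairs encode multiple synaptic contacts.
    """

    config: NetworkConfig
    variant: str
    seed: int
    edges: dict

    def out_degrees(self, proj: str) -> np.ndarray:
        src, _ = PROJ_POPS[proj]
        pre, _, _ = self.edges[proj]
        return np.bincount(pre, minlength=self.config.n_pop(src))

    def in_degrees(self, proj: str) -> np.ndarray:
        _, tgt = PROJ_POPS[proj]
        _, post, _ = self.edges[proj]
        return np.bincount(post, minlength=self.config.n_pop(tgt))

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for proj, (pre, post, lr) in self.edges.items():
            parts.append(pd.DataFrame({
                "pre": pre, "post": post, "type": proj,
                "long_range": lr.astype(bool),
            }))
        return pd.concat(parts, ignore_index=True)

    def save(self, path: str) -> None:
        self.to_frame().to_parquet(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, config: NetworkConfig,
                   variant: str = "loaded", seed: int = -1) -> "ConnectivityGraph":
        edges = {}
        for proj, g in df.groupby("type"):
            edges[proj] = (
                g["pre"].to_numpy(np.int64),
                g["post"].to_numpy(np.int64),
                g["long_range"].to_numpy(bool),
            )
        return cls(config=config, variant=variant, seed=seed, edges=edges)

    # -- arrays for the simulator ------------------------------------------
    def _csr(self, projs, n_src, offsets_src, offsets_tgt):
        cfg = self.config
        pres, posts, ws = [], [], []
        for proj in projs:
            pre, post, _ = self.edges[proj]
            src, tgt = PROJ_POPS[proj]
            pres.append(pre + offsets_src[src])
            posts.append(post + offsets_tgt[tgt])
            ws.append(np.full(pre.shape[0], cfg.weight(proj), dtype=np.float64))
        pre = np.concatenate(pres)
        post = np.concatenate(posts)
        w = np.concatenate(ws)
        order = np.argsort(pre, kind="stable")
        post = post[order].astype(np.int32)
        w = w[order]
        counts = np.bincount(pre, minlength=n_src)
        indptr = np.zeros(n_src + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        return indptr, post, w

    def recurrent_csr(self):
        """CSR over recurrent sources (E then I, global ids 0..N_e+N_i)."""
        cfg = self.config
        off = {"e": 0, "i": cfg.n_e}
        return self._csr(("ee", "ie", "ei", "ii"), cfg.n_e + cfg.n_i,
                         {"e": 0, "i": cfg.n_e, "F": 0}, off)

    def ffwd_csr(self):
        """CSR over V1 sources (0..N_F)."""
        cfg = self.config
        return self._csr(("eF", "iF"), cfg.n_f, {"F": 0},
                         {"e": 0, "i": cfg.n_e})


# ---------------------------------------------------------------------------
# samplers

def _nearest_grid_index(x, y, grid):
    nx, ny = grid
    ix = np.minimum((x / (GAMMA[0] / nx)).astype(np.int64), nx - 1)
    iy = np.minimum((y / (GAMMA[1] / ny)).astype(np.int64), ny - 1)
    return iy * nx + ix


def _spatial_draws(rng, anchor_pos, k, grid, sigma):
    """For each anchor, draw k partners from the wrapped Gaussian centered on
    it, mapped to the nearest neuron of the partner grid."""
    m = anchor_pos.shape[0]
    off = rng.normal(0.0, sigma, size=(m, k, 2))
    x = np.mod(anchor_pos[:, 0, None] + off[:, :, 0], GAMMA[0])
    y = np.mod(anchor_pos[:, 1, None] + off[:, :, 1], GAMMA[1])
    return _nearest_grid_index(x, y, grid)


def _tuned_draws(rng, anchor_theta, k, partner_theta, config):
    """For each anchor, draw k partners uniformly from the similarly tuned
    set {j : similarity(theta_anchor, theta_j) >= threshold}."""
    thr = config.tuning_threshold
    delta = np.arccos(thr)
    order = np.argsort(partner_theta, kind="stable")
    st = partner_theta[order]
    n = st.size
    if config.orientation_doubling:
        half = delta / 2.0
        st2 = np.concatenate([st, st + np.pi])
        center = np.where(anchor_theta < half, anchor_theta + np.pi, anchor_theta)
        lo = np.searchsorted(st2, center - half, side="left")
        hi = np.searchsorted(st2, center + half, side="right")
        if np.any(hi <= lo):
            raise ValueError("empty similarly-tuned candidate set")
        draws = lo[:, None] + (rng.random((anchor_theta.size, k))
                               * (hi - lo)[:, None]).astype(np.int64)
        return order[draws % n]
    lo = np.searchsorted(st, anchor_theta - delta, side="left")
    hi = np.searchsorted(st, anchor_theta + delta, side="right")
    if np.any(hi <= lo):
        raise ValueError("empty similarly-tuned candidate set")
    draws = lo[:, None] + (rng.random((anchor_theta.size, k))
                           * (hi - lo)[:, None]).astype(np.int64)
    return order[draws]


def _edges_from_draws(n_anchor, partner_idx_local, lr_count, anchors_are_pre):
    k = partner_idx_local.shape[1]
    anchor = np.repeat(np.arange(n_anchor), k)
    partner = partner_idx_local.ravel()
    lr = np.zeros(n_anchor * k, dtype=bool)
    if lr_count:
        lr_mask = np.zeros(k, dtype=bool)
        lr_mask[k - lr_count:] = True  # last lr_count draws are long-range
        lr = np.tile(lr_mask, n_anchor)
    if anchors_are_pre:
        return anchor, partner, lr
    return partner, anchor, lr


def _sample_projection(rng, config, layout, proj, anchors_are_pre=True,
                       k_override=None):
    src, tgt = PROJ_POPS[proj]
    if anchors_are_pre:
        anchor_pop, partner_pop = src, tgt
        k = config.k_out(proj)
    else:
        anchor_pop, partner_pop = tgt, src
        k = config.k_in(proj)
    if k_override is not None:
        k = k_override
    anchor_pos, anchor_theta = layout.pop(anchor_pop)
    partner_pos, partner_theta = layout.pop(partner_pop)
    tuned = proj in ("ee", "eF")
    n_lr = int(round(config.long_range_fraction * k)) if tuned else 0
    n_local = k - n_lr
    parts = []
    if n_local:
        parts.append(_spatial_draws(rng, anchor_pos, n_local,
                                    layout.grid(partner_pop), config.sigma(proj)))
    if n_lr:
        parts.append(_tuned_draws(rng, anchor_theta, n_lr, partner_theta, config))
    draws = np.concatenate(parts, axis=1)
    return _edges_from_draws(anchor_pos.shape[0], draws, n_lr, anchors_are_pre)


def sample_connections(config: NetworkConfig, layout: NetworkLayout,
                       seed: int) -> ConnectivityGraph:
    """Default network: every source neuron makes exactly K_out synapses per
    projection type; 15% of E->E and V1->E synapses are long-range tuned."""
    edges = {}
    for proj in PROJECTIONS:
        rng = child_rng(seed, f"conn-{proj}")
        edges[proj] = _sample_projection(rng, config, layout, proj,
                                         anchors_are_pre=True)
    return ConnectivityGraph(config=config, variant="default", seed=seed,
                             edges=edges)


def matched_indegree_network(config: NetworkConfig, layout: NetworkLayout,
                             seed: int) -> ConnectivityGraph:
    """Control network with identical in-degrees: every neuron receives
    exactly the population-mean number of inputs of each type, drawn from the
    same spatial / tuning distributions; out-degrees are free."""
    edges = {}
    for proj in PROJECTIONS:
        rng = child_rng(seed, f"matched-{proj}")
        edges[proj] = _sample_projection(rng, config, layout, proj,
                                         anchors_are_pre=False)
    return ConnectivityGraph(config=config, variant="matched", seed=seed,
                             edges=edges)


def random_network(config: NetworkConfig, overlap: float, seed: int,
                   layout: NetworkLayout | None = None) -> ConnectivityGraph:
    """Disordered control: no spatial or tuning dependence.  The two V1
    source populations project to target sets sharing fraction ``overlap``
    of their members (1 = identical sets, 0 = disjoint halves)."""
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be in [0, 1]")
    edges = {}
    for proj in ("ee", "ie", "ei", "ii"):
        rng = child_rng(seed, f"rand-{proj}")
        src, tgt = PROJ_POPS[proj]
        n_src, n_tgt = config.n_pop(src), config.n_pop(tgt)
        k = config.k_out(proj)
        draws = rng.integers(0, n_tgt, size=(n_src, k))
        edges[proj] = _edges_from_draws(n_src, draws, 0, True)
    n_f = config.n_f
    if layout is not None:
        f_pop = (layout.pos_f[:, 0] >= GAMMA[0] / 2).astype(int)
    else:
        f_pop = (np.arange(n_f) >= n_f // 2).astype(int)
    for proj in ("eF", "iF"):
        rng = child_rng(seed, f"rand-{proj}")
        src, tgt = PROJ_POPS[proj]
        n_tgt = config.n_pop(tgt)
        k = config.k_out(proj)
        size = max(int(round(n_tgt / (2.0 - overlap))), 1)
        perm = rng.permutation(n_tgt)
        sets = [perm[:size], perm[n_tgt - size:]]
        draws = np.empty((n_f, k), dtype=np.int64)
        for p in (0, 1):
            rows = np.flatnonzero(f_pop == p)
            pool = sets[p]
            draws[rows] = pool[rng.integers(0, pool.size, size=(rows.size, k))]
        edges[proj] = _edges_from_draws(n_f, draws, 0, True)
    return ConnectivityGraph(config=config, variant=f"random-{overlap}",
                             seed=seed, edges=edges)
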