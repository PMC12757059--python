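"""Pinwheel orientation-preference maps.

Preferred orientations are assigned from the complex field

    z(x, y) = sum_{j=0}^{n-1} exp( i (2*pi/Lambda) * l_j *
                                   [cos(j*pi/n) x + sin(j*pi/n) y] + i*phi_j )

a superposition of ``n`` plane waves with random signs ``l_j = +/-1`` and
uniform phases ``phi_j``.  The preferred orientation is half the complex
argument, ``theta = arg(z)/2`` wrapped into [0, pi), which produces the
characteristic pinwheel layout with average column spacing ``Lambda``.

The domain is the rectangle Gamma = [0, 2] x [0, 1] shared by every layer of
the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GAMMA",
    "OrientationMap",
    "uniform_grid",
    "generate_pinwheel_map",
]

#: Extent of the model domain Gamma: (width in x, height in y).
GAMMA = (2.0, 1.0)


def uniform_grid(nx: int, ny: int) -> np.ndarray:
    """Cell-centered uniform grid of ``nx * ny`` positions covering Gamma.

    Returns an ``(nx*ny, 2)`` array of (x, y) positions, x varying fastest.
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be positive")
    x = (np.arange(nx) + 0.5) * (GAMMA[0] / nx)
    y = (np.arange(ny) + 0.5) * (GAMMA[1] / ny)
    xx, yy = np.meshgrid(x, y, indexing="xy")
    return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class OrientationMap:
    """Preferred orientation for every position of a uniform grid on Gamma."""

    positions: np.ndarray  # (n, 2)
    theta: np.ndarray  # (n,), radians in [0, pi)
    lambda_col: float
    n_waves: int
    seed: int
    grid_shape: tuple[int, int] = field(default=(0, 0))  # (nx, ny)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.positions.shape[0] != self.theta.shape[0]:
            raise ValueError("positions and theta must have the same length")

    def __len__(self) -> int:
        return self.theta.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Columnar (x, y, theta) table."""
        return pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "theta": self.theta,
            }
        )

    def to_array(self) -> np.ndarray:
        """Dense (ny, nx) array of orientations."""
        nx, ny = self.grid_shape
        if nx * ny != len(self):
            raise ValueError("grid_shape inconsistent with number of positions")
        return self.theta.reshape(ny, nx)

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str, lambda_col: float = np.nan, n_waves: int = 0,
             seed: int = -1) -> "OrientationMap":
        df = pd.read_csv(path)
        return cls(
            positions=df[["x", "y"]].to_numpy(),
            theta=df["theta"].to_numpy(),
            lambda_col=lambda_col,
            n_waves=n_waves,
            seed=seed,
        )


def generate_pinwheel_map(
    grid: np.ndarray | tuple[int, int],
    lambda_col: float = 0.125,
    n_waves: int = 30,
    seed: int = 0,
    *,
    signs: np.ndarray | None = None,
    phases: np.ndarray | None = None,
) -> OrientationMap:
    """Generate a pinwheel orientation map over a uniform grid.

    Parameters
    ----------
    grid
        Either an ``(n, 2)`` position array or a ``(nx, ny)`` grid shape,
        expanded with :func:`uniform_grid`.
    lambda_col
        Average orientation-column spacing (domain units, default 0.125).
    n_waves
        Number of superposed plane waves (default 30).
    seed
        Seed for the random wave signs and phases.
    signs, phases
        Optional explicit wave parameters (arrays of length ``n_waves``);
        override the seeded draws.  Mainly for tests of degenerate cases.
    """
    if lambda_col <= 0:
        raise ValueError("lambda_col must be positive")
    if n_waves < 1:
        raise ValueError("n_waves must be >= 1")

    grid_shape = (0, 0)
    if isinstance(grid, tuple):
        grid_shape = grid
        positions = uniform_grid(*grid)
    else:
        positions = np.asarray(grid, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 2 or positions.shape[0] == 0:
            raise ValueError("grid must be a nonempty (n, 2) position array")

    rng = np.random.default_rng(seed)
    if signs is None:
        signs = rng.choice([-1.0, 1.0], size=n_waves)
    if phases is None:
        phases = rng.uniform(0.0, 2 * np.pi, size=n_waves)
    signs = np.asarray(signs, dtype=float)
    phases = np.asarray(phases, dtype=float)

    j = np.arange(n_waves)
    # wave vectors k_j = (2*pi/Lambda) * l_j * (cos(j*pi/n), sin(j*pi/n))
    kx = (2 * np.pi / lambda_col) * signs * np.cos(j * np.pi / n_waves)
    ky = (2 * np.pi / lambda_col) * signs * np.sin(j * np.pi / n_waves)
    phase = positions[:, :1] * kx[None, :] + positions[:, 1:2] * ky[None, :] + phases[None, :]
    z = np.exp(1j * phase).sum(axis=1)
    theta = np.mod(np.angle(z), 2 * np.pi) / 2.0  # orientation = arg(z)/2 in [0, pi)
    theta = np.mod(theta, np.pi)
    return OrientationMap(
        positions=positions,
        theta=theta,
        lambda_col=lambda_col,
        n_waves=n_waves,
        seed=seed,
        grid_shape=grid_shape,
    )
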