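"""Visual stimuli: Gabor images, plaids, Ornstein-Uhlenbeck pixel noise,
contrast grids and synthetic natural-image stand-ins.

A Gabor image of contrast ``c`` centered at ``(x_k, y_k)`` is

    m(x, y) = c * exp(-[(x-x_k)^2 + (y-y_k)^2] / (2 sigma^2))
                * cos((2 pi / lambda) [(x-x_k) cos(theta) + (y-y_k) sin(theta)])

sampled on a 25 x 25 pixel lattice spanning a square patch of side 0.5 domain
units centered on the image (about +/-1.25 envelope SDs).  Every pixel is
corrupted by an independent OU process

    tau_n dxi = -xi dt + sigma_n dW

with tau_n = 40 ms and sigma_n = 3.5, giving stationary per-pixel variance
sigma_n^2 / (2 tau_n).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "PATCH_SIDE",
    "GaborImage",
    "NoiseField",
    "gabor_image",
    "plaid_image",
    "evolve_noise",
    "contrast_grid",
    "delta_contrast_conditions",
    "synthetic_natural_images",
]

#: Side length (domain units) of the square pixel patch of one image.
PATCH_SIDE = 0.5


def pixel_lattice(center: tuple[float, float], npix: int = 25,
                  side: float = PATCH_SIDE) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) coordinates of the pixel lattice: ``npix`` points per axis,
    inclusive of the patch edges, so the central pixel sits exactly on the
    image center when ``npix`` is odd."""
    if npix < 1:
        raise ValueError("npix must be >= 1")
    half = side / 2.0
    x = np.linspace(center[0] - half, center[0] + half, npix)
    y = np.linspace(center[1] - half, center[1] + half, npix)
    xx, yy = np.meshgrid(x, y, indexing="xy")
    return xx, yy


def pixel_area(npix: int = 25, side: float = PATCH_SIDE) -> float:
    """Quadrature cell area of the pixel lattice."""
    h = side / (npix - 1) if npix > 1 else side
    return h * h


@dataclass
class GaborImage:
    pixels: np.ndarray  # (npix, npix)
    contrast: float
    center: tuple[float, float]
    theta: float
    sigma: float = 0.2
    lambda_wave: float = 0.6

    @property
    def npix(self) -> int:
        return self.pixels.shape[0]


def gabor_image(
    c: float,
    center: tuple[float, float],
    theta: float,
    sigma: float = 0.2,
    lambda_wave: float = 0.6,
    npix: int = 25,
    side: float = PATCH_SIDE,
) -> GaborImage:
    """Gabor image of contrast ``c >= 0`` at orientation ``theta``."""
    if c < 0:
        raise ValueError("contrast must be nonnegative")
    if npix < 1:
        raise ValueError("npix must be >= 1")
    xx, yy = pixel_lattice(center, npix, side)
    dx = xx - center[0]
    dy = yy - center[1]
    envelope = np.exp(-(dx**2 + dy**2) / (2 * sigma**2))
    carrier = np.cos((2 * np.pi / lambda_wave) * (dx * np.cos(theta) + dy * np.sin(theta)))
    return GaborImage(
        pixels=c * envelope * carrier,
        contrast=c,
        center=center,
        theta=theta,
        sigma=sigma,
        lambda_wave=lambda_wave,
    )


def plaid_image(components: list[tuple[float, float]],
                center: tuple[float, float],
                sigma: float = 0.2, lambda_wave: float = 0.6,
                npix: int = 25, side: float = PATCH_SIDE) -> np.ndarray:
    """Pixelwise sum of Gabor components ``[(contrast, theta), ...]`` at one
    center.  No clipping is applied."""
    pix = np.zeros((npix, npix))
    for c, th in components:
        pix += gabor_image(c, center, th, sigma, lambda_wave, npix, side).pixels
    return pix


@dataclass
class NoiseField:
    """Per-pixel OU noise state."""

    xi: np.ndarray
    tau_n: float = 40.0  # ms
    sigma_n: float = 3.5
    dt: float = 0.05  # ms

    @property
    def stationary_std(self) -> float:
        return self.sigma_n / np.sqrt(2.0 * self.tau_n)


def evolve_noise(state: NoiseField, n_steps: int, seed: int | np.random.Generator = 0,
                 record: bool = False) -> NoiseField | tuple[NoiseField, np.ndarray]:
    """Euler-Maruyama integration of the OU pixel noise.

    xi <- xi + (-xi/tau_n) dt + (sigma_n/tau_n) sqrt(dt) N(0, 1), independently
    per pixel.  With ``record=True`` also returns the trajectory of shape
    ``(n_steps,) + xi.shape``.
    """
    if state.dt <= 0:
        raise ValueError("dt must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xi = np.array(state.xi, dtype=float)
    a = state.dt / state.tau_n
    b = (state.sigma_n / state.tau_n) * np.sqrt(state.dt)
    traj = np.empty((n_steps,) + xi.shape) if record else None
    for k in range(n_steps):
        xi = xi - a * xi + b * rng.standard_normal(xi.shape)
        if record:
            traj[k] = xi
    out = NoiseField(xi=xi, tau_n=state.tau_n, sigma_n=state.sigma_n, dt=state.dt)
    return (out, traj) if record else out


def contrast_grid(c1_values, c2_values) -> list[tuple[float, float]]:
    """Cartesian product of contrasts for image 1 and image 2."""
    c1_values = list(c1_values)
    c2_values = list(c2_values)
    if not c1_values or not c2_values:
        raise ValueError("contrast value lists must be nonempty")
    if any(c < 0 for c in c1_values + c2_values):
        raise ValueError("contrasts must be nonnegative")
    return list(product(c1_values, c2_values))


def delta_contrast_conditions(deltas=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
                              base: float = 0.5) -> list[tuple[float, float]]:
    """Conditions c1 = base + dc, c2 = base - dc (mean contrast fixed)."""
    return [(base + d, base - d) for d in deltas]


def synthetic_natural_images(n_images: int = 50, shape: tuple[int, int] = (64, 114),
                             seed: int = 0, scale: float = 0.5) -> np.ndarray:
    """Grayscale image set with 1/f-like spatial statistics.

    Synthetic stand-in for a natural photograph collection: spectrally shaped
    Gaussian noise whose radially averaged power spectrum falls off
    approximately as 1/f^2, rescaled per image to the range
    ``[-scale, scale]`` so intensities are commensurate with Gabor contrasts.
    Returns an array of shape ``(n_images,) + shape``.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    f = np.sqrt(fx**2 + fy**2)
    f[0, 0] = np.inf  # zero the DC component
    amp = 1.0 / f  # power ~ 1/f^2
    images = np.empty((n_images, ny, nx))
    for k in range(n_images):
        white = rng.standard_normal((ny, nx))
        img = np.fft.ifft2(np.fft.fft2(white) * amp).real
        img -= img.mean()
        peak = np.abs(img).max()
        images[k] = img / peak * scale if peak > 0 else img
    return images
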