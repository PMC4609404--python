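"""Phantom generation and fan-beam measurement simulation.

The measurement model is the usual transmission-CT photon model: for ray
``i`` with true line integral ``l_i = [A mu]_i`` the detector records

    y_i ~ Poisson(b_i * exp(-l_i) + r_i)

with entrance intensity ``b_i`` and read-out noise mean ``r_i``.  The
log-transformed measurement is ``l_hat_i = ln(b_i / (y_i - r_i))`` and the
statistical weight used by the penalized weighted-least-squares
reconstructions is ``omega_i = (y_i - r_i)**2 / y_i``.

The reproduction experiments follow the convention of additive zero-mean
Gaussian noise applied directly to each line integral, with a standard
deviation equal to a stated percentage of that ray's noiseless value
(``noise_level`` as a fraction, e.g. 0.002 for "0.2% noise"); the exit
intensities and weights are then derived from the noisy integrals.  Poisson
resampling of the photon counts is available as an optional mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScanGeometry, SystemMatrix, build_system_matrix, forward_project

__all__ = ["Sinogram", "make_shepp_logan", "simulate_scan", "statistical_weights"]


# Standard (Toft-modified) Shepp-Logan head phantom: ten ellipses given as
# (additive value, semi-axis a, semi-axis b, center x, center y, angle deg)
# on the unit square [-1, 1]^2.  Values compose additively and the modified
# grey levels keep the total inside [0, 1].
_SHEPP_LOGAN_ELLIPSES = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


@dataclass
class Sinogram:
    """Measured fan-beam data for one scan.

    Vectors are ray-ordered (view-major) of length ``n_views * n_detectors``.

    Attributes
    ----------
    l_hat : measured line integrals.
    y : exit photon intensities.
    b : entrance photon intensities.
    r : read-out noise means.
    omega : statistical weights ``(y - r)**2 / y``.
    l_true : noiseless line integrals when known (simulation), else None.
    """

    l_hat: np.ndarray
    y: np.ndarray
    b: np.ndarray
    r: np.ndarray
    omega: np.ndarray
    l_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.l_hat)):
            raise ValueError("non-finite measured line integrals")
        if np.any(self.y <= self.r) or np.any(self.r < 0):
            raise ValueError("require y > r >= 0 for every ray")

    @property
    def n_rays(self) -> int:
        return self.l_hat.size


def statistical_weights(y: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Per-ray statistical weight ``omega = (y - r)**2 / y``."""
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    return (y - r) ** 2 / y


def make_shepp_logan(n: int) -> np.ndarray:
    """Rasterize the modified Shepp-Logan head phantom on an ``n x n`` grid.

    Pixel values are in [0, 1] (the additive ellipse composition is clipped).
    Pixel centers sample the unit square [-1, 1]^2.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    coords = -1.0 + (2.0 * np.arange(n) + 1.0) / n
    x = coords[None, :]
    y = -coords[:, None]  # row 0 at the top
    img = np.zeros((n, n))
    for val, a, b, x0, y0, ang in _SHEPP_LOGAN_ELLIPSES:
        phi = np.deg2rad(ang)
        c, s = np.cos(phi), np.sin(phi)
        xr = (x - x0) * c + (y - y0) * s
        yr = -(x - x0) * s + (y - y0) * c
        img += val * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return np.clip(img, 0.0, 1.0)


def simulate_scan(mu: np.ndarray, geom: ScanGeometry, noise_level: float = 0.0,
                  b0: float = 1e6, seed: int | None = None,
                  A: SystemMatrix | None = None,
                  poisson: bool = False) -> Sinogram:
    """Simulate a fan-beam scan of attenuation image ``mu``.

    Parameters
    ----------
    mu : (N, N) attenuation image matching ``geom.image_n``.
    noise_level : relative Gaussian noise fraction; each measured line
        integral is ``l_true_i * (1 + noise_level * eps_i)`` with standard
        normal ``eps_i``.  Rays with zero true integral stay exact.
    b0 : entrance photon intensity per ray.
    seed : RNG seed; the same seed reproduces the sinogram bit-for-bit.
    A : optional prebuilt system matrix (avoids re-tracing the geometry).
    poisson : if True, additionally resample the exit intensities as
        Poisson counts (full photon-statistics mode, not used by the
        reproduction experiments).
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if b0 <= 0:
        raise ValueError("b0 must be positive")
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (geom.image_n, geom.image_n):
        raise ValueError(f"image shape {mu.shape} does not match geometry N={geom.image_n}")
    if A is None:
        A = build_system_matrix(geom)
    rng = np.random.default_rng(seed)
    l_true = forward_project(A, mu)
    b = np.full(l_true.size, float(b0))
    r = np.zeros(l_true.size)

    if noise_level > 0:
        eps = rng.standard_normal(l_true.size)
        l_hat = l_true * (1.0 + noise_level * eps)
    else:
        l_hat = l_true.copy()

    y = b * np.exp(-l_hat)
    if poisson:
        y = rng.poisson(y).astype(float)
        y = np.maximum(y, 1.0)  # avoid log of zero counts
        l_hat = np.log(b / (y - r))

    omega = statistical_weights(y, r)
    return Sinogram(l_hat=l_hat, y=y, b=b, r=r, omega=omega, l_true=l_true)
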