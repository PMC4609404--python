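"""Fan-beam scan geometry and the ray-driven system matrix.

Conventions
-----------
* The image is an ``N x N`` grid of square pixels of edge ``pixel_size``
  centered on the origin.  Pixel ``(row 0, col 0)`` sits at the top-left
  corner; row ``r``, column ``c`` covers
  ``x in [-N/2 + c, -N/2 + c + 1] * pixel_size`` and
  ``y in [N/2 - r - 1, N/2 - r] * pixel_size``.
* Images are vectorized row-major: pixel ``(r, c)`` maps to ``j = r*N + c``.
* The X-ray source for view ``v`` at angle ``theta_v = v * angular_step``
  sits at ``R * (cos theta, sin theta)`` with ``R = source_to_center``.
* The detector is flat and equispaced, modelled as a virtual line through
  the isocenter perpendicular to the central ray; element centers are
  equispaced positions along that line.  Ray ``(v, d)`` is the line from the
  source through element center ``d``.

The system matrix entry ``a_ij`` is the exact Euclidean intersection length
of ray ``i`` with pixel ``j`` (Siddon's algorithm), so ``A @ mu`` is the
discrete line integral of the attenuation map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ScanGeometry",
    "SystemMatrix",
    "build_geometry",
    "default_detector_span",
    "trace_ray",
    "build_system_matrix",
    "forward_project",
    "back_project",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Fan-beam acquisition description.

    Lengths are in image-edge units (``pixel_size`` defaults to 1).
    """

    n_views: int
    angular_step_deg: float
    n_detectors: int
    image_n: int
    source_to_center: float
    detector_span: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.n_views < 1 or self.n_detectors < 1 or self.image_n < 1:
            raise ValueError("n_views, n_detectors and image_n must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        half_edge = self.image_n * self.pixel_size / 2.0
        if self.source_to_center <= half_edge:
            raise ValueError("source must lie outside the image grid")

    @property
    def n_rays(self) -> int:
        return self.n_views * self.n_detectors

    @property
    def view_angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angular_step_deg) * np.arange(self.n_views)

    def detector_positions(self) -> np.ndarray:
        """Signed element-center offsets along the virtual detector line."""
        d = self.n_detectors
        pitch = self.detector_span / d
        return (np.arange(d) - (d - 1) / 2.0) * pitch

    def covers_grid(self) -> bool:
        """True if the fan subtends the circumscribed circle of the grid."""
        rc = self.image_n * self.pixel_size * np.sqrt(0.5)
        t_max = self.detector_span / 2.0  # outer edge of the detector row
        if t_max == 0.0:
            return self.n_detectors == 1
        r = self.source_to_center
        reach = t_max * r / np.hypot(r, t_max)
        return bool(reach >= rc)


def default_detector_span(image_n: int, source_to_center: float,
                          pixel_size: float = 1.0, margin: float = 1.1) -> float:
    """Detector span (through the isocenter) covering the circumscribed
    circle of the image from every view, with a safety margin."""
    rc = image_n * pixel_size * np.sqrt(0.5)
    r = source_to_center
    if r <= rc:
        raise ValueError("source inside the circumscribed circle")
    half = margin * rc * r / np.sqrt(r * r - rc * rc)
    return 2.0 * half


def build_geometry(n_views: int, angular_step_deg: float, n_detectors: int,
                   image_n: int, source_factor: float = 2.0,
                   detector_span: float | None = None,
                   pixel_size: float = 1.0) -> ScanGeometry:
    """Build a fan-beam geometry with the source at
    ``source_factor * image edge length`` from the isocenter.

    ``detector_span`` defaults to the smallest span (plus 10% margin) whose
    fan covers the circumscribed circle of the grid from all views.
    """
    if n_views < 1 or n_detectors < 1 or image_n < 1:
        raise ValueError("counts must be positive")
    if source_factor < 1.0:
        raise ValueError("source_factor must be >= 1")
    src = source_factor * image_n * pixel_size
    if detector_span is None:
        detector_span = default_detector_span(image_n, src, pixel_size)
    geom = ScanGeometry(n_views=n_views, angular_step_deg=angular_step_deg,
                        n_detectors=n_detectors, image_n=image_n,
                        source_to_center=src, detector_span=detector_span,
                        pixel_size=pixel_size)
    if n_detectors > 1 and not geom.covers_grid():
        raise ValueError("detector span does not cover the image grid")
    return geom


def _ray_endpoints(geom: ScanGeometry, view: int) -> tuple[np.ndarray, np.ndarray]:
    """Source point and the detector element centers for one view."""
    theta = np.deg2rad(geom.angular_step_deg) * view
    src = geom.source_to_center * np.array([np.cos(theta), np.sin(theta)])
    u = np.array([-np.sin(theta), np.cos(theta)])  # detector line direction
    t = geom.detector_positions()
    ends = t[:, None] * u[None, :]
    return src, ends


def _siddon_view(geom: ScanGeometry, src: np.ndarray, ends: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Siddon intersection lengths for all rays of one view.

    Returns (ray_index_within_view, pixel_index, length) arrays.
    Rays are parametrized as ``p(alpha) = src + alpha * (end - src)`` with
    alpha unbounded, so the detector may sit inside or outside the grid.
    """
    n = geom.image_n
    h = geom.pixel_size
    half = n * h / 2.0
    d = ends.shape[0]

    dx = ends[:, 0] - src[0]
    dy = ends[:, 1] - src[1]
    planes = -half + h * np.arange(n + 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        ax = (planes[None, :] - src[0]) / dx[:, None]
        ay = (planes[None, :] - src[1]) / dy[:, None]
    # rays parallel to an axis: no crossings with those planes
    ax[dx == 0.0, :] = np.inf
    ay[dy == 0.0, :] = np.inf

    with np.errstate(invalid="ignore"):
        ax_lo = np.minimum(ax[:, 0], ax[:, -1])
        ax_hi = np.maximum(ax[:, 0], ax[:, -1])
        ay_lo = np.minimum(ay[:, 0], ay[:, -1])
        ay_hi = np.maximum(ay[:, 0], ay[:, -1])
    # parallel rays: inside iff the fixed coordinate is inside the slab
    par_x = dx == 0.0
    par_y = dy == 0.0
    ax_lo = np.where(par_x, np.where(np.abs(src[0]) < half, -np.inf, np.inf), ax_lo)
    ax_hi = np.where(par_x, np.where(np.abs(src[0]) < half, np.inf, -np.inf), ax_hi)
    ay_lo = np.where(par_y, np.where(np.abs(src[1]) < half, -np.inf, np.inf), ay_lo)
    ay_hi = np.where(par_y, np.where(np.abs(src[1]) < half, np.inf, -np.inf), ay_hi)

    a_in = np.maximum(ax_lo, ay_lo)
    a_out = np.minimum(ax_hi, ay_hi)
    hit = a_in < a_out
    if not np.any(hit):
        return (np.empty(0, np.intp), np.empty(0, np.intp), np.empty(0))

    alphas = np.concatenate([ax, ay], axis=1)
    alphas = np.clip(alphas, a_in[:, None], a_out[:, None])
    alphas.sort(axis=1)

    seg = np.diff(alphas, axis=1)
    mids = 0.5 * (alphas[:, :-1] + alphas[:, 1:])
    ray_len = np.hypot(dx, dy)[:, None]
    lengths = seg * ray_len

    mx = src[0] + mids * dx[:, None]
    my = src[1] + mids * dy[:, None]
    cols_x = np.floor((mx + half) / h).astype(np.intp)
    rows_y = np.floor((half - my) / h).astype(np.intp)

    valid = (lengths > 1e-12) & hit[:, None] & \
        (cols_x >= 0) & (cols_x < n) & (rows_y >= 0) & (rows_y < n)
    ray_idx = np.broadcast_to(np.arange(d, dtype=np.intp)[:, None], valid.shape)
    j = rows_y * n + cols_x
    return ray_idx[valid], j[valid], lengths[valid]


def trace_ray(geom: ScanGeometry, view: int, detector: int
              ) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices and exact intersection lengths of a single ray.

    Returns ``(j, a)`` with ``j`` the row-major pixel indices the ray crosses
    and ``a`` the corresponding lengths; both empty if the ray misses the
    grid.
    """
    if not (0 <= view < geom.n_views):
        raise IndexError(f"view {view} out of range")
    if not (0 <= detector < geom.n_detectors):
        raise IndexError(f"detector {detector} out of range")
    src, ends = _ray_endpoints(geom, view)
    _, j, a = _siddon_view(geom, src, ends[detector:detector + 1])
    order = np.argsort(j)
    # merge duplicate pixels (possible when a clipped zero-length segment
    # survives the threshold on an edge crossing)
    j, a = j[order], a[order]
    if j.size:
        uj, inv = np.unique(j, return_inverse=True)
        ua = np.zeros(uj.size)
        np.add.at(ua, inv, a)
        return uj, ua
    return j, a


class SystemMatrix:
    """Sparse ray-pixel intersection matrix ``A`` of shape
    ``(n_views * n_detectors, N*N)`` with per-view row blocks.

    Rays are ordered view-major: ray ``i = v * n_detectors + d``.
    """

    def __init__(self, geom: ScanGeometry, matrix: sp.csr_matrix):
        self.geom = geom
        self.matrix = matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def row_sums(self) -> np.ndarray:
        """Per-ray in-grid path length ``sum_j a_ij``."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def view_block(self, views: np.ndarray | slice) -> sp.csr_matrix:
        """Rows belonging to the given view indices."""
        nd = self.geom.n_detectors
        idx = np.arange(self.geom.n_views)[views]
        rows = (idx[:, None] * nd + np.arange(nd)[None, :]).ravel()
        return self.matrix[rows]


def build_system_matrix(geom: ScanGeometry) -> SystemMatrix:
    """Assemble the full Siddon system matrix, one view at a time."""
    n2 = geom.image_n ** 2
    nd = geom.n_detectors
    blocks = []
    for v in range(geom.n_views):
        src, ends = _ray_endpoints(geom, v)
        r, j, a = _siddon_view(geom, src, ends)
        blocks.append(sp.csr_matrix((a, (r, j)), shape=(nd, n2)))
    mat = sp.vstack(blocks, format="csr")
    mat.sum_duplicates()
    return SystemMatrix(geom, mat)


def forward_project(A: SystemMatrix | sp.spmatrix, mu: np.ndarray) -> np.ndarray:
    """Line integrals ``l = A @ mu``; ``mu`` may be an image or a vector."""
    mat = A.matrix if isinstance(A, SystemMatrix) else A
    v = np.asarray(mu, dtype=float).ravel()
    if v.size != mat.shape[1]:
        raise ValueError(f"image size {v.size} != {mat.shape[1]}")
    return mat @ v


def back_project(A: SystemMatrix | sp.spmatrix, v: np.ndarray,
                 as_image: bool = True) -> np.ndarray:
    """Adjoint action ``A.T @ v``, returned as an image grid by default."""
    mat = A.matrix if isinstance(A, SystemMatrix) else A
    w = np.asarray(v, dtype=float).ravel()
    if w.size != mat.shape[0]:
        raise ValueError(f"vector size {w.size} != {mat.shape[0]}")
    out = mat.T @ w
    if as_image and isinstance(A, SystemMatrix):
        n = A.geom.image_n
        return out.reshape(n, n)
    return out
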