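"""Closed cubic B-spline active contour driven by a generalized gradient
vector flow (GGVF) field.

The external force field (u, v) is obtained by diffusing the gradient of an
edge map f: starting from (u, v) = (f_x, f_y), gradient descent on the GGVF
energy iterates

    u <- u + dtau * [ g(|grad f|) * lap(u) - (1 - g(|grad f|)) * (u - f_x) ]

(and likewise for v with f_y), with the edge-gated weight
``g = exp(-|grad f| / k)``.  Where the edge strength is low g ~ 1 and the
field diffuses freely, giving the snake a large capture range; near strong
edges g ~ 0 and the field stays pinned to the edge gradient.

The contour is a closed cubic B-spline over cyclic control points; the
spline's intrinsic smoothness replaces explicit internal (tension/rigidity)
forces.  At each evolution step the curve is sampled, the field is read at
the samples, and the sampled forces are projected back onto the control
points through the pseudo-inverse of the spline sampling matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve, gaussian_filter, map_coordinates

from .phantom import as_image

__all__ = [
    "GVFField",
    "BSplineContour",
    "SnakeParams",
    "SnakeResult",
    "edge_map",
    "compute_gvf",
    "bspline_basis",
    "sample_contour",
    "init_circle",
    "evolve_snake",
    "contour_to_mask",
    "contour_boundary_pixels",
    "mask_boundary_pixels",
]

_LAP = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def edge_stopping(grad_mag: np.ndarray | float, k: float) -> np.ndarray | float:
    """Edge-gated smoothing weight g = exp(-|grad f| / k): 1 where the edge
    force vanishes (pure smoothing), decaying with edge strength."""
    return np.exp(-np.asarray(grad_mag) / k)


@dataclass(frozen=True)
class GVFField:
    """Diffused external-force field over the image grid.

    ``u`` is the x (column) component, ``v`` the y (row) component.
    """

    u: np.ndarray
    v: np.ndarray
    k: float
    iterations_run: int

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share a shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("GVF field contains non-finite values")


@dataclass(frozen=True)
class BSplineContour:
    """Closed cubic B-spline defined by cyclic control points (row, col).

    The curve is parameterized uniformly: parameter t in [0, m) with m
    control points, each unit interval one spline segment supported by 4
    consecutive (cyclically indexed) control points.
    """

    control_points: np.ndarray  # (m, 2) array of (row, col)

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
            raise ValueError("contour needs >= 4 control points of (row, col)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("control points must be finite")
        object.__setattr__(self, "control_points", pts)

    @property
    def n_control(self) -> int:
        return self.control_points.shape[0]


@dataclass(frozen=True)
class SnakeParams:
    n_samples: int = 96
    step_size: float = 1.0
    max_iters: int = 2000
    tol: float = 0.02
    gvf_k: float = 0.5
    gvf_iters: int = 80

    def __post_init__(self) -> None:
        if min(self.n_samples, self.step_size, self.max_iters, self.tol,
               self.gvf_k, self.gvf_iters) <= 0:
            raise ValueError("all snake parameters must be positive")
        if self.tol >= 1.0:
            raise ValueError("tol must be < 1 pixel")


@dataclass(frozen=True)
class SnakeResult:
    contour: BSplineContour
    iterations: int
    converged: bool


def edge_map(img: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gradient-magnitude edge map |grad(G_sigma * I)|, normalized to [0, 1].

    Zero everywhere on a constant image.
    """
    img = as_image(img)
    smooth = gaussian_filter(img, sigma=sigma, mode="nearest") if sigma > 0 else img
    gy, gx = np.gradient(smooth)
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    return mag


def compute_gvf(
    edge: np.ndarray, k: float = 0.5, iters: int = 80, dt: float = 0.2
) -> GVFField:
    """Iterate the GGVF descent equations from (u, v) = (f_x, f_y).

    ``dt`` must satisfy the explicit-Euler stability bound dt <= 1/4 for the
    4-neighbor Laplacian with g <= 1 (default 0.2).
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    if not 0 < dt <= 0.25:
        raise ValueError("dt must be in (0, 0.25] for stability")
    f = as_image(edge)
    fy, fx = np.gradient(f)
    grad_mag = np.hypot(fx, fy)
    g = edge_stopping(grad_mag, k)
    h = 1.0 - g
    u = fx.copy()
    v = fy.copy()
    for it in range(iters):
        u = u + dt * (g * convolve(u, _LAP, mode="nearest") - h * (u - fx))
        v = v + dt * (g * convolve(v, _LAP, mode="nearest") - h * (v - fy))
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise FloatingPointError(f"GVF diverged at iteration {it}")
    return GVFField(u=u, v=v, k=k, iterations_run=iters)


def bspline_basis(i: int, p: int, t: float, knots: np.ndarray) -> float:
    """Cox-de Boor recursion for the B-spline blending function B_{i,p}(t).

    ``p`` is the order (p=4 gives cubic splines); the 0/0 convention is 0.
    ``t`` must lie within the global knot range.
    """
    knots = np.asarray(knots, dtype=np.float64)
    if not knots[0] <= t <= knots[-1]:
        raise ValueError(f"t={t} outside knot range [{knots[0]}, {knots[-1]}]")
    if p == 1:
        # half-open base intervals; the final interval closes at the last knot
        if knots[i] <= t < knots[i + 1]:
            return 1.0
        if t == knots[-1] and knots[i] < knots[i + 1] == knots[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if knots[i + p - 1] != knots[i]:
        left = (t - knots[i]) / (knots[i + p - 1] - knots[i]) * bspline_basis(
            i, p - 1, t, knots
        )
    right = 0.0
    if knots[i + p] != knots[i + 1]:
        right = (knots[i + p] - t) / (knots[i + p] - knots[i + 1]) * bspline_basis(
            i + 1, p - 1, t, knots
        )
    return left + right


def _uniform_cubic_blend(u: np.ndarray) -> np.ndarray:
    """The four uniform cubic B-spline blending weights at local parameter
    u in [0, 1): columns (b0, b1, b2, b3) applied to control points
    P_{i-1}, P_i, P_{i+1}, P_{i+2}."""
    u = np.asarray(u, dtype=np.float64)
    u2 = u * u
    u3 = u2 * u
    b0 = (1.0 - u) ** 3 / 6.0
    b1 = (3.0 * u3 - 6.0 * u2 + 4.0) / 6.0
    b2 = (-3.0 * u3 + 3.0 * u2 + 3.0 * u + 1.0) / 6.0
    b3 = u3 / 6.0
    return np.stack([b0, b1, b2, b3], axis=-1)


def _sampling_matrix(n_ctrl: int, n_samples: int) -> np.ndarray:
    """(n_samples, n_ctrl) matrix A with A @ P giving points evenly spaced
    in parameter along the closed cubic spline."""
    t = np.arange(n_samples) * (n_ctrl / n_samples)
    seg = np.floor(t).astype(int)
    u = t - seg
    blend = _uniform_cubic_blend(u)
    A = np.zeros((n_samples, n_ctrl))
    for j in range(4):
        idx = (seg - 1 + j) % n_ctrl
        A[np.arange(n_samples), idx] += blend[:, j]
    return A


def sample_contour(contour: BSplineContour, n: int) -> np.ndarray:
    """Sample the closed spline at n points evenly spaced in parameter.

    Returns an (n, 2) array of (row, col); the polyline is closed (the
    point after the last sample is the first).
    """
    m = contour.n_control
    if n < m:
        raise ValueError(f"need at least one sample per segment (n >= {m})")
    return _sampling_matrix(m, n) @ contour.control_points


def init_circle(
    center: tuple[float, float],
    radius: float,
    n_ctrl: int = 48,
    image_shape: tuple[int, int] | None = None,
) -> BSplineContour:
    """Circle-shaped initial contour: n_ctrl control points equally spaced
    on the circle (the sampled spline lies slightly inside it)."""
    if radius <= 2:
        raise ValueError("radius must be > 2 pixels")
    if image_shape is not None:
        H, W = image_shape
        r0, c0 = center
        if r0 - radius < 0 or c0 - radius < 0 or r0 + radius > H - 1 or c0 + radius > W - 1:
            raise ValueError("initial circle extends outside the image")
    theta = 2.0 * np.pi * np.arange(n_ctrl) / n_ctrl
    pts = np.stack(
        [center[0] + radius * np.sin(theta), center[1] + radius * np.cos(theta)],
        axis=1,
    )
    return BSplineContour(pts)


def _sample_field(field: GVFField, points: np.ndarray) -> np.ndarray:
    """Bilinear field lookup at (row, col) points; outside the grid the
    lookup clamps to the border.  Returns (n, 2) forces as (d_row, d_col)."""
    coords = [points[:, 0], points[:, 1]]
    fv = map_coordinates(field.v, coords, order=1, mode="nearest")
    fu = map_coordinates(field.u, coords, order=1, mode="nearest")
    return np.stack([fv, fu], axis=1)


class ContourEscapeError(RuntimeError):
    def __init__(self, iteration: int, last_contour: BSplineContour):
        super().__init__(f"contour escaped image bounds at iteration {iteration}")
        self.last_contour = last_contour


def evolve_snake(
    c0: BSplineContour, gvf: GVFField, params: SnakeParams = SnakeParams()
) -> SnakeResult:
    """Evolve the contour under the GVF field until the maximum
    control-point displacement falls below ``tol`` or ``max_iters`` is hit.

    Per step: sample the curve at ``n_samples`` points, read (u, v) at each
    sample bilinearly, project the sampled forces onto control-point
    displacements through the pseudo-inverse of the sampling matrix, and
    move the control points by ``step_size`` times the projection.
    """
    H, W = gvf.u.shape
    A = _sampling_matrix(c0.n_control, params.n_samples)
    A_pinv = np.linalg.pinv(A)
    P = c0.control_points.copy()
    converged = False
    it = 0
    for it in range(1, params.max_iters + 1):
        samples = A @ P
        forces = _sample_field(gvf, samples)
        dP = params.step_size * (A_pinv @ forces)
        P = P + dP
        if (P[:, 0].min() < -1 or P[:, 0].max() > H or
                P[:, 1].min() < -1 or P[:, 1].max() > W):
            raise ContourEscapeError(it, BSplineContour(P - dP))
        if np.abs(dP).max() < params.tol:
            converged = True
            break
    return SnakeResult(contour=BSplineContour(P), iterations=it, converged=converged)


def contour_to_mask(
    contour: BSplineContour, image_shape: tuple[int, int], n_samples: int = 720
) -> np.ndarray:
    """Rasterize the region enclosed by the contour to a boolean mask."""
    from matplotlib.path import Path

    poly = sample_contour(contour, max(n_samples, contour.n_control))
    H, W = image_shape
    rows, cols = np.mgrid[0:H, 0:W]
    pts = np.stack([rows.ravel(), cols.ravel()], axis=1)
    inside = Path(poly).contains_points(pts)
    return inside.reshape(H, W)


def contour_boundary_pixels(
    contour: BSplineContour, n_samples: int = 720
) -> np.ndarray:
    """Integer (row, col) boundary pixels traced by the sampled curve."""
    poly = sample_contour(contour, max(n_samples, contour.n_control))
    pix = np.rint(poly).astype(int)
    return np.unique(pix, axis=0)


def mask_boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a boolean mask: members with a 4-neighbor outside."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, mode="constant")
    inner = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~inner
    return np.argwhere(boundary)
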