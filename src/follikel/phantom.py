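"""Synthetic piecewise-constant phantoms and multiplicative speckle corruption.

Speckle in coherent (ultrasound) imaging is modelled multiplicatively:
``J(X) = I(X) * (1 + eta(X))`` with ``eta`` zero-mean i.i.d. noise, so the
perturbation magnitude scales with the local intensity — bright regions are
noisier than dark ones.  The phantom generator produces the piecewise-constant
test images (circles and rectangles of several sizes on a darker background)
used to evaluate despeckling filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Shape",
    "PhantomSpec",
    "SpeckleParams",
    "default_phantom_spec",
    "generate_phantom",
    "apply_speckle",
    "speckle_noise_field",
]


def as_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce a 2-D raster to the float64 [0, 1] image carrier."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


@dataclass(frozen=True)
class Shape:
    """A single phantom primitive.

    ``kind`` is ``"circle"`` (center + radius) or ``"rectangle"`` (top-left
    corner + (height, width), half-open extent).  Coordinates are 0-based
    (row, col) with the origin at the top-left.
    """

    kind: str
    center: tuple[float, float]
    size: tuple[float, ...]
    level: float

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "rectangle"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"shape level {self.level} outside [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    canvas_size: tuple[int, int] = (256, 256)
    background_level: float = 0.15
    shapes: tuple[Shape, ...] = ()

    def __post_init__(self) -> None:
        H, W = self.canvas_size
        if H < 3 or W < 3:
            raise ValueError("canvas must be at least 3x3")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background level outside [0, 1]")
        for i, s in enumerate(self.shapes):
            if self._out_of_canvas(s):
                raise ValueError(f"shape {i} ({s.kind}) extends outside the canvas")

    def _out_of_canvas(self, s: Shape) -> bool:
        H, W = self.canvas_size
        r, c = s.center
        if s.kind == "circle":
            rad = s.size[0]
            return r - rad < 0 or c - rad < 0 or r + rad > H - 1 or c + rad > W - 1
        h, w = s.size
        return r < 0 or c < 0 or r + h > H or c + w > W


@dataclass(frozen=True)
class SpeckleParams:
    """Zero-configuration multiplicative noise: J = I * (1 + eta).

    ``eta`` has the given mean and variance; the default distribution is
    uniform on ``[mean - a, mean + a]`` with ``a = sqrt(3 * variance)``
    (the common ``imnoise``-style speckle model).  Gaussian ``eta`` is
    available as an option.
    """

    mean: float = 0.0
    variance: float = 0.075
    distribution: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("noise variance must be >= 0")
        if self.distribution not in ("uniform", "gaussian"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "uniform" and self.variance > 1.0 / 3.0:
            raise ValueError("uniform speckle requires variance <= 1/3")


def default_phantom_spec(canvas_size: tuple[int, int] = (256, 256)) -> PhantomSpec:
    """The packaged phantom: circles and rectangles of three sizes, two
    foreground levels (0.5 and 0.9) on a 0.15 background.

    Shape positions scale with the canvas so a smaller canvas keeps the same
    layout for quick tests.
    """
    H, W = canvas_size
    sy, sx = H / 256.0, W / 256.0

    def pt(r: float, c: float) -> tuple[float, float]:
        return (r * sy, c * sx)

    shapes = (
        Shape("circle", pt(64, 64), (24 * min(sy, sx),), 0.9),
        Shape("circle", pt(64, 176), (12 * min(sy, sx),), 0.5),
        Shape("circle", pt(120, 128), (6 * min(sy, sx),), 0.9),
        Shape("rectangle", pt(160, 40), (31 * sy, 31 * sx), 0.5),
        Shape("rectangle", pt(168, 140), (15 * sy, 15 * sx), 0.9),
        Shape("rectangle", pt(200, 200), (5 * sy, 5 * sx), 0.5),
    )
    return PhantomSpec(canvas_size=canvas_size, background_level=0.15, shapes=shapes)


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Rasterize a phantom spec to a float image in [0, 1].

    A pixel belongs to a circle iff its (integer) center lies within the
    radius; rectangles use half-open extents.  Deterministic.
    """
    H, W = spec.canvas_size
    img = np.full((H, W), spec.background_level, dtype=np.float64)
    rows, cols = np.mgrid[0:H, 0:W]
    for s in spec.shapes:
        if s.kind == "circle":
            r0, c0 = s.center
            rad = s.size[0]
            mask = (rows - r0) ** 2 + (cols - c0) ** 2 <= rad**2
        else:
            r0, c0 = s.center
            h, w = s.size
            mask = (rows >= r0) & (rows < r0 + h) & (cols >= c0) & (cols < c0 + w)
        img[mask] = s.level
    return img


def speckle_noise_field(
    shape: tuple[int, int], params: SpeckleParams
) -> np.ndarray:
    """Draw the i.i.d. relative-perturbation field eta with the configured
    mean, variance and distribution.  Reproducible for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    if params.distribution == "uniform":
        a = np.sqrt(3.0 * params.variance)
        return rng.uniform(params.mean - a, params.mean + a, size=shape)
    return rng.normal(params.mean, np.sqrt(params.variance), size=shape)


def apply_speckle(
    img: np.ndarray, params: SpeckleParams, *, clip: bool = True
) -> np.ndarray:
    """Corrupt an image with multiplicative speckle: J = I * (1 + eta).

    The result is clipped to [0, 1] unless ``clip=False`` (moment checks on
    the perturbation should be computed pre-clip to avoid censoring bias).
    A zero image maps to a zero image for any noise parameters.
    """
    img = as_image(img)
    eta = speckle_noise_field(img.shape, params)
    out = img * (1.0 + eta)
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out
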