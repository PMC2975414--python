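"""Bilateral filtering: conventional, speckle-reducing (normalized-range),
Gaussian baseline, and the iterative scheme.

The conventional bilateral filter replaces each pixel by a normalized
weighted mean of its spatial neighborhood ``N(X)``:

    h(X) = C^-1 * sum_{Y in N(X)} J(Y) * w_d(X, Y) * w_r(X, Y)

with a spatial Gaussian ``w_d = exp(-||X - Y||^2 / (2 sigma_d^2))`` and a
range Gaussian on the intensity difference
``w_r = exp(-|J(Y) - J(X)|^2 / (2 sigma_r^2))``.

Under multiplicative speckle, ``J = I * (1 + eta)``, the intensity
difference between same-region pixels scales with the region brightness, so
a single ``sigma_r`` cannot suit both bright and dark regions.  The
speckle-reducing variant therefore normalizes the range distance by the
center intensity, ``D = |J(Y) - J(X)| / |J(X)|``, which in a homogeneous
region depends on the noise only — the filter's range kernel becomes
invariant to local brightness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import as_image

__all__ = [
    "BilateralParams",
    "bilateral_weights",
    "filter_conventional",
    "filter_normalized",
    "filter_gaussian",
    "filter_iterative",
    "filter_image",
]

#: default division guard for the normalized range distance (1/255, one
#: 8-bit quantization step)
DEFAULT_EPSILON = 1.0 / 255.0


def default_half_width(sigma_d: float) -> int:
    """Conventional 3-sigma truncation of the spatial Gaussian."""
    return max(1, int(np.ceil(3.0 * sigma_d)))


@dataclass(frozen=True)
class BilateralParams:
    """Parameters of one bilateral filtering run.

    sigma_d : spatial fall-off, pixels.
    sigma_r : range fall-off — absolute intensity units in conventional
        mode, relative (intensity / center intensity) units in normalized
        mode.
    half_width : neighborhood radius; window is (2h+1) x (2h+1).  Defaults
        to ceil(3 * sigma_d).
    mode : "conventional" or "normalized".
    iterations : how many times the single-pass filter is re-applied to its
        own output.
    epsilon : floor on |J(X)| in the normalized range distance, guarding
        division at (near-)zero pixels.
    """

    sigma_d: float = 3.0
    sigma_r: float = 0.7
    half_width: int | None = None
    mode: str = "normalized"
    iterations: int = 1
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.sigma_r <= 0:
            raise ValueError("sigma_d and sigma_r must be > 0")
        if self.mode not in ("conventional", "normalized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.half_width is None:
            object.__setattr__(self, "half_width", default_half_width(self.sigma_d))
        elif self.half_width < 1:
            raise ValueError("half_width must be >= 1")


def _spatial_kernel(half_width: int, sigma_d: float) -> np.ndarray:
    dy, dx = np.mgrid[-half_width : half_width + 1, -half_width : half_width + 1]
    return np.exp(-(dy**2 + dx**2) / (2.0 * sigma_d**2))


def bilateral_weights(
    window: np.ndarray, center_value: float, params: BilateralParams
) -> np.ndarray:
    """Weight patch for one (2h+1) x (2h+1) window centered on a pixel.

    Exposes the per-pixel weights for inspection and testing; the image
    filters compute the same quantity vectorized over all pixels.
    """
    window = np.asarray(window, dtype=np.float64)
    h = params.half_width
    if window.shape != (2 * h + 1, 2 * h + 1):
        raise ValueError(
            f"window shape {window.shape} does not match half_width {h}"
        )
    if window[h, h] != center_value:
        raise ValueError("center_value must equal the window's central pixel")
    diff = np.abs(window - center_value)
    if params.mode == "normalized":
        diff = diff / max(abs(center_value), params.epsilon)
    w = _spatial_kernel(h, params.sigma_d) * np.exp(
        -(diff**2) / (2.0 * params.sigma_r**2)
    )
    return w


def _bilateral_pass(img: np.ndarray, params: BilateralParams) -> np.ndarray:
    """One vectorized bilateral pass (reflect-padded borders).

    Loops over the window offsets, not over pixels: each offset contributes
    a shifted copy of the image weighted by its spatial factor and the
    per-pixel range factor.
    """
    h = params.half_width
    H, W = img.shape
    padded = np.pad(img, h, mode="reflect")
    inv_two_sr2 = 1.0 / (2.0 * params.sigma_r**2)
    spatial = _spatial_kernel(h, params.sigma_d)
    if params.mode == "normalized":
        denom = np.maximum(np.abs(img), params.epsilon)
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    for dy in range(-h, h + 1):
        for dx in range(-h, h + 1):
            s = spatial[dy + h, dx + h]
            shifted = padded[h + dy : h + dy + H, h + dx : h + dx + W]
            d = shifted - img
            if params.mode == "normalized":
                d = d / denom
            w = s * np.exp(-(d * d) * inv_two_sr2)
            num += w * shifted
            den += w
    return num / den


def filter_conventional(img: np.ndarray, params: BilateralParams) -> np.ndarray:
    """Single-pass conventional bilateral filter."""
    img = as_image(img)
    if params.mode != "conventional":
        params = replace(params, mode="conventional")
    return _bilateral_pass(img, params)


def filter_normalized(img: np.ndarray, params: BilateralParams) -> np.ndarray:
    """Single-pass speckle-reducing bilateral filter (normalized range)."""
    img = as_image(img)
    if params.mode != "normalized":
        params = replace(params, mode="normalized")
    return _bilateral_pass(img, params)


def filter_gaussian(
    img: np.ndarray, sigma: float = 3.0, window: int | None = 9
) -> np.ndarray:
    """Plain Gaussian smoothing baseline (truncated to the given window)."""
    img = as_image(img)
    if window is not None:
        truncate = ((window - 1) / 2) / sigma
    else:
        truncate = 4.0
    return gaussian_filter(img, sigma=sigma, mode="mirror", truncate=truncate)


def filter_iterative(
    img: np.ndarray,
    params: BilateralParams,
    *,
    return_snapshots: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[np.ndarray]]:
    """Apply the selected single-pass filter ``params.iterations`` times,
    feeding each output back as the next input.

    ``iterations=1`` equals the single-pass filter exactly.  With
    ``return_snapshots=True`` the per-iteration outputs are also returned.
    """
    img = as_image(img)
    out = img
    snapshots: list[np.ndarray] = []
    for _ in range(params.iterations):
        out = _bilateral_pass(out, params)
        if return_snapshots:
            snapshots.append(out.copy())
    if return_snapshots:
        return out, snapshots
    return out


def filter_image(img: np.ndarray, params: BilateralParams) -> np.ndarray:
    """Convenience front door: the iterative filter in the selected mode."""
    return filter_iterative(img, params)
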