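"""Despeckling quality metrics.

On synthetic data, where the clean reference I0 is known, three measures
compare the reference with a processed image I:

* NMSE — normalized mean square error of the mean-removed images,
  ``sum(((I0 - m0) - (I - m))^2) / sum((I0 - m0)^2)``; lower is better.
* alpha — noise-suppression measure: the normalized cross-correlation of
  the mean-removed intensities; in [-1, 1], higher is better.
* beta — edge-preservation measure: the same correlation computed on the
  4-neighbor Laplacians of the two images; in [-1, 1], higher is better.

On real images, where no reference exists, the local Laplacian contrast
(mean |4 I(x,y) - sum of the 4 neighbors| over a chosen point set) measures
residual noise in homogeneous regions and edge strength on edge sets, and
Pratt's figure of merit scores an extracted boundary against a reference
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import convolve
from scipy.spatial import cKDTree

from .phantom import as_image

__all__ = [
    "MetricsReport",
    "nmse",
    "noise_suppression_alpha",
    "edge_preservation_beta",
    "laplacian_map",
    "laplacian_contrast",
    "pratt_fom",
    "compute_report",
]

_LAPLACIAN_STENCIL = np.array(
    [[0.0, -1.0, 0.0], [-1.0, 4.0, -1.0], [0.0, -1.0, 0.0]]
)


class DegenerateInputError(ValueError):
    """Raised when a metric's denominator is identically zero."""


@dataclass(frozen=True)
class MetricsReport:
    nmse: float
    alpha: float
    beta: float
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "nmse": self.nmse,
            "alpha": self.alpha,
            "beta": self.beta,
            "params": dict(self.params),
            "seed": self.seed,
        }


def _check_pair(reference: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    reference = as_image(reference)
    test = as_image(test)
    if reference.shape != test.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs test {test.shape}"
        )
    return reference, test


def nmse(reference: np.ndarray, test: np.ndarray) -> float:
    reference, test = _check_pair(reference, test)
    r = reference - reference.mean()
    t = test - test.mean()
    denom = float(np.sum(r * r))
    if denom == 0.0:
        raise DegenerateInputError("constant reference image: NMSE undefined")
    return float(np.sum((r - t) ** 2) / denom)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Mean-removed normalized cross-correlation of two same-shape arrays."""
    a = a - a.mean()
    b = b - b.mean()
    na = float(np.sum(a * a))
    nb = float(np.sum(b * b))
    if na == 0.0 or nb == 0.0:
        raise DegenerateInputError("constant input: correlation undefined")
    return float(np.sum(a * b) / np.sqrt(na * nb))


def noise_suppression_alpha(reference: np.ndarray, test: np.ndarray) -> float:
    reference, test = _check_pair(reference, test)
    return _ncc(reference, test)


def laplacian_map(img: np.ndarray) -> np.ndarray:
    """4-neighbor Laplacian c = 4 I - (up + down + left + right), computed
    on interior pixels only (the 1-pixel border is excluded so the value at
    every reported pixel uses real neighbors)."""
    img = as_image(img)
    lap = convolve(img, _LAPLACIAN_STENCIL, mode="nearest")
    return lap[1:-1, 1:-1]


def edge_preservation_beta(reference: np.ndarray, test: np.ndarray) -> float:
    reference, test = _check_pair(reference, test)
    lr = laplacian_map(reference)
    lt = laplacian_map(test)
    if np.all(lr == 0.0):
        raise DegenerateInputError(
            "reference has identically-zero Laplacian: beta undefined"
        )
    return _ncc(lr, lt)


def _validate_points(
    points: np.ndarray, shape: tuple[int, int] | None = None, *, interior: bool = False
) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("point set must be a non-empty (n, 2) array of (row, col)")
    if shape is not None:
        lo = 1 if interior else 0
        H, W = shape
        hi_r, hi_c = (H - 2, W - 2) if interior else (H - 1, W - 1)
        bad = (
            (pts[:, 0] < lo) | (pts[:, 0] > hi_r) | (pts[:, 1] < lo) | (pts[:, 1] > hi_c)
        )
        if np.any(bad):
            idx = np.nonzero(bad)[0][:10].tolist()
            where = "interior (all 4 neighbors in bounds)" if interior else "bounds"
            raise ValueError(f"points at indices {idx} violate image {where}")
    return pts


def laplacian_contrast(img: np.ndarray, points: np.ndarray) -> float:
    """Mean absolute 4-neighbor Laplacian contrast over a point set.

    ``points`` is an (n, 2) integer array of (row, col) interior pixels —
    a homogeneous region or a set of edge points.  Zero on constant images;
    the absolute value keeps the measure discriminative in noise, where raw
    Laplacians average toward zero.
    """
    img = as_image(img)
    pts = _validate_points(points, img.shape, interior=True).astype(np.intp)
    r, c = pts[:, 0], pts[:, 1]
    cvals = 4.0 * img[r, c] - (
        img[r - 1, c] + img[r, c - 1] + img[r + 1, c] + img[r, c + 1]
    )
    return float(np.mean(np.abs(cvals)))


def pratt_fom(
    auto_boundary: np.ndarray, reference_boundary: np.ndarray, gamma: float = 0.05
) -> float:
    """Pratt's figure of merit for boundary accuracy.

    ``FOM = (1 / max(I_A, I_I)) * sum_i 1 / (1 + gamma * d(i)^2)`` where the
    sum runs over the ``I_I`` reference-boundary pixels and ``d(i)`` is the
    Euclidean distance from reference pixel i to the nearest of the ``I_A``
    automatically extracted boundary pixels.  In (0, 1]; equals 1 iff the
    two sets coincide.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    auto = _validate_points(auto_boundary)
    ref = _validate_points(reference_boundary)
    d, _ = cKDTree(auto).query(ref)
    total = float(np.sum(1.0 / (1.0 + gamma * d**2)))
    return total / max(len(auto), len(ref))


def compute_report(
    reference: np.ndarray,
    test: np.ndarray,
    params: dict[str, Any] | None = None,
    seed: int | None = None,
) -> MetricsReport:
    """Bundle NMSE, alpha and beta for one reference/test pair."""
    return MetricsReport(
        nmse=nmse(reference, test),
        alpha=noise_suppression_alpha(reference, test),
        beta=edge_preservation_beta(reference, test),
        params=dict(params or {}),
        seed=seed,
    )
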