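"""Image, boundary-CSV and config I/O.

Images are carried in memory as float64 rasters in [0, 1].  On read, 8-bit
data is divided by 255 and 16-bit by 65535; float images pass through.  On
write, ``.tif``/``.tiff`` stores 16-bit (or float32 with ``float_tiff``),
``.png``/``.pgm`` store 8-bit.  Boundary CSVs are comma-separated with
header ``row,col``, 0-based integer pixels, LF line endings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import tifffile


class ImageIOError(ValueError):
    """Typed error for unreadable or non-grayscale inputs."""


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - wrap the backend error
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ImageIOError(
                f"{path} is not single-channel (shape {arr.shape}); "
                "convert to grayscale first"
            )
    if arr.ndim != 2:
        raise ImageIOError(f"{path} is not a 2-D image (shape {arr.shape})")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def write_image(path: str | Path, img: np.ndarray, *, float_tiff: bool = False) -> None:
    path = Path(path)
    img = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        if float_tiff:
            tifffile.imwrite(path, img.astype(np.float32))
        else:
            tifffile.imwrite(path, np.round(img * 65535).astype(np.uint16))
    elif suffix in (".png", ".pgm"):
        iio.imwrite(path, np.round(img * 255).astype(np.uint8))
    else:
        raise ImageIOError(f"unsupported image format {suffix!r}")


def read_boundary_csv(path: str | Path) -> np.ndarray:
    pts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if pts.shape[1] != 2:
        raise ImageIOError(f"{path}: boundary CSV must have two columns (row,col)")
    return pts


def write_boundary_csv(path: str | Path, points: np.ndarray) -> None:
    points = np.asarray(points)
    with open(path, "w", newline="\n") as fh:
        fh.write("row,col\n")
        for r, c in points:
            fh.write(f"{int(round(r))},{int(round(c))}\n")


def write_sidecar(path: str | Path, params: dict[str, Any]) -> Path:
    """JSON sidecar (<output>.json) embedding the full parameter set that
    produced an output file, sufficient to reproduce it."""
    side = Path(str(path) + ".json")
    with open(side, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return side


def load_json(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
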