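"""Image I/O, flat/dark correction and region statistics.

Raw and simulated count images travel as 16-bit unsigned grayscale TIFF,
parametric maps as 32-bit float TIFF.  Angle metadata travels in sidecar
delimited-text manifests rather than TIFF tags.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import tifffile
from numpy.typing import NDArray

__all__ = [
    "CorrectionSet",
    "RegionSpec",
    "RoiStats",
    "correct_image",
    "roi_stats",
    "read_image",
    "write_image",
    "read_angle_manifest",
    "write_angle_manifest",
]


@dataclass(frozen=True)
class CorrectionSet:
    """Dark (offset) and peak-position flat (slope reference) images."""

    dark: NDArray[np.float64]
    flat: NDArray[np.float64]

    def __post_init__(self) -> None:
        dark = np.asarray(self.dark, dtype=float)
        flat = np.asarray(self.flat, dtype=float)
        object.__setattr__(self, "dark", dark)
        object.__setattr__(self, "flat", flat)
        if dark.shape != flat.shape:
            raise ValueError("dark and flat must share one shape")


@dataclass(frozen=True)
class RegionSpec:
    """Rectangular ROI, 0-based half-open pixel intervals."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_start >= self.row_stop or self.col_start >= self.col_stop:
            raise ValueError("region must be non-empty")
        if min(self.row_start, self.col_start) < 0:
            raise ValueError("region indices must be non-negative")

    def slice(self) -> tuple[slice, slice]:
        return (
            slice(self.row_start, self.row_stop),
            slice(self.col_start, self.col_stop),
        )


class RoiStats(NamedTuple):
    mean: float
    std: float
    sem: float
    n: int


def correct_image(
    raw: NDArray, correction: CorrectionSet, peak_flat_scale: float = 1.0
) -> tuple[NDArray[np.float64], NDArray[np.bool_]]:
    """Offset-and-slope correction against the peak-position flat.

    Computes ``(raw - dark) / (peak_flat_scale * (flat - dark))``.  All
    images at every analyzer offset must be divided by the same
    peak-position flat so that object-free background at offset theta
    reads the analyzer transmission at theta — a per-angle flat would
    silently cancel exactly the factor the retrieval solves for.

    Returns the corrected image and a validity mask (False where the flat
    does not exceed the dark).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != correction.dark.shape:
        raise ValueError("raw and correction images must share one shape")
    span = peak_flat_scale * (correction.flat - correction.dark)
    valid = span > 0
    out = np.full(raw.shape, np.nan)
    np.divide(raw - correction.dark, span, out=out, where=valid)
    return out, valid


def roi_stats(image: NDArray, region: RegionSpec) -> RoiStats:
    """Mean, standard deviation, standard error and count inside the ROI.

    NaN pixels (masked) are excluded from the statistics.
    """
    rows, cols = image.shape
    if region.row_stop > rows or region.col_stop > cols:
        raise ValueError("region exceeds image bounds")
    patch = np.asarray(image, dtype=float)[region.slice()]
    vals = patch[np.isfinite(patch)]
    n = int(vals.size)
    if n == 0:
        return RoiStats(float("nan"), float("nan"), float("nan"), 0)
    mean = float(vals.mean())
    std = float(vals.std(ddof=1)) if n > 1 else 0.0
    sem = std / np.sqrt(n) if n > 1 else 0.0
    return RoiStats(mean, std, float(sem), n)


def write_image(path: str | Path, image: NDArray) -> None:
    """Write a 2-D image as TIFF.

    Integer input is stored as 16-bit unsigned (counts), float input as
    32-bit float (parametric maps).  Round-trips losslessly at those
    depths.
    """
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        if image.min() < 0 or image.max() > np.iinfo(np.uint16).max:
            raise ValueError("integer image does not fit 16-bit unsigned range")
        tifffile.imwrite(path, image.astype(np.uint16))
    else:
        tifffile.imwrite(path, image.astype(np.float32))


def read_image(path: str | Path) -> NDArray:
    """Read a TIFF image; uint stays integer, floats come back as float32."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return tifffile.imread(path)


def write_angle_manifest(path: str | Path, names: list[str], thetas: list[float]) -> None:
    """Sidecar manifest: one ``filename<TAB>theta_urad`` line per image."""
    with open(path, "w") as fh:
        fh.write("# filename\ttheta_urad\n")
        for name, theta in zip(names, thetas, strict=True):
            fh.write(f"{name}\t{float(theta)!r}\n")


def read_angle_manifest(path: str | Path) -> tuple[list[str], list[float]]:
    names: list[str] = []
    thetas: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, theta = line.split()
            names.append(name)
            thetas.append(float(theta))
    return names, thetas
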