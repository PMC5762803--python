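"""Gaussian rocking-curve estimation and working-point location.

Fits a three-parameter Gaussian to measured (angle, intensity) samples of
the analyzer transmission and locates the angular offsets ("working
points") at a requested fraction of the peak, either on the fitted model
or by interpolating the measured samples directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import curve_fit

from .model import RockingCurve

__all__ = [
    "RCSamples",
    "RCFit",
    "fit_gaussian",
    "working_point_angle",
    "working_point_from_samples",
    "load_rc_samples",
]


@dataclass(frozen=True)
class RCSamples:
    """Measured rocking-curve samples: angles in microradians, intensities >= 0."""

    angles: NDArray[np.float64]
    intensities: NDArray[np.float64]

    def __post_init__(self) -> None:
        ang = np.asarray(self.angles, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "angles", ang)
        object.__setattr__(self, "intensities", inten)
        if ang.shape != inten.shape or ang.ndim != 1:
            raise ValueError("angles and intensities must be matching 1-D arrays")
        if len(np.unique(ang)) < 4:
            raise ValueError("at least 4 distinct angles required")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")

    def sorted(self) -> "RCSamples":
        order = np.argsort(self.angles)
        return RCSamples(self.angles[order], self.intensities[order])


@dataclass(frozen=True)
class RCFit:
    """Result of a Gaussian fit ``A * exp(-(theta - center)^2 / (2 sigma^2))``."""

    amplitude: float
    center: float
    sigma: float
    residual_norm: float
    #: estimated 1-sigma parameter errors (amplitude, center, sigma)
    stderr: tuple[float, float, float]
    peak_at_edge: bool = False

    def as_rocking_curve(self) -> RockingCurve:
        return RockingCurve(sigma=self.sigma)


def _gauss(theta, amplitude, center, sigma):
    return amplitude * np.exp(-((theta - center) ** 2) / (2.0 * sigma**2))


def _moment_init(angles, intensities):
    weights = np.clip(intensities, 0.0, None)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all intensities are zero")
    center = float((angles * weights).sum() / total)
    spread = float(np.sqrt(((angles - center) ** 2 * weights).sum() / total))
    if spread <= 0:
        spread = float(np.ptp(angles)) / 4 or 1.0
    return float(intensities.max()), center, spread


def fit_gaussian(samples: RCSamples, *, weighted: bool = False) -> RCFit:
    """Nonlinear least-squares Gaussian fit to rocking-curve samples.

    Initialized from intensity-weighted moments; recovers exact Gaussian
    input to machine precision.  With ``weighted=True`` the fit assumes
    Poisson (counting) errors ``sqrt(I)``.

    Raises
    ------
    RuntimeError
        If the optimizer fails to converge (diagnostics in the message).
    """
    srt = samples.sorted()
    angles, intensities = srt.angles, srt.intensities
    p0 = _moment_init(angles, intensities)
    # Poisson errors, floored at one count so empty tail bins are not
    # given unbounded weight
    sigma_w = np.sqrt(np.clip(intensities, 1.0, None)) if weighted else None
    try:
        popt, pcov = curve_fit(
            _gauss,
            angles,
            intensities,
            p0=p0,
            sigma=sigma_w,
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise RuntimeError(
            f"Gaussian fit did not converge (init {p0}): {exc}"
        ) from exc
    amplitude, center, sigma = popt
    sigma = abs(float(sigma))
    residual = float(np.linalg.norm(_gauss(angles, *popt) - intensities))
    stderr = tuple(float(s) for s in np.sqrt(np.clip(np.diag(pcov), 0, None)))
    peak_at_edge = bool(np.argmax(intensities) in (0, len(intensities) - 1))
    return RCFit(
        amplitude=float(amplitude),
        center=float(center),
        sigma=sigma,
        residual_norm=residual,
        stderr=stderr,  # type: ignore[arg-type]
        peak_at_edge=peak_at_edge,
    )


def working_point_angle(rc: RockingCurve, fraction: float, side: str) -> float:
    """Offset where the model curve crosses ``fraction`` of its peak.

    ``side`` is ``"low"`` (negative offset), ``"high"`` (positive) or
    ``"peak"`` (0, requires ``fraction == 1``).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if side == "peak":
        return 0.0
    if side not in ("low", "high"):
        raise ValueError(f"side must be 'low', 'high' or 'peak', got {side!r}")
    magnitude = rc.sigma * math.sqrt(-2.0 * math.log(fraction))
    return -magnitude if side == "low" else magnitude


def working_point_from_samples(samples: RCSamples, fraction: float, side: str) -> float:
    """Offset at ``fraction`` of the measured peak, by linear interpolation.

    Scans outward from the measured peak on the requested side and
    interpolates between the first pair of samples bracketing the target
    intensity.  Lets retrieval use actual rather than nominal working
    points.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    srt = samples.sorted()
    angles, intensities = srt.angles, srt.intensities
    peak_idx = int(np.argmax(intensities))
    target = fraction * intensities[peak_idx]
    if side == "peak":
        return float(angles[peak_idx])
    if side == "low":
        idx = np.arange(peak_idx, -1, -1)
    elif side == "high":
        idx = np.arange(peak_idx, len(angles))
    else:
        raise ValueError(f"side must be 'low', 'high' or 'peak', got {side!r}")
    for a, b in zip(idx[:-1], idx[1:]):
        ia, ib = intensities[a], intensities[b]
        if (ia >= target >= ib) or (ia <= target <= ib):
            if ia == ib:
                return float(angles[a])
            frac = (target - ia) / (ib - ia)
            return float(angles[a] + frac * (angles[b] - angles[a]))
    raise ValueError(
        f"fraction {fraction} not bracketed by samples on the {side} side"
    )


def load_rc_samples(path: str | Path) -> RCSamples:
    """Read 2-column delimited text (angle_urad, intensity); '#' comments."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (angle, intensity)")
    return RCSamples(data[:, 0], data[:, 1])
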