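"""Gaussian analyzer transmission model and closed-form parametric retrieval.

The analyzer crystal acts as an angular band-pass filter whose transmission
versus angular offset is modeled as a unit-peak Gaussian of width ``sigma``.
An object pixel modulates the local curve through three parameters:

* apparent absorption ``I_R`` (transmission including extinction),
* refraction angle ``dtheta_r`` (mean beam deviation, microradians),
* scattering variance ``sigma_s**2`` (width of the ultra-small-angle
  scattering distribution, microradians squared).

Convolving the Gaussian analyzer curve with a Gaussian scattering density
gives a closed-form forward model; measuring intensities at three distinct
analyzer offsets allows an exact algebraic inversion for all three
parameters.  Two-image reductions are provided for pixels known to be free
of scattering or free of refraction.

All angles are analyzer offsets from the rocking-curve peak, in
microradians; the Bragg angle itself never enters the retrieval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "RockingCurve",
    "WorkingPoints",
    "PixelTriple",
    "ParametricResult",
    "ParametricImages",
    "rc_transmission",
    "forward_intensity",
    "retrieve_refraction",
    "retrieve_scatter_variance",
    "retrieve_apparent_absorption",
    "retrieve_pixel",
    "retrieve_two_image_refraction",
    "retrieve_two_image_absorption_noscatter",
    "retrieve_two_image_scatter_norefraction",
    "retrieve_two_image_absorption_norefraction",
    "retrieve_parametric_images",
]

logger = logging.getLogger(__name__)

#: relative threshold below which the inversion denominator is degenerate
DEGENERACY_EPS = 1e-12


@dataclass(frozen=True)
class RockingCurve:
    """Unit-peak Gaussian analyzer transmission function.

    Parameters
    ----------
    sigma : float
        Angular width (standard deviation) in microradians.
    bragg_offset : float, optional
        Reference (Bragg) angle in microradians.  Working angles are
        expressed relative to the peak, so this is metadata only and
        defaults to 0.
    """

    sigma: float
    bragg_offset: float = 0.0

    #: transmission at the peak, fixed
    peak_transmission: float = field(default=1.0, init=False, repr=False)

    def __post_init__(self) -> None:
        if not (self.sigma > 0) or not math.isfinite(self.sigma):
            raise ValueError(f"sigma must be positive and finite, got {self.sigma}")

    def transmission(self, theta):
        """Transmission at offset ``theta`` (microradians) from the peak."""
        return rc_transmission(theta, self)


@dataclass(frozen=True)
class WorkingPoints:
    """Ordered analyzer offsets (microradians) at which images are taken."""

    thetas: tuple[float, ...]

    def __post_init__(self) -> None:
        thetas = tuple(float(t) for t in self.thetas)
        object.__setattr__(self, "thetas", thetas)
        if not all(math.isfinite(t) for t in thetas):
            raise ValueError("working points must be finite")
        if len(set(thetas)) != len(thetas):
            raise ValueError(f"working points must be pairwise distinct: {thetas}")

    def __len__(self) -> int:
        return len(self.thetas)


@dataclass(frozen=True)
class PixelTriple:
    """Intensities measured at the working points for a single pixel.

    Intensities are normalized so that an object-free pixel at offset
    ``theta`` reads the analyzer transmission at ``theta``.
    """

    intensities: tuple[float, ...]
    working_points: WorkingPoints

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.intensities)
        object.__setattr__(self, "intensities", vals)
        if len(vals) != len(self.working_points):
            raise ValueError("intensities and working points differ in length")


@dataclass(frozen=True)
class ParametricResult:
    """Retrieved per-pixel parameters.

    ``scatter_variance`` is reported as computed and may be negative on
    noisy input; ``valid`` is False when the inversion was degenerate.
    """

    apparent_absorption: float
    refraction: float
    scatter_variance: float
    valid: bool


def rc_transmission(theta, rc: RockingCurve):
    """Analyzer transmission ``exp(-theta**2 / (2 sigma**2))``.

    Even in ``theta`` and maximal (unity) at the peak.  Accepts scalars or
    arrays.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    out = np.exp(-(theta**2) / (2.0 * rc.sigma**2))
    return float(out) if out.ndim == 0 else out


def forward_intensity(i_r, dtheta_r, sigma_s, theta, rc: RockingCurve):
    """Closed-form detected intensity for one pixel at analyzer offset ``theta``.

    Evaluates ``I_R * sqrt(sigma^2/(sigma_s^2+sigma^2))
    * exp(-(theta+dtheta_r)^2 / (2 (sigma_s^2+sigma^2)))`` — the Gaussian
    convolution of the analyzer curve with the scattering density.  With
    ``sigma_s == 0`` it reduces to ``I_R * R(theta + dtheta_r)``.
    """
    sigma_s = np.asarray(sigma_s, dtype=float)
    if np.any(sigma_s < 0):
        raise ValueError("sigma_s must be non-negative")
    var = sigma_s**2 + rc.sigma**2
    out = (
        np.asarray(i_r, dtype=float)
        * np.sqrt(rc.sigma**2 / var)
        * np.exp(-((np.asarray(theta, dtype=float) + dtheta_r) ** 2) / (2.0 * var))
    )
    return float(out) if np.ndim(out) == 0 else out


def _log_ratios(i1, i2, i3):
    """log(I1/I2) and log(I3/I2) with NaN where any intensity is nonpositive."""
    with np.errstate(divide="ignore", invalid="ignore"):
        bad = (i1 <= 0) | (i2 <= 0) | (i3 <= 0)
        l1 = np.where(bad, np.nan, np.log(np.where(bad, 1.0, i1 / i2)))
        l3 = np.where(bad, np.nan, np.log(np.where(bad, 1.0, i3 / i2)))
    return l1, l3


def _invert_triple(i1, i2, i3, t1, t2, t3, sigma):
    """Vectorized three-image inversion.

    Returns ``(dtheta_r, scatter_variance, valid)``.  The two log-ratio
    equations are linear in ``dtheta_r`` and ``1/(sigma_s^2 + sigma^2)``;
    solving them yields

        total_var = (t2-t1)(t2-t3)(t1-t3) / (2 D)
        dtheta_r  = [L3 (t2^2-t1^2) - L1 (t2^2-t3^2)] / (2 D)

    with ``L1 = ln(I1/I2)``, ``L3 = ln(I3/I2)`` and
    ``D = L1 (t2-t3) - L3 (t2-t1)``.
    """
    l1, l3 = _log_ratios(i1, i2, i3)
    term_a = l1 * (t2 - t3)
    term_b = l3 * (t2 - t1)
    denom = term_a - term_b
    scale = np.maximum(np.maximum(np.abs(term_a), np.abs(term_b)), 1.0)
    degenerate = ~(np.abs(denom) > DEGENERACY_EPS * scale)
    valid = np.isfinite(l1) & np.isfinite(l3) & ~degenerate

    safe = np.where(valid, denom, 1.0)
    total_var = (t2 - t1) * (t2 - t3) * (t1 - t3) / (2.0 * safe)
    dtheta = (l3 * (t2**2 - t1**2) - l1 * (t2**2 - t3**2)) / (2.0 * safe)
    scatter_var = total_var - sigma**2
    # a non-positive total variance cannot come from the forward model
    valid = valid & (total_var > 0)
    dtheta = np.where(valid, dtheta, np.nan)
    scatter_var = np.where(valid, scatter_var, np.nan)
    return dtheta, scatter_var, valid


def _triple_inputs(triple: PixelTriple):
    if len(triple.working_points) != 3:
        raise ValueError("three intensities/working points required")
    i1, i2, i3 = triple.intensities
    t1, t2, t3 = triple.working_points.thetas
    return i1, i2, i3, t1, t2, t3


def retrieve_refraction(triple: PixelTriple) -> float:
    """Refraction angle (microradians) from a three-image pixel.

    Exact algebraic inverse of :func:`forward_intensity` on noiseless
    input.  Returns NaN for degenerate or nonpositive-intensity pixels.
    """
    i1, i2, i3, t1, t2, t3 = _triple_inputs(triple)
    dtheta, _, _ = _invert_triple(
        np.float64(i1), np.float64(i2), np.float64(i3), t1, t2, t3, sigma=1.0
    )
    return float(dtheta)


def retrieve_scatter_variance(triple: PixelTriple, rc: RockingCurve) -> float:
    """Scattering variance (microradians squared), possibly negative on noise.

    Returns NaN for degenerate or nonpositive-intensity pixels.
    """
    i1, i2, i3, t1, t2, t3 = _triple_inputs(triple)
    _, svar, _ = _invert_triple(
        np.float64(i1), np.float64(i2), np.float64(i3), t1, t2, t3, rc.sigma
    )
    return float(svar)


def retrieve_apparent_absorption(
    triple: PixelTriple,
    dtheta_r: float,
    scatter_var: float,
    rc: RockingCurve,
    which: int = 2,
) -> float:
    """Apparent absorption from one of the measured images (``which`` in 1..3).

    On noiseless data the result is independent of ``which``.
    """
    if which not in (1, 2, 3):
        raise ValueError("which must be 1, 2 or 3")
    total_var = scatter_var + rc.sigma**2
    if not total_var > 0:
        return float("nan")
    intensity = triple.intensities[which - 1]
    theta = triple.working_points.thetas[which - 1]
    return float(
        intensity
        * math.sqrt(total_var)
        / rc.sigma
        * math.exp((theta + dtheta_r) ** 2 / (2.0 * total_var))
    )


def retrieve_pixel(triple: PixelTriple, rc: RockingCurve, which: int = 2) -> ParametricResult:
    """Full three-parameter retrieval for a single pixel."""
    i1, i2, i3, t1, t2, t3 = _triple_inputs(triple)
    dtheta, svar, valid = _invert_triple(
        np.float64(i1), np.float64(i2), np.float64(i3), t1, t2, t3, rc.sigma
    )
    if not valid:
        return ParametricResult(float("nan"), float("nan"), float("nan"), False)
    i_r = retrieve_apparent_absorption(triple, float(dtheta), float(svar), rc, which)
    return ParametricResult(i_r, float(dtheta), float(svar), True)


def retrieve_two_image_refraction(
    intensities: Sequence[float], thetas: Sequence[float], rc: RockingCurve
) -> float:
    """Refraction from two images, valid only for scatter-free pixels.

    ``dtheta_r = sigma^2/(t2-t1) * ln(I1/I2) - (t2+t1)/2``.
    """
    (i1, i2), (t1, t2) = intensities, thetas
    if t1 == t2:
        raise ValueError("working points must be distinct")
    if i1 <= 0 or i2 <= 0:
        return float("nan")
    return float(rc.sigma**2 / (t2 - t1) * math.log(i1 / i2) - (t2 + t1) / 2.0)


def retrieve_two_image_absorption_noscatter(
    intensity: float, theta: float, dtheta_r: float, rc: RockingCurve
) -> float:
    """Apparent absorption from one image, assuming no scattering.

    ``I_R = I * exp((theta + dtheta_r)^2 / (2 sigma^2))``.
    """
    return float(intensity * math.exp((theta + dtheta_r) ** 2 / (2.0 * rc.sigma**2)))


def retrieve_two_image_scatter_norefraction(
    intensities: Sequence[float], thetas: Sequence[float], rc: RockingCurve
) -> float:
    """Scattering variance from two images, assuming no refraction.

    ``sigma_s^2 = (t2^2 - t1^2) / (2 ln(I1/I2)) - sigma^2``.  Degenerate
    when ``|t1| == |t2|`` (the log vanishes together with the numerator).
    """
    (i1, i2), (t1, t2) = intensities, thetas
    if i1 <= 0 or i2 <= 0:
        return float("nan")
    if math.isclose(abs(t1), abs(t2)):
        return float("nan")
    log_ratio = math.log(i1 / i2)
    if log_ratio == 0.0:
        return float("nan")
    return float((t2**2 - t1**2) / (2.0 * log_ratio) - rc.sigma**2)


def retrieve_two_image_absorption_norefraction(
    intensity: float, theta: float, scatter_var: float, rc: RockingCurve
) -> float:
    """Apparent absorption from one image, assuming no refraction."""
    total_var = scatter_var + rc.sigma**2
    if not total_var > 0:
        return float("nan")
    return float(
        intensity
        * math.sqrt(total_var)
        / rc.sigma
        * math.exp(theta**2 / (2.0 * total_var))
    )


@dataclass
class ParametricImages:
    """Per-pixel parametric maps retrieved from a three-image stack.

    ``scatter_variance`` keeps the signed values; :attr:`sigma_s` is the
    derived standard-deviation map with negatives clamped to zero.  The
    mask is False wherever the inversion was degenerate or an input
    intensity was nonpositive.
    """

    apparent_absorption: NDArray[np.float64]
    refraction: NDArray[np.float64]
    scatter_variance: NDArray[np.float64]
    mask: NDArray[np.bool_]
    pixel_pitch_um: float | None = None

    @property
    def sigma_s(self) -> NDArray[np.float64]:
        """Scattering width map (microradians); negative variances clamp to 0."""
        return np.sqrt(np.clip(self.scatter_variance, 0.0, None))

    @property
    def negative_variance_fraction(self) -> float:
        """Fraction of valid pixels whose computed variance is negative."""
        valid = self.mask
        if not valid.any():
            return 0.0
        return float((self.scatter_variance[valid] < 0).mean())


def retrieve_parametric_images(
    images: Sequence[NDArray[np.float64]] | NDArray[np.float64],
    working_points: WorkingPoints,
    rc: RockingCurve,
    *,
    absorption_index: int = 2,
    pixel_pitch_um: float | None = None,
) -> ParametricImages:
    """Apply the three-image inversion pixel-wise to co-registered images.

    Parameters
    ----------
    images : sequence of three 2-D arrays
        Normalized intensities at the three working points.
    working_points : WorkingPoints
        The three analyzer offsets, matching the image order.
    rc : RockingCurve
        Analyzer model with width ``sigma``.
    absorption_index : int, optional
        Which of the three images (1-based) to use for the apparent
        absorption; the result is index-independent on noiseless data.
    """
    imgs = [np.asarray(im, dtype=float) for im in images]
    if len(imgs) != 3:
        raise ValueError("exactly three images required")
    if len(working_points) != 3:
        raise ValueError("exactly three working points required")
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise ValueError("images must share one shape")

    t1, t2, t3 = working_points.thetas
    i1, i2, i3 = imgs
    dtheta, svar, valid = _invert_triple(i1, i2, i3, t1, t2, t3, rc.sigma)

    theta_i = working_points.thetas[absorption_index - 1]
    intensity_i = imgs[absorption_index - 1]
    total_var = svar + rc.sigma**2
    with np.errstate(invalid="ignore", over="ignore"):
        i_r = (
            intensity_i
            * np.sqrt(total_var)
            / rc.sigma
            * np.exp((theta_i + dtheta) ** 2 / (2.0 * total_var))
        )
    i_r = np.where(valid, i_r, np.nan)

    n_above = int(np.nansum(i_r[valid] > 1.0)) if valid.any() else 0
    if n_above:
        logger.info(
            "apparent absorption exceeds 1 on %d of %d valid pixels "
            "(expected on noisy background; not clipped)",
            n_above,
            int(valid.sum()),
        )

    return ParametricImages(
        apparent_absorption=i_r,
        refraction=dtheta,
        scatter_variance=svar,
        mask=valid,
        pixel_pitch_um=pixel_pitch_um,
    )
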