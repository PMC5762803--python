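"""Monte Carlo simulator of analyzer-based images of refracting/scattering phantoms.

Photons travel parallel to the beam axis.  Per photon: a transverse
position is diced at the intrinsic resolution; if it crosses a scatter
foil a Gaussian scattering angle is drawn; crossing an absorbing cylinder
it survives a Bernoulli absorption trial and picks up a deterministic
refraction angle from two-interface geometrical optics; finally it is
accepted onto the detector with probability equal to the analyzer
transmission at the summed angular deviation.  Accepted photons are binned
into detector pixels, and images are normalized so that an object-free
pixel has expectation equal to the analyzer transmission at the set
offset.

The simulator shares no code path with the closed-form retrieval, so
agreement between the two is a genuine cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.ndimage import gaussian_filter

from .constants import PMMA_DELTA_17KEV, pmma_mu_per_mm
from .model import RockingCurve, WorkingPoints

__all__ = [
    "CylinderElement",
    "ScatterFoilElement",
    "Phantom",
    "SimulationConfig",
    "ImageStack",
    "cylinder_path_length",
    "cylinder_deflection",
    "simulate_image",
    "simulate_working_point_set",
    "make_simulated_phantom",
    "make_paper_stairway_phantom",
    "SIMULATED_FOIL_SIGMAS_URAD",
]

#: scattering widths (urad) of the 12 reference foils, thinnest to thickest
SIMULATED_FOIL_SIGMAS_URAD = (
    0.0, 0.86, 1.71, 2.57, 3.43, 4.28, 6.42, 8.57, 10.71, 12.85, 17.13, 21.41,
)

#: deflections beyond this are far outside any analyzer acceptance; the
#: divergent sub-micron rim of a cylinder is capped here instead of traced
MAX_DEFLECTION_URAD = 1000.0


@dataclass(frozen=True)
class CylinderElement:
    """Horizontal absorbing/refracting cylinder (axis along x).

    ``mu`` is the linear attenuation in 1/mm, ``delta`` the refractive
    index decrement.
    """

    radius_mm: float
    center_y_mm: float
    mu_per_mm: float
    delta: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        if self.mu_per_mm < 0 or self.delta < 0:
            raise ValueError("mu and delta must be non-negative")


@dataclass(frozen=True)
class ScatterFoilElement:
    """Rectangular foil of homogeneous Gaussian scattering width ``sigma_s``.

    Foils are pure scatterers by default; ``mu_t`` (dimensionless
    attenuation mu*thickness) is available for emulating absorbing layers.
    """

    x_range_mm: tuple[float, float]
    y_range_mm: tuple[float, float]
    sigma_s_urad: float
    mu_t: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_s_urad < 0:
            raise ValueError("sigma_s must be non-negative")
        if self.x_range_mm[0] >= self.x_range_mm[1] or self.y_range_mm[0] >= self.y_range_mm[1]:
            raise ValueError("foil ranges must be non-empty")


@dataclass(frozen=True)
class Phantom:
    """Scene of cylinders and scatter foils inside a rectangular field of view.

    The field of view spans ``[0, width_mm] x [0, height_mm]``; image rows
    map to y (top row = y = 0, increasing downward), columns to x.
    """

    elements: tuple[CylinderElement | ScatterFoilElement, ...]
    width_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("field of view must be non-empty")

    @property
    def cylinders(self) -> tuple[CylinderElement, ...]:
        return tuple(e for e in self.elements if isinstance(e, CylinderElement))

    @property
    def foils(self) -> tuple[ScatterFoilElement, ...]:
        return tuple(e for e in self.elements if isinstance(e, ScatterFoilElement))


@dataclass(frozen=True)
class SimulationConfig:
    """Photon budget, detector geometry and analyzer setting for one run."""

    rc: RockingCurve
    theta_urad: float = 0.0
    photons_per_pixel: int = 10_000
    pixel_pitch_um: float = 14.0
    intrinsic_resolution_um: float = 1.0
    psf_fwhm_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photons_per_pixel <= 0:
            raise ValueError("photon budget must be positive")
        if self.pixel_pitch_um < self.intrinsic_resolution_um:
            raise ValueError("pixel pitch must not be below the intrinsic resolution")


@dataclass
class ImageStack:
    """Co-registered images at several analyzer offsets, plus metadata."""

    images: NDArray[np.float64]  # (n_angles, rows, cols)
    working_points: WorkingPoints
    counts: NDArray[np.int64] | None = None
    pixel_pitch_um: float | None = None

    def __post_init__(self) -> None:
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_angles, rows, cols) array")
        if self.images.shape[0] != len(self.working_points):
            raise ValueError("one working point per image required")


def cylinder_path_length(y_mm, radius_mm: float):
    """Chord length ``2 sqrt(R^2 - y^2)`` through a cylinder, 0 outside."""
    y = np.asarray(y_mm, dtype=float)
    inside = np.abs(y) < radius_mm
    path = np.where(inside, 2.0 * np.sqrt(np.clip(radius_mm**2 - y**2, 0.0, None)), 0.0)
    return float(path) if path.ndim == 0 else path


def cylinder_deflection(y_mm, radius_mm: float, delta: float):
    """Two-interface small-angle deflection in microradians, signed.

    ``2 delta y / sqrt(R^2 - y^2)`` (positive away from the axis for
    y > 0), antisymmetric in y, zero outside the cylinder, capped at
    ``MAX_DEFLECTION_URAD`` near the grazing edge where it diverges.

    Raises
    ------
    ValueError
        For scalar input exactly on the edge ``|y| == R``.
    """
    y = np.asarray(y_mm, dtype=float)
    scalar = y.ndim == 0
    if scalar and abs(float(y)) == radius_mm:
        raise ValueError("deflection is singular exactly at the cylinder edge")
    inside = np.abs(y) < radius_mm
    root = np.sqrt(np.clip(radius_mm**2 - y**2, 1e-300, None))
    defl = np.where(inside, 2.0 * delta * y / root * 1e6, 0.0)
    defl = np.clip(defl, -MAX_DEFLECTION_URAD, MAX_DEFLECTION_URAD)
    return float(defl) if scalar else defl


def _column_rng(seed: int, angle_index: int, col: int) -> np.random.Generator:
    # independent substream per (angle, column): adding angles or columns
    # never perturbs the photons of existing ones
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(angle_index, col))
    )


def _simulate_column(
    phantom: Phantom,
    cfg: SimulationConfig,
    theta: float,
    rng: np.random.Generator,
    x0_mm: float,
    n_rows: int,
) -> NDArray[np.int64]:
    """Accepted-photon counts per pixel row for one detector column."""
    pitch_mm = cfg.pixel_pitch_um / 1000.0
    res_mm = cfg.intrinsic_resolution_um / 1000.0
    height_mm = n_rows * pitch_mm
    n = cfg.photons_per_pixel * n_rows
    x1_mm = x0_mm + pitch_mm
    foils = [
        f for f in phantom.foils
        if f.x_range_mm[0] < x1_mm and f.x_range_mm[1] > x0_mm
    ]

    # transverse position, quantized to the intrinsic resolution grid
    y = rng.uniform(0.0, height_mm, size=n)
    y = (np.floor(y / res_mm) + 0.5) * res_mm
    if foils:
        x = rng.uniform(x0_mm, x1_mm, size=n)
        x = (np.floor(x / res_mm) + 0.5) * res_mm

    # scattering layer: Gaussian draw where the photon crosses a foil
    sigma_s = np.zeros(n)
    mu_t = np.zeros(n)
    for foil in foils:
        hit = (y >= foil.y_range_mm[0]) & (y < foil.y_range_mm[1])
        if foil.x_range_mm[0] > x0_mm or foil.x_range_mm[1] < x1_mm:
            hit &= (x >= foil.x_range_mm[0]) & (x < foil.x_range_mm[1])
        sigma_s[hit] = foil.sigma_s_urad
        if foil.mu_t:
            mu_t[hit] += foil.mu_t
    scattered = sigma_s > 0
    total_angle = np.full(n, theta)
    if scattered.any():
        total_angle[scattered] += rng.normal(0.0, sigma_s[scattered])

    # absorptive/refractive structures (inlined subset math for speed; the
    # public cylinder_* helpers define the same geometry)
    optical_depth = mu_t
    for cyl in phantom.cylinders:
        rel_y = y - cyl.center_y_mm
        inside = np.abs(rel_y) < cyl.radius_mm
        rel_in = rel_y[inside]
        root = np.sqrt(np.maximum(cyl.radius_mm**2 - rel_in**2, 1e-300))
        if cyl.mu_per_mm:
            optical_depth[inside] += cyl.mu_per_mm * 2.0 * root
        if cyl.delta:
            total_angle[inside] += np.clip(
                2.0 * cyl.delta * rel_in / root * 1e6,
                -MAX_DEFLECTION_URAD,
                MAX_DEFLECTION_URAD,
            )

    # survival (absorption) and analyzer acceptance are independent Bernoulli
    # trials; a single uniform against the product probability draws the
    # identical joint distribution with one draw per photon
    log_p = -(total_angle**2) / (2.0 * cfg.rc.sigma**2)
    log_p -= optical_depth
    accepted = rng.uniform(size=n) < np.exp(log_p)

    rows = np.minimum((y[accepted] / pitch_mm).astype(np.int64), n_rows - 1)
    return np.bincount(rows, minlength=n_rows)


def simulate_image(
    phantom: Phantom, cfg: SimulationConfig, *, angle_index: int = 0
) -> tuple[NDArray[np.float64], NDArray[np.int64]]:
    """Simulate one image at the analyzer offset ``cfg.theta_urad``.

    Returns ``(intensity, counts)``: raw accepted-photon counts and the
    normalized image (counts divided by the per-pixel photon budget, so an
    object-free pixel has expectation equal to the analyzer transmission).
    Deterministic for a given seed and configuration.
    """
    pitch_mm = cfg.pixel_pitch_um / 1000.0
    n_rows = max(int(round(phantom.height_mm / pitch_mm)), 1)
    n_cols = max(int(round(phantom.width_mm / pitch_mm)), 1)

    counts = np.empty((n_rows, n_cols), dtype=np.int64)
    for col in range(n_cols):
        rng = _column_rng(cfg.seed, angle_index, col)
        counts[:, col] = _simulate_column(
            phantom, cfg, cfg.theta_urad, rng, col * pitch_mm, n_rows
        )

    intensity = counts / float(cfg.photons_per_pixel)
    if cfg.psf_fwhm_um > 0:
        # source/detector blur applied as a convolution of the generated signal
        sigma_px = cfg.psf_fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0))) / cfg.pixel_pitch_um
        intensity = gaussian_filter(intensity, sigma_px, mode="nearest")
    return intensity, counts


def simulate_working_point_set(
    phantom: Phantom,
    cfg: SimulationConfig,
    working_points: WorkingPoints | Sequence[float],
) -> ImageStack:
    """Simulate one image per working point with independent photon substreams."""
    if not isinstance(working_points, WorkingPoints):
        working_points = WorkingPoints(tuple(working_points))
    images = []
    counts = []
    for idx, theta in enumerate(working_points.thetas):
        img, cnt = simulate_image(
            phantom, replace(cfg, theta_urad=float(theta)), angle_index=idx
        )
        images.append(img)
        counts.append(cnt)
    return ImageStack(
        images=np.stack(images),
        working_points=working_points,
        counts=np.stack(counts),
        pixel_pitch_um=cfg.pixel_pitch_um,
    )


def make_simulated_phantom(
    *,
    rod_diameter_mm: float = 3.6,
    foil_width_mm: float = 2.3,
    foil_height_mm: float = 7.2,
    foil_sigmas_urad: Sequence[float] = SIMULATED_FOIL_SIGMAS_URAD,
    mu_per_mm: float | None = None,
    delta: float = PMMA_DELTA_17KEV,
    margin_mm: float = 0.5,
) -> Phantom:
    """Reference phantom: one horizontal rod crossed by adjacent scatter foils.

    Twelve foils by default, with the reference scattering widths from 0 to
    21.41 urad.  The rod's attenuation defaults to tabulated PMMA at
    17 keV; both ``mu`` and ``delta`` are overridable.
    """
    if mu_per_mm is None:
        mu_per_mm = pmma_mu_per_mm(17.0)
    height = foil_height_mm
    width = len(tuple(foil_sigmas_urad)) * foil_width_mm + 2 * margin_mm
    center_y = height / 2.0
    elements: list[CylinderElement | ScatterFoilElement] = [
        CylinderElement(
            radius_mm=rod_diameter_mm / 2.0,
            center_y_mm=center_y,
            mu_per_mm=mu_per_mm,
            delta=delta,
        )
    ]
    for i, s in enumerate(foil_sigmas_urad):
        x0 = margin_mm + i * foil_width_mm
        elements.append(
            ScatterFoilElement(
                x_range_mm=(x0, x0 + foil_width_mm),
                y_range_mm=(0.0, height),
                sigma_s_urad=float(s),
            )
        )
    return Phantom(tuple(elements), width_mm=width, height_mm=height)


def phantom_to_dict(phantom: Phantom) -> dict:
    """Plain-dict form of a phantom for structured text (YAML) configs."""
    elements = []
    for el in phantom.elements:
        if isinstance(el, CylinderElement):
            elements.append(
                {
                    "type": "cylinder",
                    "radius_mm": el.radius_mm,
                    "center_y_mm": el.center_y_mm,
                    "mu_per_mm": el.mu_per_mm,
                    "delta": el.delta,
                }
            )
        else:
            elements.append(
                {
                    "type": "foil",
                    "x_range_mm": list(el.x_range_mm),
                    "y_range_mm": list(el.y_range_mm),
                    "sigma_s_urad": el.sigma_s_urad,
                    "mu_t": el.mu_t,
                }
            )
    return {
        "width_mm": phantom.width_mm,
        "height_mm": phantom.height_mm,
        "elements": elements,
    }


def phantom_from_dict(data: dict) -> Phantom:
    """Inverse of :func:`phantom_to_dict`."""
    elements: list[CylinderElement | ScatterFoilElement] = []
    for el in data.get("elements", []):
        kind = el.get("type")
        if kind == "cylinder":
            elements.append(
                CylinderElement(
                    radius_mm=float(el["radius_mm"]),
                    center_y_mm=float(el["center_y_mm"]),
                    mu_per_mm=float(el["mu_per_mm"]),
                    delta=float(el["delta"]),
                )
            )
        elif kind == "foil":
            elements.append(
                ScatterFoilElement(
                    x_range_mm=tuple(float(v) for v in el["x_range_mm"]),
                    y_range_mm=tuple(float(v) for v in el["y_range_mm"]),
                    sigma_s_urad=float(el["sigma_s_urad"]),
                    mu_t=float(el.get("mu_t", 0.0)),
                )
            )
        else:
            raise ValueError(f"unknown phantom element type: {kind!r}")
    return Phantom(
        tuple(elements),
        width_mm=float(data["width_mm"]),
        height_mm=float(data["height_mm"]),
    )


def make_paper_stairway_phantom(
    *,
    n_layers_max: int = 6,
    sigma_one_layer_urad: float = 3.0,
    mu_layer_per_mm: float = 0.27,
    layer_thickness_mm: float = 0.1,
    step_width_mm: float = 2.3,
    step_height_mm: float = 7.2,
    blank_width_mm: float = 1.5,
    rod_diameter_mm: float | None = 5.0,
    rod_mu_per_mm: float | None = None,
    rod_delta: float = PMMA_DELTA_17KEV,
) -> Phantom:
    """Stairway of stacked scattering layers, optionally crossed by a rod.

    Step ``n`` (1-based) carries ``n`` layers: scattering width grows as
    ``sigma_one_layer * sqrt(n)`` (widths add in quadrature for stacked
    random scatterers) and transmission falls as
    ``exp(-n * mu_layer * t_layer)``.  Blank strips flank the stairway for
    normalization.
    """
    if n_layers_max < 1:
        raise ValueError("need at least one step")
    height = max(step_height_mm, rod_diameter_mm or 0.0)
    width = 2 * blank_width_mm + n_layers_max * step_width_mm
    y_mid = height / 2.0
    y0 = y_mid - step_height_mm / 2.0
    elements: list[CylinderElement | ScatterFoilElement] = []
    if rod_diameter_mm is not None:
        elements.append(
            CylinderElement(
                radius_mm=rod_diameter_mm / 2.0,
                center_y_mm=y_mid,
                mu_per_mm=(
                    pmma_mu_per_mm(17.0) if rod_mu_per_mm is None else rod_mu_per_mm
                ),
                delta=rod_delta,
            )
        )
    for n in range(1, n_layers_max + 1):
        x0 = blank_width_mm + (n - 1) * step_width_mm
        elements.append(
            ScatterFoilElement(
                x_range_mm=(x0, x0 + step_width_mm),
                y_range_mm=(y0, y0 + step_height_mm),
                sigma_s_urad=sigma_one_layer_urad * math.sqrt(n),
                mu_t=n * mu_layer_per_mm * layer_thickness_mm,
            )
        )
    return Phantom(tuple(elements), width_mm=width, height_mm=height)
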