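"""End-to-end validation experiments: simulate, retrieve, quantify.

Each function runs a complete simulate-and-retrieve experiment on a
built-in phantom and reduces it to the quantities used for validation:
per-foil scattering recovery, refraction linearity, triad robustness,
square-root layer scaling and the multi-angle reference comparison.

Experiment sizes (photon budget, pixel pitch, foil width) are parameters
so the same code runs at quick-test and at full scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .mir import AngleStack, mir_retrieve
from .model import (
    ParametricImages,
    RockingCurve,
    WorkingPoints,
    forward_intensity,
    retrieve_parametric_images,
)
from .rocking import working_point_angle
from .simulate import (
    Phantom,
    SimulationConfig,
    cylinder_deflection,
    make_paper_stairway_phantom,
    make_simulated_phantom,
    simulate_working_point_set,
)

__all__ = [
    "inversion_sweep",
    "FoilRecoveryResult",
    "run_foil_recovery",
    "StairwayResult",
    "run_stairway_experiment",
    "triad_from_fractions",
]


def triad_from_fractions(
    rc: RockingCurve, fractions: tuple[tuple[float, str], ...]
) -> WorkingPoints:
    """Working points from (fraction, side) pairs, e.g. ((0.5,'low'),(1,'peak'),(0.5,'high'))."""
    return WorkingPoints(
        tuple(working_point_angle(rc, f, side) for f, side in fractions)
    )


def inversion_sweep(
    n_tuples: int,
    seed: int = 0,
    *,
    sigma: float = 8.6,
    min_separation_urad: float = 1.0,
) -> dict:
    """Forward-then-invert round trip over random parameter/triad tuples.

    Draws ``I_R in (0, 1]``, ``dtheta_r in [-30, 30]``, scattering variance
    in ``[0, 900]`` and distinct triads within three analyzer widths of the
    peak, and reports the worst relative recovery error of each parameter.
    Fully vectorized.
    """
    rng = np.random.default_rng(seed)
    rc = RockingCurve(sigma=sigma)
    i_r = rng.uniform(0.01, 1.0, n_tuples)
    dtheta = rng.uniform(-30.0, 30.0, n_tuples)
    svar = rng.uniform(0.0, 900.0, n_tuples)
    sigma_s = np.sqrt(svar)

    # distinct triads in +-3 sigma with a minimum pairwise separation so
    # the inversion is well conditioned (degenerate triads are masked by
    # design, not part of the accuracy contract)
    lo = -3.0 * sigma
    span = 6.0 * sigma
    thetas = np.sort(rng.uniform(lo, lo + span, (n_tuples, 3)), axis=1)
    while True:
        bad = (np.diff(thetas, axis=1) < min_separation_urad).any(axis=1)
        if not bad.any():
            break
        thetas[bad] = np.sort(rng.uniform(lo, lo + span, (int(bad.sum()), 3)), axis=1)

    t1, t2, t3 = thetas[:, 0], thetas[:, 1], thetas[:, 2]
    intensities = [
        forward_intensity(i_r, dtheta, sigma_s, t, rc) for t in (t1, t2, t3)
    ]

    from .model import _invert_triple  # shared vectorized kernel

    got_dtheta, got_svar, valid = _invert_triple(*intensities, t1, t2, t3, sigma)
    total_var = got_svar + sigma**2
    got_ir = (
        intensities[1]
        * np.sqrt(total_var)
        / sigma
        * np.exp((t2 + got_dtheta) ** 2 / (2.0 * total_var))
    )

    scale = np.maximum(np.abs(dtheta), 1.0)
    err_dtheta = np.abs(got_dtheta - dtheta) / scale
    err_svar = np.abs(got_svar - svar) / np.maximum(svar, 1.0)
    err_ir = np.abs(got_ir - i_r) / i_r
    return {
        "n": n_tuples,
        "valid_fraction": float(valid.mean()),
        "max_rel_err_refraction": float(np.nanmax(err_dtheta[valid])),
        "max_rel_err_scatter_variance": float(np.nanmax(err_svar[valid])),
        "max_rel_err_absorption": float(np.nanmax(err_ir[valid])),
        "params": (i_r, dtheta, svar, thetas),
    }


def _linear_fit_with_error(x: NDArray, y: NDArray, y_err: NDArray | None = None):
    """Weighted straight-line fit; returns (slope, intercept, slope_err)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_err is None:
        w = np.ones_like(x)
    else:
        w = 1.0 / np.clip(np.asarray(y_err, dtype=float), 1e-12, None) ** 2
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    denom = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sxx * sy - sx * sxy) / denom
    if y_err is None:
        resid = y - (slope * x + intercept)
        dof = max(len(x) - 2, 1)
        s2 = (resid**2).sum() / dof
        slope_err = math.sqrt(s2 * sw / denom)
    else:
        slope_err = math.sqrt(sw / denom)
    return float(slope), float(intercept), float(slope_err)


@dataclass
class FoilRecoveryResult:
    """Reduction of a rod+foils simulate-and-retrieve run."""

    working_points: WorkingPoints
    truth_sigma_s: NDArray[np.float64]
    foil_svar_mean: NDArray[np.float64]
    foil_svar_sem: NDArray[np.float64]
    #: per-pixel spread of the variance estimate inside each foil ROI --
    #: the error bar of a single-pixel measurement
    foil_svar_std: NDArray[np.float64]
    sigma_slope: float
    sigma_slope_err: float
    refraction_truth: NDArray[np.float64]
    refraction_est: NDArray[np.float64]
    refraction_sem: NDArray[np.float64]
    refraction_slope: float
    refraction_slope_err: float
    background_ir_mean: float
    background_ir_sem: float
    background_ir_n: int
    rod_center_transmission: float
    images: ParametricImages

    @property
    def foil_sigma_est(self) -> NDArray[np.float64]:
        return np.sqrt(np.clip(self.foil_svar_mean, 0.0, None))

    @property
    def foil_sigma_sem(self) -> NDArray[np.float64]:
        # error propagation through the square root; foil 0 (zero width)
        # keeps the variance-scale error
        denom = 2.0 * np.clip(self.foil_sigma_est, 1e-3, None)
        return self.foil_svar_sem / denom

    @property
    def foil_sigma_std(self) -> NDArray[np.float64]:
        denom = 2.0 * np.clip(self.foil_sigma_est, 1e-3, None)
        return self.foil_svar_std / denom


def run_foil_recovery(
    *,
    rc: RockingCurve | None = None,
    working_points: WorkingPoints | None = None,
    photons_per_pixel: int = 10_000,
    pixel_pitch_um: float = 36.0,
    foil_width_mm: float = 0.72,
    margin_mm: float = 0.5,
    seed: int = 0,
    refraction_limit_urad: float = 10.0,
) -> FoilRecoveryResult:
    """Simulate the rod+12-foil phantom at a triad and quantify the retrieval.

    Foil scattering widths are measured in bands above and below the rod
    (pure foil, no absorber); refraction linearity is measured in the
    foil-free margins inside the rod, against the pixel-averaged
    geometric deflection.
    """
    rc = rc or RockingCurve(sigma=8.6)
    if working_points is None:
        working_points = triad_from_fractions(
            rc, ((0.5, "low"), (1.0, "peak"), (0.5, "high"))
        )
    phantom = make_simulated_phantom(
        foil_width_mm=foil_width_mm, margin_mm=margin_mm
    )
    cfg = SimulationConfig(
        rc=rc,
        photons_per_pixel=photons_per_pixel,
        pixel_pitch_um=pixel_pitch_um,
        seed=seed,
    )
    stack = simulate_working_point_set(phantom, cfg, working_points)
    result = retrieve_parametric_images(
        list(stack.images), working_points, rc, pixel_pitch_um=pixel_pitch_um
    )

    pitch_mm = pixel_pitch_um / 1000.0
    rod = phantom.cylinders[0]
    rod_top = rod.center_y_mm - rod.radius_mm
    rod_bottom = rod.center_y_mm + rod.radius_mm
    inset = 0.15  # mm kept clear of the rod edge artifact and the FOV rim

    def rows(y0, y1):
        return slice(int(math.ceil(y0 / pitch_mm)), int(y1 / pitch_mm))

    band_rows = [rows(inset, rod_top - inset), rows(rod_bottom + inset, phantom.height_mm - inset)]

    svar = result.scatter_variance
    truth = np.array([f.sigma_s_urad for f in phantom.foils])
    foil_mean = np.empty(len(truth))
    foil_sem = np.empty(len(truth))
    foil_std = np.empty(len(truth))
    for i, foil in enumerate(phantom.foils):
        c0 = int(math.ceil(foil.x_range_mm[0] / pitch_mm)) + 1
        c1 = int(foil.x_range_mm[1] / pitch_mm) - 1
        vals = np.concatenate([svar[r, c0:c1].ravel() for r in band_rows])
        vals = vals[np.isfinite(vals)]
        foil_mean[i] = vals.mean()
        foil_std[i] = vals.std(ddof=1)
        foil_sem[i] = foil_std[i] / math.sqrt(vals.size)

    sigma_est = np.sqrt(np.clip(foil_mean, 0.0, None))
    # slope fitted against the single-pixel error bars (ROI spread), the
    # error bars the recovery claim is stated against
    sigma_std = foil_std / (2.0 * np.clip(sigma_est, 1e-3, None))
    nonzero = truth > 0
    sigma_slope, _, sigma_slope_err = _linear_fit_with_error(
        truth[nonzero], sigma_est[nonzero], sigma_std[nonzero]
    )

    # refraction linearity in the foil-free margins
    margin_cols = np.r_[
        1 : int(margin_mm / pitch_mm) - 1,
        result.refraction.shape[1] - int(margin_mm / pitch_mm) + 1 : result.refraction.shape[1] - 1,
    ]
    n_rows = result.refraction.shape[0]
    sub = 8  # sub-pixel samples for the pixel-averaged geometric truth
    truth_rows = []
    est_rows = []
    sem_rows = []
    for r in range(n_rows):
        y = (r + (np.arange(sub) + 0.5) / sub) * pitch_mm - rod.center_y_mm
        if np.any(np.abs(y) >= rod.radius_mm):
            continue
        t = float(np.mean(cylinder_deflection(y, rod.radius_mm, rod.delta)))
        if abs(t) > refraction_limit_urad:
            continue
        vals = result.refraction[r, margin_cols]
        vals = vals[np.isfinite(vals)]
        if vals.size < 4:
            continue
        truth_rows.append(t)
        est_rows.append(vals.mean())
        sem_rows.append(vals.std(ddof=1) / math.sqrt(vals.size))
    refraction_truth = np.array(truth_rows)
    refraction_est = np.array(est_rows)
    refraction_sem = np.array(sem_rows)
    refr_slope, _, refr_slope_err = _linear_fit_with_error(
        refraction_truth, refraction_est, refraction_sem
    )

    # object-free background: margins, outside the rod
    ir = result.apparent_absorption
    bg = np.concatenate([ir[r][:, margin_cols].ravel() for r in band_rows])
    bg = bg[np.isfinite(bg)]
    bg_mean = float(bg.mean())
    bg_sem = float(bg.std(ddof=1) / math.sqrt(bg.size))

    center_row = int(rod.center_y_mm / pitch_mm)
    rod_center = ir[center_row - 1 : center_row + 2][:, margin_cols]
    rod_center_transmission = float(np.nanmean(rod_center))

    return FoilRecoveryResult(
        working_points=working_points,
        truth_sigma_s=truth,
        foil_svar_mean=foil_mean,
        foil_svar_sem=foil_sem,
        foil_svar_std=foil_std,
        sigma_slope=sigma_slope,
        sigma_slope_err=sigma_slope_err,
        refraction_truth=refraction_truth,
        refraction_est=refraction_est,
        refraction_sem=refraction_sem,
        refraction_slope=refr_slope,
        refraction_slope_err=refr_slope_err,
        background_ir_mean=bg_mean,
        background_ir_sem=bg_sem,
        background_ir_n=int(bg.size),
        rod_center_transmission=rod_center_transmission,
        images=result,
    )


@dataclass
class StairwayResult:
    """Reduction of a stairway simulate-and-retrieve run with MIR reference."""

    n_layers: NDArray[np.int_]
    triad_sigma: NDArray[np.float64]
    triad_sigma_sem: NDArray[np.float64]
    triad_sigma_std: NDArray[np.float64]
    mir_sigma: NDArray[np.float64]
    mir_sigma_sem: NDArray[np.float64]
    mir_sigma_std: NDArray[np.float64]
    sqrt_exponent: float
    sqrt_exponent_err: float
    sigma_one_layer: float


def run_stairway_experiment(
    *,
    rc: RockingCurve | None = None,
    sigma_one_layer_urad: float = 3.0,
    photons_per_pixel: int = 2000,
    pixel_pitch_um: float = 56.0,
    step_width_mm: float = 1.2,
    blank_width_mm: float = 0.8,
    n_mir_angles: int = 30,
    seed: int = 0,
) -> StairwayResult:
    """Stairway recovery: three-image triad plus an N-angle reference stack.

    Returns per-step scattering widths from both retrievals and the fitted
    exponent of width versus layer count (0.5 when widths add in
    quadrature).
    """
    rc = rc or RockingCurve(sigma=8.6)
    phantom = make_paper_stairway_phantom(
        sigma_one_layer_urad=sigma_one_layer_urad,
        step_width_mm=step_width_mm,
        blank_width_mm=blank_width_mm,
    )
    triad = triad_from_fractions(rc, ((0.5, "low"), (1.0, "peak"), (0.5, "high")))
    cfg = SimulationConfig(
        rc=rc,
        photons_per_pixel=photons_per_pixel,
        pixel_pitch_um=pixel_pitch_um,
        seed=seed,
    )
    stack3 = simulate_working_point_set(phantom, cfg, triad)
    triad = retrieve_parametric_images(list(stack3.images), triad, rc)

    mir_angles = np.linspace(-3.0 * rc.sigma, 3.0 * rc.sigma, n_mir_angles)
    mir_stack = simulate_working_point_set(phantom, cfg, tuple(mir_angles))
    mir_res = mir_retrieve(AngleStack.from_image_stack(mir_stack), rc)

    pitch_mm = pixel_pitch_um / 1000.0
    rod = phantom.cylinders[0] if phantom.cylinders else None
    foils = phantom.foils
    # bands of pure stairway above/below the rod
    inset = 0.15
    if rod is not None:
        spans = [
            (inset, rod.center_y_mm - rod.radius_mm - inset),
            (rod.center_y_mm + rod.radius_mm + inset, phantom.height_mm - inset),
        ]
    else:
        spans = [(inset, phantom.height_mm - inset)]
    # clip to the stairway's own vertical extent
    y_lo = min(f.y_range_mm[0] for f in foils)
    y_hi = max(f.y_range_mm[1] for f in foils)
    band_rows = []
    for lo, hi in spans:
        lo, hi = max(lo, y_lo + inset), min(hi, y_hi - inset)
        if hi > lo:
            band_rows.append(
                slice(int(math.ceil(lo / pitch_mm)), int(hi / pitch_mm))
            )

    def per_step(svar_map):
        means = np.empty(len(foils))
        sems = np.empty(len(foils))
        stds = np.empty(len(foils))
        for i, foil in enumerate(foils):
            c0 = int(math.ceil(foil.x_range_mm[0] / pitch_mm)) + 1
            c1 = int(foil.x_range_mm[1] / pitch_mm) - 1
            vals = np.concatenate([svar_map[r, c0:c1].ravel() for r in band_rows])
            vals = vals[np.isfinite(vals)]
            means[i] = vals.mean()
            stds[i] = vals.std(ddof=1)
            sems[i] = stds[i] / math.sqrt(vals.size)
        sigma = np.sqrt(np.clip(means, 0.0, None))
        denom = 2.0 * np.clip(sigma, 1e-3, None)
        return sigma, sems / denom, stds / denom

    triad_sigma, triad_sem, triad_std = per_step(triad.scatter_variance)
    mir_sigma, mir_sem, mir_std = per_step(mir_res.scatter_variance)

    n_layers = np.arange(1, len(foils) + 1)
    # log-log straight line: exponent of sigma ~ n**b
    log_err = triad_sem / np.clip(triad_sigma, 1e-6, None)
    exponent, _, exponent_err = _linear_fit_with_error(
        np.log(n_layers), np.log(np.clip(triad_sigma, 1e-6, None)), log_err
    )

    return StairwayResult(
        n_layers=n_layers,
        triad_sigma=triad_sigma,
        triad_sigma_sem=triad_sem,
        triad_sigma_std=triad_std,
        mir_sigma=mir_sigma,
        mir_sigma_sem=mir_sem,
        mir_sigma_std=mir_std,
        sqrt_exponent=exponent,
        sqrt_exponent_err=exponent_err,
        sigma_one_layer=sigma_one_layer_urad,
    )
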