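"""Multiple-image retrieval: per-pixel Gaussian fit over many analyzer angles.

Sampling the full local rocking curve at N >= 4 analyzer offsets and
fitting a Gaussian per pixel gives an independent estimate of the same
three parameters the closed-form three-image inversion produces — the
precision reference against which the fast method is validated.

The per-pixel fits are performed with a vectorized Gauss-Newton iteration
over all pixels at once (moments initialization); on a single pixel the
result matches :func:`abiret.rocking.fit_gaussian`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .model import RockingCurve, WorkingPoints
from .simulate import ImageStack

__all__ = ["AngleStack", "MIRResult", "mir_retrieve"]


@dataclass(frozen=True)
class AngleStack:
    """N >= 4 co-registered images at strictly increasing analyzer offsets."""

    images: NDArray[np.float64]  # (n_angles, rows, cols)
    thetas: NDArray[np.float64]

    def __post_init__(self) -> None:
        imgs = np.asarray(self.images, dtype=float)
        thetas = np.asarray(self.thetas, dtype=float)
        object.__setattr__(self, "images", imgs)
        object.__setattr__(self, "thetas", thetas)
        if imgs.ndim != 3:
            raise ValueError("images must be (n_angles, rows, cols)")
        if thetas.ndim != 1 or thetas.shape[0] != imgs.shape[0]:
            raise ValueError("one angle per image required")
        if thetas.shape[0] < 4:
            raise ValueError("at least 4 angles required")
        if np.any(np.diff(thetas) <= 0):
            raise ValueError("angles must be strictly increasing")

    @classmethod
    def from_image_stack(cls, stack: ImageStack) -> "AngleStack":
        thetas = np.asarray(stack.working_points.thetas, dtype=float)
        order = np.argsort(thetas)
        return cls(stack.images[order], thetas[order])


@dataclass
class MIRResult:
    """Per-pixel Gaussian-fit maps and derived parametric images.

    ``sigma_m`` is the fitted width of the local curve; the scattering
    variance is ``sigma_m^2 - sigma^2`` and the apparent absorption is
    ``amplitude * sigma_m / sigma`` (unity on object-free pixels).
    """

    amplitude: NDArray[np.float64]
    refraction: NDArray[np.float64]
    sigma_m: NDArray[np.float64]
    scatter_variance: NDArray[np.float64]
    apparent_absorption: NDArray[np.float64]
    residual_norm: NDArray[np.float64]
    mask: NDArray[np.bool_]

    @property
    def sigma_s(self) -> NDArray[np.float64]:
        return np.sqrt(np.clip(self.scatter_variance, 0.0, None))


def _moments_init(thetas, data):
    """Weighted-moment starting values per pixel; data is (n_angles, n_pix)."""
    w = np.clip(data, 0.0, None)
    total = w.sum(axis=0)
    total = np.where(total > 0, total, 1.0)
    center = (thetas[:, None] * w).sum(axis=0) / total
    spread = np.sqrt(((thetas[:, None] - center) ** 2 * w).sum(axis=0) / total)
    span = float(np.ptp(thetas))
    spread = np.where(spread > 1e-3, spread, span / 4.0)
    return data.max(axis=0), center, spread


def _gauss_newton(thetas, data, n_iter=60, tol=1e-12):
    """Fit A*exp(-(t-c)^2/(2 s^2)) per pixel, all pixels at once.

    Returns (A, c, s, residual_norm, converged).  Damped Gauss-Newton with
    per-pixel step halving; pixels that go non-finite are frozen and
    reported unconverged.
    """
    amp, cen, sig = _moments_init(thetas, data)
    amp = amp.astype(float).copy()
    cen = cen.astype(float).copy()
    sig = sig.astype(float).copy()
    n_pix = data.shape[1]
    t = thetas[:, None]

    def residuals(a, c, s):
        model = a * np.exp(-((t - c) ** 2) / (2.0 * s**2))
        return model - data, model

    res, model = residuals(amp, cen, sig)
    cost = (res**2).sum(axis=0)
    converged = np.zeros(n_pix, dtype=bool)
    for _ in range(n_iter):
        active = ~converged
        if not active.any():
            break
        # Jacobian of the Gaussian in (A, c, s)
        d = t - cen
        j_a = model / np.where(amp != 0, amp, 1.0)
        j_c = model * d / sig**2
        j_s = model * d**2 / sig**3
        # normal equations per pixel (3x3), built explicitly
        jtj = np.empty((n_pix, 3, 3))
        cols = (j_a, j_c, j_s)
        for i in range(3):
            for j in range(i, 3):
                jtj[:, i, j] = jtj[:, j, i] = (cols[i] * cols[j]).sum(axis=0)
        jtr = np.stack([(c_ * res).sum(axis=0) for c_ in cols], axis=1)
        # Levenberg damping keeps ill-conditioned pixels stable
        diag = np.arange(3)
        jtj[:, diag, diag] += 1e-10 * np.maximum(jtj[:, diag, diag], 1e-30)
        try:
            step = np.linalg.solve(jtj, jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(m, r, rcond=None)[0] for m, r in zip(jtj, jtr)]
            )
        new_amp = amp - step[:, 0]
        new_cen = cen - step[:, 1]
        new_sig = np.abs(sig - step[:, 2])
        new_res, new_model = residuals(new_amp, new_cen, new_sig)
        new_cost = (new_res**2).sum(axis=0)
        ok = np.isfinite(new_cost) & (new_cost <= cost) & (new_sig > 0)
        improve = ok & active
        amp = np.where(improve, new_amp, amp)
        cen = np.where(improve, new_cen, cen)
        sig = np.where(improve, new_sig, sig)
        model = np.where(improve, new_model, model)
        res = np.where(improve, new_res, res)
        newly = active & ok & (cost - new_cost <= tol * np.maximum(cost, 1e-300))
        cost = np.where(improve, new_cost, cost)
        converged |= newly
    # pixels still active but finite stopped at a (near-)stationary point;
    # only genuinely broken fits stay unconverged
    converged |= np.isfinite(cost) & np.isfinite(amp) & np.isfinite(cen) & (sig > 0)
    return amp, cen, sig, np.sqrt(cost), converged


def mir_retrieve(stack: AngleStack, rc: RockingCurve) -> MIRResult:
    """Per-pixel Gaussian fit of the local rocking curve.

    Masks pixels whose peak intensity is nonpositive, whose fit failed, or
    whose fitted center lies outside the sampled angular range (no
    extrapolation).
    """
    thetas = stack.thetas
    n_angles, rows, cols = stack.images.shape
    data = stack.images.reshape(n_angles, rows * cols)

    fit_ok = data.max(axis=0) > 0
    amp, cen, sig, resnorm, converged = _gauss_newton(thetas, data)
    in_range = (cen >= thetas[0]) & (cen <= thetas[-1])
    mask = fit_ok & converged & in_range & (sig > 0) & np.isfinite(amp)

    scatter_var = sig**2 - rc.sigma**2
    i_r = amp * sig / rc.sigma
    shape = (rows, cols)

    def _map(v):
        return np.where(mask, v, np.nan).reshape(shape)

    return MIRResult(
        amplitude=_map(amp),
        refraction=_map(-cen),
        sigma_m=_map(sig),
        scatter_variance=_map(scatter_var),
        apparent_absorption=_map(i_r),
        residual_norm=resnorm.reshape(shape),
        mask=mask.reshape(shape),
    )


def synthesize_stack(
    i_r, dtheta_r, sigma_s, thetas, rc: RockingCurve
) -> AngleStack:
    """Noiseless stack from the closed-form model (testing convenience).

    ``i_r``/``dtheta_r``/``sigma_s`` are 2-D maps (or scalars broadcast to
    1x1); one image per angle in ``thetas``.
    """
    from .model import forward_intensity

    i_r = np.atleast_2d(np.asarray(i_r, dtype=float))
    dtheta_r = np.broadcast_to(np.asarray(dtheta_r, dtype=float), i_r.shape)
    sigma_s = np.broadcast_to(np.asarray(sigma_s, dtype=float), i_r.shape)
    thetas = np.sort(np.asarray(thetas, dtype=float))
    images = np.stack(
        [forward_intensity(i_r, dtheta_r, sigma_s, t, rc) for t in thetas]
    )
    return AngleStack(images, thetas)
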