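"""Sum-of-Gaussians filament models, analytic gradients and solvers.

A filament's intensity footprint is modelled as a chain of 2D Gaussians of
PSF width placed at equal arc spacing ``ds`` along a path — a straight line
for stabilized seeds, a 3rd-order polynomial for dynamic microtubules —
with one shared amplitude ``A`` plus a constant background ``Bg``:

    F_i = A * (G_start,i + G_1,i + ... + G_end,i) + Bg
    G_j,i = exp(-(ix - mx_j)^2 / sx^2 - (iy - my_j)^2 / sy^2)

The chi-squared objective sum_i (I_i - F_i)^2 is minimized with a
Levenberg-Marquardt solver fed analytic derivatives.  For the polynomial
path the slope coefficient m is eliminated through the two endpoints, so
the path always passes through both; the Gaussian placement steps the
path parameter by ds / sqrt(1 + y'(x)^2) and the gradients are propagated
exactly through that recursion (they reduce to the straight-path
expressions when curvature and inflection vanish).

Endpoints are finally refined with an iterative two-Gaussian mask fit
(tip Gaussian plus one neighbour displaced ``ds`` inward) whose residual
inward bias is cancelled against the same fit run on the noiseless fitted
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import ClassVar

import numpy as np

__all__ = [
    "dense_model_image",
    "LineSoGModel",
    "PolySoGModel",
    "LMConfig",
    "LMResult",
    "lm_minimize",
    "fit_model",
    "gaussian_mask_refine",
    "MaskFitResult",
    "contour_length",
]


# ---------------------------------------------------------------------------
# line model


@dataclass
class LineSoGModel:
    """Gaussian chain along a fixed line direction.

    Free parameters (theta): ``[xs, ys, xe, ye, ds, A, Bg]``.  A chain of
    J + 1 Gaussians, J = round(|end - start| / ds), is spread evenly from
    the start point to the end point (realized spacing |e - s| / J ~ ds),
    so both tips are chain members and the intensity density is uniform up
    to the very ends.  ``ds`` acts through the count J only.  ``sigma`` is
    the PSF width (sx, sy) and is not fit; ``direction`` records the
    initial orientation for window geometry.
    """

    direction: np.ndarray          # fixed unit vector (dx, dy)
    sigma: tuple[float, float]
    fixed_J: int | None = None     # freeze the chain count (smooth polish)
    n_params: int = 7
    amp_index: ClassVar[int] = 5   # position of A in theta
    ds_index: ClassVar[int] = 4

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("direction must be a nonzero vector")
        self.direction = d / n

    # theta = [xs, ys, xe, ye, ds, A, Bg]
    def _count(self, theta: np.ndarray) -> int:
        xs, ys, xe, ye, ds = theta[:5]
        if ds <= 0:
            raise ValueError("ds must be positive")
        r = math.hypot(xe - xs, ye - ys)
        J = self.fixed_J or max(int(round(r / ds)), 1)
        if J > 1000:
            raise ValueError("chain too long for spacing ds")
        return J

    def chain(self, theta: np.ndarray) -> np.ndarray:
        """J+1 Gaussians spread evenly from start to end (spacing ~ ds)."""
        xs, ys, xe, ye = theta[:4]
        J = self._count(theta)
        t = (np.arange(J + 1) / J)[:, None]
        p0 = np.array([xs, ys])
        p1 = np.array([xe, ye])
        return p0 + t * (p1 - p0)

    def model(self, theta: np.ndarray, X: np.ndarray, Y: np.ndarray
              ) -> np.ndarray:
        F, _ = self._eval(theta, X, Y, want_jac=False)
        return F

    def jac(self, theta, X, Y):
        return self._eval(theta, X, Y, want_jac=True)

    def _eval(self, theta, X, Y, want_jac: bool):
        xs, ys, xe, ye, ds, A, Bg = theta
        sx, sy = self.sigma
        mu = self.chain(theta)                       # (J+1, 2)
        dx = X[None, :] - mu[:, 0:1]                 # (J+1, npix)
        dy = Y[None, :] - mu[:, 1:2]
        G = np.exp(-(dx**2) / sx**2 - (dy**2) / sy**2)
        S = G.sum(axis=0)
        F = A * S + Bg
        if not want_jac:
            return F, None
        J = len(mu) - 1
        # mu_j = mu_s + (j/J)(mu_e - mu_s): linear in both endpoints
        t = (np.arange(J + 1) / J)[:, None]          # (J+1, 1)
        gx = dx / sx**2
        gy = dy / sy**2
        D = np.empty((7, X.size))
        D[0] = 2 * A * ((1.0 - t) * gx * G).sum(axis=0)     # d/dxs
        D[1] = 2 * A * ((1.0 - t) * gy * G).sum(axis=0)     # d/dys
        D[2] = 2 * A * (t * gx * G).sum(axis=0)             # d/dxe
        D[3] = 2 * A * (t * gy * G).sum(axis=0)             # d/dye
        # ds only selects the count J = round(dist/ds): piecewise constant
        D[4] = 0.0
        D[5] = S                                            # d/dA
        D[6] = 1.0                                          # d/dBg
        return F, D


# ---------------------------------------------------------------------------
# polynomial model


@dataclass
class PolySoGModel:
    """Gaussian chain along a cubic path with the start point fixed.

    Free parameters (theta): ``[xe, ye, ds, A, Bg, b, I]``.  The path
    my = I mx^3 + b mx^2 + m mx + c passes through the fixed start (the
    seed end) and the free end point; m is eliminated via the endpoints,

        m = (ye - ys)/(xe - xs) - b (xe + xs) - I (xs^2 + xe^2 + xs xe),

    and c follows from the start point.  Setting b = I = 0 reduces the
    model to the straight chain through the two endpoints.
    """

    start: tuple[float, float]     # fixed seed end (xs, ys)
    sigma: tuple[float, float]
    fixed_J: int | None = None
    n_params: int = 7
    amp_index: ClassVar[int] = 3
    ds_index: ClassVar[int] = 2

    def m_c(self, theta: np.ndarray) -> tuple[float, float]:
        xe, ye, ds, A, Bg, b, I3 = theta
        xs, ys = self.start
        dxe = xe - xs
        if abs(dxe) < 1e-9:
            raise ValueError("degenerate endpoints: fit in the swapped frame")
        m = (ye - ys) / dxe - b * (xe + xs) - I3 * (xs**2 + xe**2 + xs * xe)
        c = ys - I3 * xs**3 - b * xs**2 - m * xs
        return m, c

    def path_y(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        m, c = self.m_c(theta)
        _, _, _, _, _, b, I3 = theta
        return I3 * x**3 + b * x**2 + m * x + c

    def chain(self, theta: np.ndarray) -> np.ndarray:
        xj, _ = self._chain_with_partials(theta, want_partials=False)
        m, c = self.m_c(theta)
        xe, ye, ds, A, Bg, b, I3 = theta
        yj = I3 * xj**3 + b * xj**2 + m * xj + c
        return np.stack([xj, yj], axis=1)

    def _chain_with_partials(self, theta, want_partials: bool):
        """Chain x-coordinates and (optionally) d x_j / d theta_k.

        The placement recursion is x_{j+1} = x_j + sgn * ds / sqrt(1+s^2)
        with s(x) = 3 I x^2 + 2 b x + m; partials w.r.t. (xe, ye, ds, b, I)
        are propagated through it exactly.
        """
        xe, ye, ds, A, Bg, b, I3 = theta
        if ds <= 0:
            raise ValueError("ds must be positive")
        xs, ys = self.start
        m, _ = self.m_c(theta)
        dxe = xe - xs
        sgn = 1.0 if dxe >= 0 else -1.0
        dist = math.hypot(dxe, ye - ys)
        J = self.fixed_J or max(int(math.ceil(dist / ds)), 1)
        if J > 1000:
            raise ValueError("chain too long for spacing ds")

        # partials of m w.r.t. (xe, ye, b, I)
        dm_dxe = -(ye - ys) / dxe**2 - b - I3 * (2 * xe + xs)
        dm_dye = 1.0 / dxe
        dm_db = -(xe + xs)
        dm_dI = -(xs**2 + xe**2 + xs * xe)

        xj = np.empty(J)
        xj[0] = xs
        if want_partials:
            # columns: d/dxe, d/dye, d/dds, d/db, d/dI
            P = np.zeros((J, 5))
        x = xs
        px = np.zeros(5)
        for k in range(1, J):
            s = 3 * I3 * x**2 + 2 * b * x + m
            w = math.sqrt(1.0 + s * s)
            if want_partials:
                # du/dx and explicit du/dtheta for u = sgn*ds/w
                ds_dx = 6 * I3 * x + 2 * b
                pref = -sgn * ds * s / w**3
                du_dx = pref * ds_dx
                du = np.array([
                    pref * dm_dxe,                      # via m(xe)
                    pref * dm_dye,                      # via m(ye)
                    sgn / w,                            # explicit ds
                    pref * (2 * x + dm_db),             # via s(b) and m(b)
                    pref * (3 * x**2 + dm_dI),          # via s(I) and m(I)
                ])
                px = px * (1.0 + du_dx) + du
                P[k] = px
            x = x + sgn * ds / w
            xj[k] = x
        return (xj, P if want_partials else None)

    def model(self, theta, X, Y):
        F, _ = self._eval(theta, X, Y, want_jac=False)
        return F

    def jac(self, theta, X, Y):
        return self._eval(theta, X, Y, want_jac=True)

    def _eval(self, theta, X, Y, want_jac: bool):
        xe, ye, ds, A, Bg, b, I3 = theta
        xs, ys = self.start
        sx, sy = self.sigma
        m, c = self.m_c(theta)
        xj, P = self._chain_with_partials(theta, want_partials=want_jac)
        yj = I3 * xj**3 + b * xj**2 + m * xj + c
        dx = X[None, :] - xj[:, None]
        dy = Y[None, :] - yj[:, None]
        G = np.exp(-(dx**2) / sx**2 - (dy**2) / sy**2)
        ge_dx, ge_dy = X - xe, Y - ye
        Ge = np.exp(-(ge_dx**2) / sx**2 - (ge_dy**2) / sy**2)
        S = G.sum(axis=0) + Ge
        F = A * S + Bg
        if not want_jac:
            return F, None

        dxe = xe - xs
        dm_dxe = -(ye - ys) / dxe**2 - b - I3 * (2 * xe + xs)
        dm_dye = 1.0 / dxe
        dm_db = -(xe + xs)
        dm_dI = -(xs**2 + xe**2 + xs * xe)
        # c = ys - I xs^3 - b xs^2 - m xs depends on theta via m, b, I
        slope = 3 * I3 * xj**2 + 2 * b * xj + m     # s(x_j)

        # d y_j / d theta_k = s(x_j) dx_j/dtheta + explicit path terms
        def dy_k(col: int, dm: float, extra: np.ndarray | float) -> np.ndarray:
            dxj = P[:, col]
            return slope * dxj + dm * (xj - xs) + extra

        dyj = {
            "xe": dy_k(0, dm_dxe, 0.0),
            "ye": dy_k(1, dm_dye, 0.0),
            "ds": dy_k(2, 0.0, 0.0),
            "b": dy_k(3, dm_db, xj**2 - xs**2),
            "I": dy_k(4, dm_dI, xj**3 - xs**3),
        }
        dxj = {"xe": P[:, 0], "ye": P[:, 1], "ds": P[:, 2],
               "b": P[:, 3], "I": P[:, 4]}

        D = np.empty((7, X.size))
        for col, key in enumerate(("xe", "ye", "ds")):
            D[col] = 2 * A * ((dx * dxj[key][:, None] / sx**2
                               + dy * dyj[key][:, None] / sy**2) * G).sum(axis=0)
        # the end-tip Gaussian moves with (xe, ye) directly
        D[0] += (2 * A / sx**2) * ge_dx * Ge
        D[1] += (2 * A / sy**2) * ge_dy * Ge
        D[3] = S
        D[4] = 1.0
        for col, key in ((5, "b"), (6, "I")):
            D[col] = 2 * A * ((dx * dxj[key][:, None] / sx**2
                               + dy * dyj[key][:, None] / sy**2) * G).sum(axis=0)
        return F, D


# ---------------------------------------------------------------------------
# Levenberg-Marquardt


@dataclass
class LMConfig:
    damping0: float = 1e-3
    damping_factor: float = 10.0
    chi2_rtol: float = 1e-10
    step_tol: float = 1e-4
    max_iter: int = 100


@dataclass
class LMResult:
    theta: np.ndarray
    chi2: float
    n_iter: int
    converged: bool
    chi2_history: list[float]


def lm_minimize(fun_jac, theta0: np.ndarray, config: LMConfig | None = None,
                validate=None, free_mask: np.ndarray | None = None
                ) -> LMResult:
    """Minimize sum_i f_i(theta)^2 where fun_jac returns (f, dF/dtheta).

    ``f = I - F`` so the gradient is g = -2 J^T f and the Gauss-Newton
    Hessian (second-order term dropped) is H = 2 J^T J; the step solves
    (H + mu diag(H)) delta = -g.  The damping mu shrinks by
    ``damping_factor`` after an accepted step and grows after a rejected
    one, so chi-squared never increases over accepted steps.
    """
    if config is None:
        config = LMConfig()
    theta = np.asarray(theta0, dtype=float).copy()
    if free_mask is None:
        free_mask = np.ones(theta.size, dtype=bool)
    free = np.asarray(free_mask, dtype=bool)
    f, Jm = fun_jac(theta)
    Jm = Jm[free]
    chi2 = float(f @ f)
    mu = config.damping0
    history = [chi2]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        g = -2.0 * (Jm @ f)
        H = 2.0 * (Jm @ Jm.T)
        dH = np.maximum(np.diag(H), 1e-12)
        accepted = False
        for _ in range(25):
            try:
                delta = np.linalg.solve(H + mu * np.diag(dH), -g)
            except np.linalg.LinAlgError:
                mu *= config.damping_factor
                continue
            cand = theta.copy()
            cand[free] = cand[free] + delta
            if validate is not None and not validate(cand):
                mu *= config.damping_factor
                continue
            try:
                f_new, J_new = fun_jac(cand)
            except (ValueError, FloatingPointError):
                mu *= config.damping_factor
                continue
            chi2_new = float(f_new @ f_new)
            if not np.isfinite(chi2_new) or chi2_new > chi2:
                mu *= config.damping_factor
                continue
            accepted = True
            J_new = J_new[free]
            break
        if not accepted:
            converged = True  # no further descent possible at max damping
            break
        dchi = chi2 - chi2_new
        theta, f, Jm, chi2 = cand, f_new, J_new, chi2_new
        history.append(chi2)
        mu = max(mu / config.damping_factor, 1e-14)
        if (dchi <= config.chi2_rtol * max(chi2, 1e-300)
                or float(np.linalg.norm(delta)) < config.step_tol):
            converged = True
            break
    return LMResult(theta=theta, chi2=chi2, n_iter=n_iter,
                    converged=converged, chi2_history=history)


def fit_model(model, theta0, image, window, config: LMConfig | None = None,
              validate=None, free_mask=None) -> LMResult:
    """Fit a SoG model to ``image`` over a window (x0, y0, x1, y1)."""
    x0, y0, x1, y1 = window
    h, w = image.shape
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    X, Y = np.meshgrid(np.arange(x0, x1, dtype=float),
                       np.arange(y0, y1, dtype=float))
    X, Y = X.ravel(), Y.ravel()
    I = np.asarray(image, dtype=float)[y0:y1, x0:x1].ravel()

    def fun_jac(theta):
        F, D = model.jac(theta, X, Y)
        return I - F, D

    if validate is None:
        smin = min(model.sigma)
        kds, ka = model.ds_index, model.amp_index
        def validate(th):  # noqa: E731 - default parameter sanity
            return 0.15 * smin < th[kds] < 50.0 * smin and th[ka] > 0
    return lm_minimize(fun_jac, theta0, config, validate=validate,
                       free_mask=free_mask)


def fit_model_multiscale(model, theta0, image, window,
                         config: LMConfig | None = None,
                         blur_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0),
                         validate=None,
                         free_mask: np.ndarray | None = None,
                         polish_rounds: int = 5,
                         scan: tuple[float, float] = (3.0, 0.25)
                         ) -> LMResult:
    """Coarse-to-fine fit with a Gaussian scale-space cascade.

    Near-diffraction-limited PSFs give the chi-squared objective a capture
    radius of only ~1 sigma in the endpoint coordinates.  Each stage blurs
    the *data* with a Gaussian of std ``s_b`` and fits the model with the
    correspondingly widened PSF (sigma_eff = sqrt(sigma^2 + 2 s_b^2) in the
    exp(-d^2/sigma^2) convention), so the blurred image stays an exact
    member of the model family while the basin of attraction widens; the
    final stage (s_b = 0) fits the original image with the true PSF.

    The spacing ``ds`` is held at its initial value during the blurred
    stages (it trades off against A in a flat valley and the chain count
    J = ceil(dist/ds) is discontinuous in it); the final stage first runs
    with the native piecewise objective and then polishes with J frozen,
    re-deriving J until self-consistent, so the smooth within-cell optimum
    is reached.
    """
    from dataclasses import replace

    from scipy.ndimage import gaussian_filter

    sx, sy = model.sigma
    theta = np.asarray(theta0, dtype=float).copy()
    res = None
    prev_area = sx * sy
    if validate is None:
        smin = min(sx, sy)   # bounds follow the true PSF, not the blur
        kds, ka = model.ds_index, model.amp_index
        def validate(th):  # noqa: E731
            return 0.15 * smin < th[kds] < 50.0 * smin and th[ka] > 0
    base_free = (np.ones(model.n_params, dtype=bool) if free_mask is None
                 else np.asarray(free_mask, dtype=bool).copy())
    no_ds = base_free.copy()
    no_ds[model.ds_index] = False
    for i, s_b in enumerate(blur_sigmas):
        img_s = gaussian_filter(np.asarray(image, dtype=float), s_b) \
            if s_b > 0 else image
        sig_eff = (math.sqrt(sx**2 + 2 * s_b**2),
                   math.sqrt(sy**2 + 2 * s_b**2))
        m_s = replace(model, sigma=sig_eff)
        # blurring preserves each Gaussian's integral: rescale amplitude
        area = sig_eff[0] * sig_eff[1]
        theta[model.amp_index] *= prev_area / area
        prev_area = area
        res = fit_model(m_s, theta, img_s, window, config, validate=validate,
                        free_mask=no_ds)
        theta = res.theta
        if i == max(len(blur_sigmas) - 2, 0):
            # a tip slid along the filament axis sits on a nearly flat
            # chi-squared plateau; resolve it with an explicit 1D scan per
            # free endpoint.  Run it on this mildly blurred stage: on the
            # raw image the argmin is biased toward the inward branch,
            # whose Poisson fluctuations are larger (variance follows
            # intensity), while blurring averages that asymmetry away
            theta = _axial_endpoint_scan(m_s, theta, img_s, window,
                                         validate, half_range=scan[0],
                                         step=scan[1])
    # smooth polish with the Gaussian count frozen; the count itself is
    # integer-valued, so compare the self-consistent fit with its J +/- 1
    # neighbours and keep the lowest chi-squared
    best = None
    for _ in range(polish_rounds):
        J_cur = len(replace(model, fixed_J=None).chain(theta))
        m_froz = replace(model, fixed_J=J_cur)
        res = fit_model(m_froz, theta, image, window, config,
                        validate=validate, free_mask=base_free)
        theta = res.theta
        best = (res, J_cur)
        if len(replace(model, fixed_J=None).chain(theta)) == J_cur:
            break
    res, J_cur = best
    for J_alt in (J_cur - 1, J_cur + 1):
        if J_alt < 1:
            continue
        try:
            alt = fit_model(replace(model, fixed_J=J_alt), res.theta.copy(),
                            image, window, config, validate=validate,
                            free_mask=base_free)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if alt.chi2 < res.chi2:
            res = alt
    return res


# ---------------------------------------------------------------------------
# Gaussian mask endpoint refinement


@dataclass
class MaskFitResult:
    position: np.ndarray
    refined: bool
    n_iter: int


def _masked_centroid(img, c, inward, ds, sigma):
    """One masked-centroid evaluation of the two-Gaussian tip mask at c."""
    sx, sy = sigma
    h, w = img.shape
    rx = int(math.ceil(3 * sx + ds)) + 2
    ry = int(math.ceil(3 * sy + ds)) + 2
    x0, x1 = int(round(c[0])) - rx, int(round(c[0])) + rx + 1
    y0, y1 = int(round(c[1])) - ry, int(round(c[1])) + ry + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x1 - x0 < 3 or y1 - y0 < 3:
        return None
    X, Y = np.meshgrid(np.arange(x0, x1, dtype=float),
                       np.arange(y0, y1, dtype=float))
    # keep negative noise values: clipping at zero would add a positive
    # intensity bias beyond the tip and drag the centroid outward
    sub = img[y0:y1, x0:x1]
    n1 = c + inward * ds
    W = (np.exp(-((X - c[0]) ** 2) / (2 * sx**2)
                - ((Y - c[1]) ** 2) / (2 * sy**2))
         + np.exp(-((X - n1[0]) ** 2) / (2 * sx**2)
                  - ((Y - n1[1]) ** 2) / (2 * sy**2)))
    wsum = float((W * sub).sum())
    if wsum <= 1e-9:
        return None
    cen = np.array([float((X * W * sub).sum()),
                    float((Y * W * sub).sum())]) / wsum
    # the two-Gaussian mask's own centroid sits ds/2 inward of c; subtract
    # it so the update is neutral in the interior of a uniform ridge and
    # driven only by the intensity truncation at the tip
    return cen - (ds / 2.0) * inward


def gaussian_mask_refine(image: np.ndarray, endpoint: np.ndarray,
                         inward: np.ndarray, ds: float,
                         sigma: tuple[float, float],
                         background: float = 0.0,
                         model_image: np.ndarray | None = None,
                         tol: float = 1e-3, max_iter: int = 50
                         ) -> MaskFitResult:
    """Refine a filament tip to subpixel precision with a two-Gaussian mask.

    The mask (tip Gaussian + one neighbour displaced ``ds`` along the
    inward unit vector, each of std sigma) is iterated as a weighted
    intensity-centroid update on the background-subtracted image.  Along a
    ridge the centroid map is neutral in the axial direction (every
    interior position is close to a fixed point), so the update is run in
    lockstep on the observed image and on ``model_image`` (the noiseless
    fitted model, signal only, tip at ``endpoint``): both walks share the
    common inward drift, which cancels in their difference, and the
    refined tip is ``endpoint + (c_data - c_model)``.  Iteration stops
    when that difference changes by less than ``tol`` px.

    On divergence (no convergence in ``max_iter``, or a tip correction
    beyond 3 sigma + ds) the input estimate is returned flagged unrefined.
    """
    endpoint = np.asarray(endpoint, dtype=float)
    inward = np.asarray(inward, dtype=float)
    n = np.linalg.norm(inward)
    if n < 1e-12:
        return MaskFitResult(endpoint.copy(), False, 0)
    inward = inward / n
    data = np.asarray(image, dtype=float) - background
    # the mask is a local refinement: corrections beyond ~2 sigma mean it
    # latched onto a noise structure rather than the tip
    max_shift = 2.0 * max(sigma) + 0.5 * ds

    if model_image is None:
        # single-image mode: plain fixed point (isolated-tip use only)
        c = endpoint.copy()
        for it in range(1, max_iter + 1):
            nxt = _masked_centroid(data, c, inward, ds, sigma)
            if nxt is None:
                return MaskFitResult(endpoint.copy(), False, it)
            step = float(np.linalg.norm(nxt - c))
            c = nxt
            if step < tol:
                return MaskFitResult(c, True, it)
        return MaskFitResult(endpoint.copy(), False, max_iter)

    model = np.asarray(model_image, dtype=float)
    cd = endpoint.copy()
    cm = endpoint.copy()
    diff = np.zeros(2)
    tail: list[np.ndarray] = []
    for it in range(1, max_iter + 1):
        nd = _masked_centroid(data, cd, inward, ds, sigma)
        nm = _masked_centroid(model, cm, inward, ds, sigma)
        if nd is None or nm is None:
            return MaskFitResult(endpoint.copy(), False, it)
        # convergence means *both* walks reached their fixed points; the
        # difference alone is nearly constant during the initial common
        # drift and would stop the iteration before the tip is reached
        step = max(float(np.linalg.norm(nd - cd)),
                   float(np.linalg.norm(nm - cm)))
        cd, cm, diff = nd, nm, nd - nm
        if float(np.linalg.norm(diff)) > max_shift:
            return MaskFitResult(endpoint.copy(), False, it)
        if step < tol:
            return MaskFitResult(endpoint + diff, True, it)
        if it > max_iter - 10:
            tail.append(diff.copy())
    # image noise leaves the difference jittering around its fixed point;
    # the trailing-iteration average is the converged estimate provided the
    # jitter is small
    tail_arr = np.array(tail)
    spread = float(np.linalg.norm(tail_arr.std(axis=0)))
    mean_diff = tail_arr.mean(axis=0)
    if spread < 0.25 and float(np.linalg.norm(mean_diff)) <= max_shift:
        return MaskFitResult(endpoint + mean_diff, True, max_iter)
    return MaskFitResult(endpoint.copy(), False, max_iter)


def dense_model_image(model, theta, image_shape, window,
                      spacing_frac: float = 1.0 / 3.0) -> np.ndarray:
    """Noiseless continuous-filament image of a fitted model (signal only).

    Renders the fitted path as a dense Gaussian chain (spacing
    ``spacing_frac * sigma``) with the amplitude rescaled to preserve the
    fitted ridge intensity (A * ds / spacing).  This is the calibration
    image for the mask fit: it represents a continuous filament ending at
    the fitted tip, free of the discrete chain's tip over-weighting.
    """
    from dataclasses import replace

    sx, sy = model.sigma
    spacing = min(sx, sy) * spacing_frac
    th = np.asarray(theta, dtype=float).copy()
    ds_fit = th[model.ds_index]
    amp = th[model.amp_index] * ds_fit / spacing
    th[model.ds_index] = spacing
    try:
        pts = replace(model, fixed_J=None).chain(th)
    except ValueError:
        # degenerate fit spans a huge distance: coarsen to stay bounded
        pts0 = replace(model, fixed_J=2).chain(th)
        span = float(np.linalg.norm(pts0[-1] - pts0[0])) * (len(pts0) - 1) / 2
        span = max(span, 1.0)
        spacing2 = max(spacing, ds_fit, span / 900.0)
        amp = th[model.amp_index] * ds_fit / spacing2
        th[model.ds_index] = spacing2
        pts = replace(model, fixed_J=None).chain(th)
    h, w = image_shape
    x0, y0, x1, y1 = window
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    out = np.zeros(image_shape, dtype=float)
    X, Y = np.meshgrid(np.arange(x0, x1, dtype=float),
                       np.arange(y0, y1, dtype=float))
    acc = np.zeros_like(X)
    for cx, cy in pts:
        acc += np.exp(-((X - cx) ** 2) / sx**2 - ((Y - cy) ** 2) / sy**2)
    # end-tip Gaussian of the fitted model sits exactly at the endpoint,
    # which the dense chain already reaches; no extra tip term
    out[y0:y1, x0:x1] = amp * acc
    return out


# ---------------------------------------------------------------------------
# contour length


def contour_length(coefficients: tuple[float, ...], x_start: float,
                   x_end: float, pixel_size_nm: float = 1.0) -> float:
    """Arc length of y(x) between two path-parameter values, in nm.

    ``coefficients`` are (m, c) for a line or (I, b, m, c) for a cubic;
    the integrand sqrt(1 + y'(x)^2) is integrated by adaptive quadrature.
    For a line this equals the Euclidean endpoint distance exactly.
    """
    from scipy.integrate import quad

    if len(coefficients) == 2:
        m, _ = coefficients
        return abs(x_end - x_start) * math.hypot(1.0, m) * pixel_size_nm
    if len(coefficients) != 4:
        raise ValueError("coefficients must be (m, c) or (I, b, m, c)")
    I3, b, m, _ = coefficients
    a, bnd = sorted((x_start, x_end))
    val, _ = quad(lambda x: math.hypot(1.0, 3 * I3 * x**2 + 2 * b * x + m),
                  a, bnd, limit=200)
    return val * pixel_size_nm

def _axial_endpoint_scan(model, theta, image, window, validate,
                         half_range: float = 3.0, step: float = 0.25):
    """Greedy per-endpoint scan of chi^2 along the local axis direction."""
    x0, y0, x1, y1 = window
    h, w = image.shape
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    X, Y = np.meshgrid(np.arange(x0, x1, dtype=float),
                       np.arange(y0, y1, dtype=float))
    X, Y = X.ravel(), Y.ravel()
    I = np.asarray(image, dtype=float)[y0:y1, x0:x1].ravel()
    offsets = np.arange(-half_range, half_range + step / 2, step)

    if isinstance(model, LineSoGModel):
        ends = [((0, 1), model.direction), ((2, 3), model.direction)]
    else:
        ch = model.chain(theta)
        tang = np.array([theta[0], theta[1]]) - ch[-1]
        n = np.linalg.norm(tang)
        tang = tang / n if n > 1e-9 else model.chain(theta)[-1] * 0 + 1.0
        ends = [((0, 1), tang)]

    theta = np.asarray(theta, dtype=float).copy()
    for _ in range(2):
        for (ix, iy), u in ends:
            best, best_chi = 0.0, None
            for o in offsets:
                cand = theta.copy()
                cand[ix] += o * u[0]
                cand[iy] += o * u[1]
                if validate is not None and not validate(cand):
                    continue
                try:
                    F = model.model(cand, X, Y)
                except ValueError:
                    continue
                chi = float(((I - F) ** 2).sum())
                if best_chi is None or chi < best_chi:
                    best, best_chi = o, chi
            theta[ix] += best * u[0]
            theta[iy] += best * u[1]
    return theta
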