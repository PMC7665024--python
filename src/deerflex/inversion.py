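"""Recovery of P(r) from a DEER trace.

The analysis chain is the conventional one for pulsed dipolar spectroscopy:

1. fit a stretched-exponential background to the tail of the trace and
   divide it out, leaving the intramolecular form factor;
2. solve the ill-posed Fredholm inversion by non-negative Tikhonov
   regularization with a second-difference smoothness penalty,

       p(alpha) = argmin_{p>=0} ||K p dr - s||^2 + alpha^2 ||L2 p||^2 ,

   selecting alpha at the maximum-curvature corner of the L-curve
   (log residual norm vs log seminorm);
3. refine the Tikhonov solution by a maximum-entropy step that minimizes
   chi^2/(2 sigma^2) plus the relative entropy to the Tikhonov prior,
   with the entropy weight adjusted so the final reduced chi^2 lands in a
   band around 1.

Non-negativity is enforced inside the solver (active-set NNLS on the
stacked system), not by clipping, since clipping distorts the L-curve
geometry that the alpha selection relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit, nnls

from .dipolar_model import (
    BackgroundModel,
    DeerTrace,
    DipolarKernel,
    DistanceDistribution,
    DistanceGrid,
    build_kernel,
    default_grid,
)
from .errors import (
    ConvergenceWarning,
    DeerflexError,
    DegenerateModulationError,
    GridMismatchError,
    InsufficientTailError,
    InvalidParameterError,
    PathIntegrityError,
)

_SIGMA_FLOOR = 1e-6  # noise floor so noiseless synthetic data stay well-posed


@dataclass(frozen=True)
class DipolarSignal:
    """Background-corrected, modulation-normalized dipolar signal s(t)."""

    t: np.ndarray
    s: np.ndarray
    sigma_est: float

    def __post_init__(self):
        t = np.ascontiguousarray(np.asarray(self.t, float))
        s = np.ascontiguousarray(np.asarray(self.s, float))
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "s", s)
        if t.size != s.size:
            raise InvalidParameterError("signal and time axis lengths differ")
        if self.sigma_est < 0:
            raise InvalidParameterError("sigma_est must be >= 0")


@dataclass(frozen=True)
class RegularizationPath:
    """Tikhonov solutions over a log-spaced alpha grid with L-curve norms."""

    alphas: np.ndarray
    rho: np.ndarray  # residual norms ||K p dr - s||, pre-normalization
    eta: np.ndarray  # seminorms ||L2 p||, pre-normalization
    solutions: tuple[DistanceDistribution, ...]

    def __post_init__(self):
        a = np.asarray(self.alphas, float)
        object.__setattr__(self, "alphas", a)
        object.__setattr__(self, "rho", np.asarray(self.rho, float))
        object.__setattr__(self, "eta", np.asarray(self.eta, float))
        if not (len(a) == len(self.rho) == len(self.eta) == len(self.solutions)):
            raise InvalidParameterError("path arrays must have equal length")
        if np.any(np.diff(a) <= 0):
            raise InvalidParameterError("alphas must be strictly increasing")


@dataclass(frozen=True)
class InversionResult:
    background: BackgroundModel
    path: RegularizationPath
    alpha_selected: float
    p_tikhonov: DistanceDistribution
    p_mem: DistanceDistribution
    chi2_per_point: float
    mem_converged: bool = True
    noise_sd: float = 0.0


@dataclass(frozen=True)
class InversionConfig:
    """All knobs of the inversion chain with conventional defaults."""

    r_min: float = 1.5
    r_max: float = 8.0
    dr: float = 0.02
    bg_dim: float = 3.0
    fit_start_fraction: float = 0.6
    n_alphas: int = 41
    alpha_min: float = 1e-4
    alpha_max: float = 1e4
    target_chi2: float = 1.0
    bg_refine: int = 1  # rounds of form-factor-aware background refitting

    def grid(self) -> DistanceGrid:
        return default_grid(self.r_min, self.r_max, self.dr)

    def alphas(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.alpha_min), np.log10(self.alpha_max), self.n_alphas
        )


def fit_background(
    trace: DeerTrace,
    fit_start_fraction: float = 0.6,
    d: float = 3.0,
) -> tuple[BackgroundModel, float]:
    """Fit a*exp(-k t^(d/3)) to the trace tail; return model and noise SD.

    The modulation depth is lambda = 1 - a (clipped to [0, 1]); the noise
    standard deviation is estimated from the fit residuals in the window.
    """
    if not 0.3 <= fit_start_fraction <= 0.9:
        raise InvalidParameterError("fit_start_fraction must be in [0.3, 0.9]")
    t, v = trace.t, trace.v
    window = t >= fit_start_fraction * t[-1]
    if window.sum() < 8:
        raise InsufficientTailError(
            f"only {int(window.sum())} points in the background-fit window (need >= 8)"
        )
    tw, vw = t[window], v[window]
    tau = tw ** (d / 3.0)

    # log-linear initialization when the tail is positive, then bounded refine
    if np.all(vw > 0):
        coef = np.polyfit(tau, np.log(vw), 1)
        k0, a0 = max(-coef[0], 0.0), float(np.exp(coef[1]))
    else:
        k0, a0 = 0.01, max(float(vw[0]), 0.05)
    a0 = float(np.clip(a0, 1e-3, 2.0))
    try:
        popt, _ = curve_fit(
            lambda x, a, k: a * np.exp(-k * x ** (d / 3.0)),
            tw,
            vw,
            p0=(a0, min(max(k0, 0.0), 10.0)),
            bounds=([1e-6, 0.0], [2.0, 10.0]),
            maxfev=10000,
        )
        a, k = float(popt[0]), float(popt[1])
    except RuntimeError:
        a, k = a0, max(k0, 0.0)
    resid = vw - a * np.exp(-k * tau)
    noise_sd = float(np.std(resid, ddof=min(2, vw.size - 1)))
    lam = float(np.clip(1.0 - a, 0.0, 1.0))
    return BackgroundModel(k=k, lam=lam, d=d), noise_sd


def refine_background(
    trace: DeerTrace,
    kernel: DipolarKernel,
    p: np.ndarray,
    bg0: BackgroundModel,
) -> BackgroundModel:
    """Refit modulation depth and decay rate with the form factor in the model.

    The tail-only fit of :func:`fit_background` is biased when the dipolar
    oscillation has not decayed inside the fit window (narrow distributions
    at long distances oscillate for many microseconds).  Given a first
    distribution estimate, the full trace is refit as

        v(t) = [(1 - lam) + lam * F_hat(t)] * exp(-k t^(d/3)),

    with F_hat fixed to the current estimate and only (lam, k) free; errors
    in F_hat perturb this fit only to second order.

    F_hat is computed from the distribution restricted to the reliable
    range r <= (2 D t_max)^(1/3), i.e. distances whose dipolar half-period
    fits inside the observation window.  Beyond it the kernel is nearly
    flat in time, so any mass the first pass parked there is an alias of a
    background misfit and must be handed back to the background term
    rather than frozen into the model.
    """
    from .dipolar_model import DIPOLAR_CONSTANT_MHZ_NM3

    r_reliable = (2.0 * DIPOLAR_CONSTANT_MHZ_NM3 * trace.t[-1]) ** (1.0 / 3.0)
    p_rel = np.where(kernel.grid.r <= r_reliable, p, 0.0)
    mass = p_rel.sum() * kernel.grid.dr
    if mass > 0.1:
        p_rel = p_rel / mass
    else:  # essentially all mass beyond the reliable range: keep as-is
        p_rel = p
    F_hat = kernel.K @ (p_rel * kernel.grid.dr)
    t, v = trace.t, trace.v
    d = bg0.d

    def model(t_, lam, k):
        return ((1.0 - lam) + lam * F_hat) * np.exp(-k * t_ ** (d / 3.0))

    try:
        popt, _ = curve_fit(
            model,
            t,
            v,
            p0=(min(max(bg0.lam, 0.02), 0.98), bg0.k),
            bounds=([0.0, 0.0], [1.0, 10.0]),
            maxfev=10000,
        )
        return BackgroundModel(k=float(popt[1]), lam=float(popt[0]), d=d)
    except RuntimeError:
        return bg0


def correct_trace(
    trace: DeerTrace,
    bg: BackgroundModel,
    noise_sd: float | None = None,
) -> DipolarSignal:
    """Divide out the background and rescale to the unit-depth form factor.

    s(t) = (v(t)/B(t) - (1 - lambda)) / lambda.  Dividing by the decaying
    background amplifies the trace noise by 1/B(t), so the signal-level
    noise SD is ``noise_sd / lambda`` times the rms of 1/B over the trace;
    when no trace-level estimate is supplied it is taken from the
    high-frequency content of the corrected signal.
    """
    if bg.lam <= 0.01:
        raise DegenerateModulationError(
            f"modulation depth {bg.lam:.4f} <= 0.01: nothing to invert"
        )
    B = bg.evaluate(trace.t)
    s = (trace.v / B - (1.0 - bg.lam)) / bg.lam
    if noise_sd is None:
        sigma = float(np.std(np.diff(s)) / np.sqrt(2.0))
    else:
        sigma = noise_sd / bg.lam * float(np.sqrt(np.mean(B**-2)))
    return DipolarSignal(t=trace.t, s=s, sigma_est=sigma)


def second_difference_operator(n: int) -> np.ndarray:
    """n x n second-difference matrix with zero (free-boundary) end rows."""
    L = np.zeros((n, n))
    for i in range(1, n - 1):
        L[i, i - 1], L[i, i], L[i, i + 1] = 1.0, -2.0, 1.0
    return L


def tikhonov_solve(
    signal: DipolarSignal,
    kernel: DipolarKernel,
    alpha: float,
) -> tuple[DistanceDistribution, float, float]:
    """Non-negative Tikhonov solution at one alpha.

    Returns the normalized distribution plus the residual norm rho and
    seminorm eta of the raw (pre-normalization) solution.  An all-zero
    solution is returned flagged as empty rather than raising.
    """
    if alpha <= 0:
        raise InvalidParameterError("alpha must be > 0")
    if kernel.t.shape != signal.t.shape or not np.allclose(kernel.t, signal.t):
        raise GridMismatchError("kernel and signal time grids differ")
    n = kernel.grid.n
    A = kernel.K * kernel.grid.dr
    L = second_difference_operator(n)
    stacked = np.vstack([A, alpha * L])
    b = np.concatenate([signal.s, np.zeros(n)])
    p_raw, _ = nnls(stacked, b)
    rho = float(np.linalg.norm(A @ p_raw - signal.s))
    eta = float(np.linalg.norm(L @ p_raw))
    return DistanceDistribution.normalized(kernel.grid, p_raw), rho, eta


def tikhonov_path(
    signal: DipolarSignal,
    kernel: DipolarKernel,
    alphas: np.ndarray,
) -> RegularizationPath:
    """Tikhonov solutions over an increasing alpha grid."""
    sols, rhos, etas = [], [], []
    for alpha in np.asarray(alphas, float):
        dist, rho, eta = tikhonov_solve(signal, kernel, alpha)
        sols.append(dist)
        rhos.append(rho)
        etas.append(eta)
    return RegularizationPath(
        alphas=np.asarray(alphas, float),
        rho=np.array(rhos),
        eta=np.array(etas),
        solutions=tuple(sols),
    )


def _smooth3(x: np.ndarray) -> np.ndarray:
    """3-point moving average keeping the end points."""
    y = x.copy()
    if len(x) >= 3:
        y[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    return y


def select_alpha(path: RegularizationPath, prune_delta: float = 0.01) -> float:
    """L-curve corner: alpha of maximum signed curvature of (log rho, log eta).

    Both log axes are rescaled to [0, 1] and near-stationary points (closer
    than ``prune_delta`` in the rescaled plane to the last kept point) are
    dropped before differentiating: on an active-set path the extreme-alpha
    limbs contain runs of numerically identical solutions whose vanishing
    arc length otherwise produces unbounded spurious curvature.  On the
    pruned curve the signed curvature is computed by central finite
    differences after a light 3-point moving-average smoothing; ties break
    toward the larger alpha.  Paths whose rho is not non-decreasing or eta
    not non-increasing (beyond 1e-10 relative) are rejected.
    """
    n = len(path.alphas)
    tol_rho = max(1e-10 * path.rho.max(), 1e-14)
    tol_eta = max(1e-10 * path.eta.max(), 1e-14)
    if np.any(np.diff(path.rho) < -tol_rho) or np.any(np.diff(path.eta) > tol_eta):
        raise PathIntegrityError("rho must be non-decreasing and eta non-increasing in alpha")
    if n == 1:
        return float(path.alphas[0])
    if n == 2:
        return float(path.alphas[-1])
    x = np.log(np.maximum(path.rho, max(path.rho.max() * 1e-12, 1e-300)))
    y = np.log(np.maximum(path.eta, max(path.eta.max() * 1e-12, 1e-300)))
    x = (x - x.min()) / max(x.max() - x.min(), 1e-12)
    y = (y - y.min()) / max(y.max() - y.min(), 1e-12)
    keep = [0]
    for i in range(1, n):
        if np.hypot(x[i] - x[keep[-1]], y[i] - y[keep[-1]]) >= prune_delta:
            keep.append(i)
    keep = np.asarray(keep)
    if len(keep) < 3:
        return float(path.alphas[keep[-1]])
    xs, ys = _smooth3(x[keep]), _smooth3(y[keep])
    dx, dy = np.gradient(xs), np.gradient(ys)
    ddx, ddy = np.gradient(dx), np.gradient(dy)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, (dx * ddy - dy * ddx) / denom, -np.inf)
    kappa[0] = kappa[-1] = -np.inf  # no central difference at the ends
    best = keep[np.flatnonzero(kappa >= kappa.max() - 1e-12)[-1]]
    return float(path.alphas[best])


def mem_refine(
    signal: DipolarSignal,
    kernel: DipolarKernel,
    prior: DistanceDistribution,
    target_chi2: float = 1.0,
    max_total_iter: int = 5000,
    full_output: bool = False,
):
    """Maximum-entropy refinement of a distance distribution.

    Minimizes  chi^2/(2 sigma^2) + mu * sum_i [p ln(p/m) - p + m]  over
    p >= 0 (bound-constrained quasi-Newton inner solves, warm-started along
    the bisection), with the entropy weight mu bisected so the reduced
    chi-square lands in [0.9, 1.5] * target_chi2, aiming at the target
    itself.  If the window is unreachable (the prior already over- or
    under-fits at both extremes of mu) or the iteration budget runs out,
    the closest solution is returned and a :class:`ConvergenceWarning` is
    issued.
    """
    from scipy.optimize import minimize

    if kernel.grid != prior.grid:
        raise GridMismatchError("kernel and prior are on different distance grids")
    dr = kernel.grid.dr
    m = np.maximum(prior.p, 1e-8)  # strictly positive prior, per nm
    sigma = max(signal.sigma_est, _SIGMA_FLOOR)
    A = kernel.K * dr
    s = signal.s
    N = len(s)
    lo_chi, hi_chi = 0.9 * target_chi2, 1.5 * target_chi2
    iters_used = 0
    warm = {"x": m.copy()}

    def chi2n(p):
        return float(np.sum((A @ p - s) ** 2) / sigma**2) / N

    def solve(mu, budget):
        nonlocal iters_used

        def objective(p):
            resid = A @ p - s
            pos = np.maximum(p, 1e-300)
            ent = float(np.sum(pos * np.log(pos / m) - pos + m))
            val = 0.5 * float(resid @ resid) / sigma**2 + mu * ent
            grad = A.T @ resid / sigma**2 + mu * np.log(pos / m)
            return val, grad

        res = minimize(
            objective,
            np.maximum(warm["x"], 1e-14),
            jac=True,
            method="L-BFGS-B",
            bounds=[(1e-14, None)] * len(m),
            options={"maxiter": budget, "ftol": 1e-14, "gtol": 1e-12},
        )
        iters_used += res.nit
        warm["x"] = res.x.copy()
        return res.x

    inner = 400
    # mu bracket: at the top the entropy term must dominate the data-term
    # curvature so the solution collapses onto the prior; at the bottom the
    # data term must dominate its gradient at the prior
    g_scale = max(float(np.max(np.abs(A.T @ (A @ m - s))) / sigma**2), 1e-30)
    h_scale = max(float(np.max(np.sum(A * A, axis=0)) / sigma**2 * np.max(m)), g_scale)
    log_lo, log_hi = np.log10(g_scale) - 8.0, np.log10(h_scale) + 2.0
    p_hi = solve(10.0**log_hi, inner)
    c_hi = chi2n(p_hi)
    if c_hi < lo_chi:
        # the prior already fits tighter than the band and no entropy
        # weight can raise chi^2 above the prior's level
        best_p, converged = p_hi, False
    elif c_hi <= hi_chi:
        # the prior is already statistically consistent with the data; the
        # maximum-entropy answer is to leave it (largest admissible mu)
        best_p, converged = p_hi, True
    else:
        p_lo = solve(10.0**log_lo, inner)
        c_lo = chi2n(p_lo)
        if c_lo > hi_chi:
            # even nearly unregularized iterations cannot reach the band
            best_p = p_lo if c_lo <= c_hi else p_hi
            converged = False
        else:
            # chi2 increases with mu: bisect for the largest mu inside the
            # band — the smallest refinement that reaches consistency, in
            # keeping with maximum entropy (stay as close to the prior as
            # the data allow).  Accept on the band's upper part; landings
            # near the lower edge would re-fit noise.
            best_p, best_c, converged = p_lo, c_lo, lo_chi <= c_lo
            while iters_used < max_total_iter and log_hi - log_lo > 1e-3:
                mid = 0.5 * (log_lo + log_hi)
                p_mid = solve(10.0**mid, inner)
                c_mid = chi2n(p_mid)
                if 1.2 * target_chi2 <= c_mid <= hi_chi:
                    best_p, best_c, converged = p_mid, c_mid, True
                    break
                if c_mid > hi_chi:
                    log_hi = mid
                else:
                    log_lo = mid
                    if lo_chi <= c_mid and abs(c_mid - hi_chi) < abs(best_c - hi_chi):
                        best_p, best_c, converged = p_mid, c_mid, True
    if not converged:
        warnings.warn(
            f"maximum-entropy refinement left the chi^2 band "
            f"(reduced chi^2 = {chi2n(best_p):.3g})",
            ConvergenceWarning,
            stacklevel=2,
        )
    out = DistanceDistribution.normalized(kernel.grid, best_p)
    if full_output:
        return out, {"chi2_per_point": chi2n(best_p), "converged": converged}
    return out


def invert(trace: DeerTrace, config: InversionConfig = InversionConfig()) -> InversionResult:
    """Full inversion chain: background fit, correction, Tikhonov L-curve, MEM.

    Deterministic given the trace and configuration.  Stage failures are
    re-raised with the failing stage named in the message.
    """

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except DeerflexError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    bg, noise_sd = stage("fit_background", fit_background, trace, config.fit_start_fraction, config.bg_dim)
    kernel = stage("build_kernel", build_kernel, trace.t, config.grid())
    for round_ in range(config.bg_refine + 1):
        signal = stage("correct_trace", correct_trace, trace, bg, noise_sd)
        path = stage("tikhonov_path", tikhonov_path, signal, kernel, config.alphas())
        alpha = stage("select_alpha", select_alpha, path)
        idx = int(np.argmin(np.abs(path.alphas - alpha)))
        p_tik = path.solutions[idx]
        if round_ < config.bg_refine and not p_tik.is_empty:
            bg = stage("refine_background", refine_background, trace, kernel, p_tik.p, bg)
    if p_tik.is_empty:
        return InversionResult(
            background=bg,
            path=path,
            alpha_selected=alpha,
            p_tikhonov=p_tik,
            p_mem=p_tik,
            chi2_per_point=float("nan"),
            mem_converged=False,
            noise_sd=noise_sd,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        p_mem, info = stage(
            "mem_refine",
            mem_refine,
            signal,
            kernel,
            p_tik,
            config.target_chi2,
            full_output=True,
        )
    return InversionResult(
        background=bg,
        path=path,
        alpha_selected=alpha,
        p_tikhonov=p_tik,
        p_mem=p_mem,
        chi2_per_point=info["chi2_per_point"],
        mem_converged=info["converged"],
        noise_sd=noise_sd,
    )
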