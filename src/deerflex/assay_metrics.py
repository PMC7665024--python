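"""Scalar assay metrics: FRET efficiency, cytochrome-c release, FRAP fitting.

These are the functional readouts that accompany the structural analysis:

* FRET efficiency  E = 1 - I/I0  from donor intensities with and without
  acceptor (donor emission read at 455 nm);
* cytochrome-c release fraction  (I - I0)/(Imax - I0) * 100%  between the
  no-BAX and activated-BAX immunoblot controls;
* FRAP recovery fitting on giant unilamellar vesicles: a single-exponential
  recovery f(t) = f0 + (finf - f0)(1 - exp(-t/tau)) gives an effective
  dextran diffusion coefficient D = w^2/(4 tau) (w = bleach radius), and
  pore-forming activity is the ratio D/D0 against the detergent-disrupted
  reference (D0 = 26.5 um^2/s for 70-kDa and 51.2 um^2/s for 10-kDa
  F-dextran).  D/D0 approaches 1 when the vesicles are largely disrupted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateNormalizationError,
    FitFailureError,
    InvalidParameterError,
    InvalidReferenceError,
    UndefinedEfficiencyError,
)

#: Reference (Triton-disrupted) dextran diffusion coefficients, um^2/s.
D0_REFERENCES_UM2_S = {"70k": 26.5, "10k": 51.2}


@dataclass(frozen=True)
class RecoveryCurve:
    """Post-bleach fluorescence recovery: times in s from 0, arbitrary units."""

    times: np.ndarray
    intensities: np.ndarray
    bleach_radius: float  # um

    def __post_init__(self):
        t = np.ascontiguousarray(np.asarray(self.times, float))
        f = np.ascontiguousarray(np.asarray(self.intensities, float))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", f)
        if t.size != f.size or t.size < 10:
            raise InvalidParameterError("recovery curve needs >= 10 matching points")
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise InvalidParameterError("times must be strictly increasing from >= 0")
        if self.bleach_radius <= 0:
            raise InvalidParameterError("bleach radius must be > 0")


@dataclass(frozen=True)
class FrapResult:
    D: float  # um^2/s
    tau: float  # s
    plateau_fraction: float
    activity: float | None = None  # D/D0, set by pore_activity


def fret_efficiency(I_with_acceptor: float, I_donor_only: float) -> float:
    """FRET efficiency E = 1 - I/I0 from donor intensities.

    Values outside [0, 1] (possible with noisy intensities) are returned
    as-is; callers can range-check.
    """
    if I_donor_only == 0:
        raise UndefinedEfficiencyError("donor-only intensity I0 is zero")
    if I_with_acceptor < 0 or I_donor_only < 0:
        raise InvalidParameterError("intensities must be non-negative")
    return 1.0 - I_with_acceptor / I_donor_only


def release_fraction(I: float, I0: float, Imax: float) -> float:
    """Cytochrome-c release in percent: (I - I0)/(Imax - I0) * 100.

    I0 and Imax are the band intensities without and with activated BAX.
    """
    if Imax == I0:
        raise DegenerateNormalizationError("controls coincide (Imax == I0)")
    return (I - I0) / (Imax - I0) * 100.0


def fit_frap_recovery(curve: RecoveryCurve) -> FrapResult:
    """Fit a single-exponential recovery and convert to a diffusion coefficient.

    f(t) = f0 + (finf - f0) * (1 - exp(-t/tau));  D = w^2 / (4 tau).
    A flat curve leaves tau unidentifiable and raises
    :class:`FitFailureError` with residual diagnostics.
    """
    t, f = curve.times, curve.intensities
    span = float(f.max() - f.min())
    if span <= 0 or span < 1e-9 * max(abs(f).max(), 1.0):
        raise FitFailureError(
            "flat recovery curve: tau unidentifiable",
            diagnostics={"dynamic_range": span},
        )
    f0_guess, finf_guess = float(f[0]), float(np.mean(f[-max(3, t.size // 5):]))
    tau_guess = float(t[-1] / 4.0) if t[-1] > 0 else 1.0

    def model(t, f0, finf, tau):
        return f0 + (finf - f0) * (1.0 - np.exp(-t / tau))

    try:
        popt, pcov = curve_fit(
            model,
            t,
            f,
            p0=(f0_guess, finf_guess, tau_guess),
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        resid = f - model(t, f0_guess, finf_guess, tau_guess)
        raise FitFailureError(
            f"recovery fit did not converge: {exc}",
            diagnostics={"rms_residual": float(np.sqrt(np.mean(resid**2)))},
        ) from exc
    f0, finf, tau = (float(x) for x in popt)
    if not np.isfinite(pcov).all() or tau <= 0:
        resid = f - model(t, *popt)
        raise FitFailureError(
            "recovery fit degenerate (singular covariance or tau <= 0)",
            diagnostics={"rms_residual": float(np.sqrt(np.mean(resid**2))), "tau": tau},
        )
    D = curve.bleach_radius**2 / (4.0 * tau)
    plateau = (finf - f0) / f0 if f0 != 0 else float("nan")
    return FrapResult(D=D, tau=tau, plateau_fraction=plateau)


def pore_activity(D: float, D0: float) -> float:
    """Pore-forming activity D/D0 against the detergent-disrupted reference."""
    if D0 <= 0:
        raise InvalidReferenceError("reference diffusion coefficient D0 must be > 0")
    return D / D0
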