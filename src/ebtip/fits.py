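"""Curve-fit models: tip-binding isotherm, competition decay, FRAP
recovery and Gaussian peak localisation.

All fits are unweighted nonlinear least squares (Levenberg-Marquardt /
trust-region via scipy) initialised from closed-form linearisations, so the
fitted constants (K_D, K, tau, centre) are invariant to intensity scaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .containers import FrapTrace


@dataclass
class BindingFit:
    """One-site tip-binding isotherm I = I_max * [EB] / (K_D + [EB])."""

    kd_nM: float
    imax: float
    kd_err_nM: float
    imax_err: float
    imax_fixed: bool = False


@dataclass
class DecayFit:
    """Exponential decay with concentration, I = A * exp(-c / K)."""

    K_nM: float
    amplitude: float
    K_err_nM: float
    amplitude_err: float


@dataclass
class FrapFit:
    """FRAP recovery plateau * (1 - exp(-t / tau)); the immobile fraction
    is 1 - plateau."""

    tau_s: float
    plateau: float
    tau_err_s: float
    plateau_err: float

    @property
    def half_time_s(self) -> float:
        return self.tau_s * math.log(2.0)


@dataclass
class GaussianPeak:
    centre: float
    width: float
    amplitude: float
    baseline: float


def _errs(pcov: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.diag(pcov))


def fit_binding(concentrations, intensities,
                fixed_imax: float | None = None) -> BindingFit:
    """Fit the one-site binding isotherm; ``fixed_imax`` constrains I_max
    (the lattice-fit protocol where saturation comes from a separate
    curve)."""
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(intensities, dtype=float)
    min_pts = 2 if fixed_imax is not None else 3
    if c.size < min_pts:
        raise ValueError(f"need at least {min_pts} concentration points")
    if np.ptp(y) == 0:
        raise ValueError("intensities are all equal; isotherm is undefined")
    imax0 = fixed_imax if fixed_imax is not None else 1.2 * y.max()
    # half-saturation concentration as K_D start
    kd0 = float(np.interp(0.5 * imax0, np.sort(y), c[np.argsort(y)]))
    kd0 = max(kd0, 1e-6)
    if fixed_imax is not None:
        popt, pcov = curve_fit(lambda cc, kd: fixed_imax * cc / (kd + cc),
                               c, y, p0=(kd0,), bounds=(1e-12, np.inf),
                               maxfev=5000)
        return BindingFit(float(popt[0]), float(fixed_imax),
                          float(_errs(pcov)[0]), 0.0, imax_fixed=True)
    popt, pcov = curve_fit(lambda cc, imax, kd: imax * cc / (kd + cc),
                           c, y, p0=(imax0, kd0),
                           bounds=([0.0, 1e-12], [np.inf, np.inf]),
                           maxfev=5000)
    err = _errs(pcov)
    return BindingFit(float(popt[1]), float(popt[0]), float(err[1]),
                      float(err[0]))


def fit_decay(concentrations, intensities) -> DecayFit:
    """Fit I = A * exp(-c / K); a non-decreasing series still fits but
    warns."""
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(np.diff(y[np.argsort(c)]) >= 0):
        warnings.warn("intensities do not decrease with concentration; "
                      "decay fit may be meaningless")
    pos = y > 0
    if pos.sum() >= 2:
        slope, logA = np.polyfit(c[pos], np.log(y[pos]), 1)
        K0 = -1.0 / slope if slope < 0 else (c.max() - c.min() + 1.0)
        A0 = math.exp(logA)
    else:
        K0, A0 = c.max() + 1.0, max(y.max(), 1e-6)
    popt, pcov = curve_fit(lambda cc, a, k: a * np.exp(-cc / k), c, y,
                           p0=(A0, max(K0, 1e-6)),
                           bounds=([0.0, 1e-12], [np.inf, np.inf]),
                           maxfev=5000)
    err = _errs(pcov)
    return DecayFit(float(popt[1]), float(popt[0]), float(err[1]),
                    float(err[0]))


def fit_frap(trace: FrapTrace) -> FrapFit:
    """Fit plateau * (1 - exp(-t/tau)) to the post-bleach points of a
    normalised FRAP trace."""
    t, y = trace.post_bleach
    if t.size < 4:
        raise ValueError("need at least 4 post-bleach points")
    plateau0 = max(float(y[-3:].mean()), 1e-3)
    # log-linear start from points clearly below the plateau
    frac = np.clip(1.0 - y / plateau0, 1e-6, None)
    sel = frac > 0.05
    if sel.sum() >= 2:
        slope, _ = np.polyfit(t[sel], np.log(frac[sel]), 1)
        tau0 = -1.0 / slope if slope < 0 else max(t[-1] / 3.0, 1e-3)
    else:
        tau0 = max(t[-1] / 3.0, 1e-3)
    popt, pcov = curve_fit(lambda tt, p, tau: p * (1.0 - np.exp(-tt / tau)),
                           t, y, p0=(plateau0, tau0),
                           bounds=([0.0, 1e-12], [np.inf, np.inf]),
                           maxfev=5000)
    err = _errs(pcov)
    return FrapFit(float(popt[1]), float(popt[0]), float(err[1]),
                   float(err[0]))


def fit_gaussian_peak(position, intensity) -> GaussianPeak:
    """Gaussian + baseline fit to a profile window containing a local
    maximum; returns the subpixel peak centre."""
    x = np.asarray(position, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if x.size < 5:
        raise ValueError("window too short for a Gaussian fit")
    dy = np.diff(y)
    if np.all(dy >= 0) or np.all(dy <= 0):
        raise ValueError("window is monotone: no peak to fit")
    b0 = float(y.min())
    a0 = float(y.max() - b0)
    c0 = float(x[int(np.argmax(y))])
    w = np.clip(y - b0, 0.0, None)
    s0 = math.sqrt(max(((x - c0) ** 2 * w).sum() / w.sum(), 1e-6))
    span = x.max() - x.min()
    popt, _ = curve_fit(
        lambda xx, a, c, s, b: b + a * np.exp(-0.5 * ((xx - c) / s) ** 2),
        x, y, p0=(a0, c0, min(s0, span / 2), b0),
        bounds=([0.0, x.min() - span, 1e-6, -np.inf],
                [np.inf, x.max() + span, 5 * span, np.inf]),
        maxfev=5000)
    a, c, s, b = popt
    return GaussianPeak(float(c), float(s), float(a), float(b))
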