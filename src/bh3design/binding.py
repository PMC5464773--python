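"""Equilibrium and kinetic binding analytics.

The centerpiece is the exact solution of the three-species competition
equilibrium: one receptor R, a labeled tracer L (dissociation constant
``Kd_L``) and an unlabeled competitor C (``Kd_C``) at total concentrations
R_T, L_T, C_T.  Mass balance yields a cubic in free receptor whose unique
physical root has a closed trigonometric form; the fraction of tracer bound,

    f = [RL] / L_T,

maps linearly onto the measured anisotropy/polarization between the free and
bound asymptotes.  Competition titrations are fit for the competitor's true
equilibrium dissociation constant K_i (no Cheng-Prusoff approximation).

Also here: pseudo-first-order crosslinking kinetics y = C*(1 - exp(-k*t)),
JC-1 depolarization AUC normalization, four-parameter logistic EC50 fits and
the cytochrome-c release normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize


# --- exact competitive binding -------------------------------------------

def _fraction_bound_scalar(R_T, L_T, Kd_L, C_T, Kd_C):
    if min(R_T, L_T, C_T) < 0 or Kd_L <= 0 or Kd_C <= 0:
        raise ValueError("concentrations must be >= 0 and Kds > 0")
    if L_T == 0:
        return 0.0
    # cubic in free receptor, written in the standard reduced form
    a = Kd_L + Kd_C + L_T + C_T - R_T
    b = Kd_C * (L_T - R_T) + Kd_L * (C_T - R_T) + Kd_L * Kd_C
    c = -Kd_L * Kd_C * R_T
    p = a * a - 3.0 * b                      # must be > 0 for the trig form
    q = -2.0 * a ** 3 + 9.0 * a * b - 27.0 * c
    if p <= 0 or abs(q) >= 2.0 * p ** 1.5 * (1 - 1e-12):
        return _fraction_bound_bracketed(R_T, L_T, Kd_L, C_T, Kd_C)
    theta = math.acos(q / (2.0 * p ** 1.5))
    u = 2.0 * math.sqrt(p) * math.cos(theta / 3.0) - a
    # u = 3*[R]_free; polish the root on the monotone mass balance to remove
    # the cancellation error the trig form picks up at extreme ratios
    R = _newton_polish(max(u / 3.0, 0.0), R_T, L_T, Kd_L, C_T, Kd_C)
    frac = R / (Kd_L + R)
    return min(max(frac, 0.0), 1.0)


def _newton_polish(R, R_T, L_T, Kd_L, C_T, Kd_C, iters=4):
    for _ in range(iters):
        g = R * (1 + L_T / (Kd_L + R) + C_T / (Kd_C + R)) - R_T
        dg = (1 + L_T * Kd_L / (Kd_L + R) ** 2 + C_T * Kd_C / (Kd_C + R) ** 2)
        step = g / dg
        R_new = R - step
        if R_new < 0:
            R_new = R / 2.0
        if abs(step) <= 1e-16 * max(R, 1.0):
            return R_new
        R = R_new
    return R


def _fraction_bound_bracketed(R_T, L_T, Kd_L, C_T, Kd_C):
    """Fallback: solve the mass-balance for free receptor by bracketing.

    Used when the cubic discriminant is numerically degenerate.
    """
    def g(R):  # total receptor implied by free receptor R
        return R * (1 + L_T / (Kd_L + R) + C_T / (Kd_C + R)) - R_T

    if R_T == 0:
        return 0.0
    R = optimize.brentq(g, 0.0, R_T, xtol=1e-18, rtol=1e-15)
    return R / (Kd_L + R)


def competitive_fraction_bound(R_T, L_T, Kd_L, C_T, Kd_C):
    """Fraction of tracer bound at equilibrium in the three-species system.

    Exact closed-form (trigonometric real root of the mass-balance cubic);
    vectorized over any of the inputs.  All concentrations share one unit
    (conventionally nM).
    """
    arrs = np.broadcast_arrays(*(np.asarray(x, dtype=float)
                                 for x in (R_T, L_T, Kd_L, C_T, Kd_C)))
    out = np.empty(arrs[0].shape)
    for i in np.ndindex(out.shape):
        out[i] = _fraction_bound_scalar(*(a[i] for a in arrs))
    return out if out.shape else float(out)


def mass_balance_residuals(R_T, L_T, Kd_L, C_T, Kd_C):
    """Relative residuals of the three species balances at the solution."""
    f = competitive_fraction_bound(R_T, L_T, Kd_L, C_T, Kd_C)
    RL = f * L_T
    L = L_T - RL
    R = Kd_L * RL / L if L > 0 else 0.0
    RC = R * C_T / (Kd_C + R)
    C = C_T - RC
    res_R = (R + RL + RC - R_T) / max(R_T, 1e-300)
    res_L = (L + RL - L_T) / max(L_T, 1e-300)
    res_C = (C + RC - C_T) / max(C_T, 1e-300) if C_T > 0 else 0.0
    return res_R, res_L, res_C


def two_body_fraction_bound(R_T, L_T, Kd):
    """Quadratic solution of the single-ligand equilibrium (C_T = 0 limit)."""
    s = R_T + L_T + Kd
    RL = (s - math.sqrt(s * s - 4.0 * R_T * L_T)) / 2.0
    return RL / L_T if L_T > 0 else 0.0


def readout_from_fraction(fraction, readout_free, readout_bound):
    """Linear map from bound fraction to the measured readout."""
    return readout_free + (readout_bound - readout_free) * np.asarray(fraction)


# --- competition curve + Ki fit ------------------------------------------

@dataclass
class CompetitionCurve:
    """One competitor titration under fixed receptor/tracer conditions."""

    receptor_total: float      # nM
    tracer_total: float        # nM
    tracer_kd: float           # nM
    competitor_totals: np.ndarray  # nM, strictly increasing
    readout: np.ndarray

    def __post_init__(self):
        self.competitor_totals = np.asarray(self.competitor_totals, float)
        self.readout = np.asarray(self.readout, float)
        if np.any(np.diff(self.competitor_totals) <= 0):
            raise ValueError("competitor series must be strictly increasing")
        if np.any(self.competitor_totals < 0):
            raise ValueError("concentrations must be >= 0")
        if len(self.competitor_totals) != len(self.readout):
            raise ValueError("dose and readout lengths differ")


@dataclass
class FitResult:
    params: dict
    se: dict
    residuals: np.ndarray
    flags: list
    converged: bool

    @property
    def ok(self) -> bool:
        return self.converged and not self.flags


_KI_LOG_BOUNDS = (-4.0, 9.0)  # log10 nM search window


def fit_ki(curve: CompetitionCurve) -> FitResult:
    """Fit the competitor K_i (nM) from a competition titration.

    Nonlinear least squares on (log10 K_i, readout_free, readout_bound) with
    the exact three-species model as forward function.  A fit that does not
    converge, or whose K_i lands on the search bound, is flagged.
    """
    if len(curve.competitor_totals) < 6:
        raise ValueError("need >= 6 titration points to fit Ki")
    y = curve.readout

    def model(theta):
        logki, r_free, r_bound = theta
        f = competitive_fraction_bound(curve.receptor_total, curve.tracer_total,
                                       curve.tracer_kd, curve.competitor_totals,
                                       10.0 ** logki)
        return readout_from_fraction(f, r_free, r_bound)

    def resid(theta):
        return model(theta) - y

    # start heuristic: asymptotes from the data ends, Ki near the midpoint dose
    mid = y[0] + 0.5 * (y[-1] - y[0])
    pos = curve.competitor_totals[curve.competitor_totals > 0]
    guess_ki = math.log10(np.median(pos)) if len(pos) else 1.0
    order = np.argsort(np.abs(y - mid))
    for j in order:
        if curve.competitor_totals[j] > 0:
            guess_ki = math.log10(curve.competitor_totals[j])
            break
    x0 = np.array([guess_ki, y[-1], y[0]])
    lo = [_KI_LOG_BOUNDS[0], -np.inf, -np.inf]
    hi = [_KI_LOG_BOUNDS[1], np.inf, np.inf]
    sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)

    flags = []
    logki = sol.x[0]
    if not sol.success:
        flags.append("non-converged")
    if logki - _KI_LOG_BOUNDS[0] < 1e-6 or _KI_LOG_BOUNDS[1] - logki < 1e-6:
        flags.append("ki-at-bound")
    # unidentifiable Ki: the fitted competitor barely displaces the tracer
    # anywhere in the titrated range
    ki_hat = 10.0 ** logki
    f_lo = competitive_fraction_bound(curve.receptor_total, curve.tracer_total,
                                      curve.tracer_kd,
                                      float(curve.competitor_totals[0]), ki_hat)
    f_hi = competitive_fraction_bound(curve.receptor_total, curve.tracer_total,
                                      curve.tracer_kd,
                                      float(curve.competitor_totals[-1]), ki_hat)
    if f_lo - f_hi < 0.05:
        flags.append("no-transition")

    se = _asymptotic_se(sol)
    params = {"ki": 10.0 ** logki, "log10_ki": float(logki),
              "readout_free": float(sol.x[1]), "readout_bound": float(sol.x[2])}
    ses = {"log10_ki": se[0], "readout_free": se[1], "readout_bound": se[2]}
    return FitResult(params, ses, sol.fun, flags, bool(sol.success))


def _asymptotic_se(sol):
    """Asymptotic parameter SEs from the least-squares Jacobian."""
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


# --- crosslinking kinetics ------------------------------------------------

@dataclass
class KineticsTimeCourse:
    """Fraction of receptor crosslinked over time (minutes)."""

    times: np.ndarray
    fraction_crosslinked: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.fraction_crosslinked = np.asarray(self.fraction_crosslinked, float)
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and increasing")
        if len(self.times) != len(self.fraction_crosslinked):
            raise ValueError("times and values lengths differ")


def fit_crosslink_kinetics(tc: KineticsTimeCourse) -> FitResult:
    """Fit y = C*(1 - exp(-k t)); report C, k (1/min) and half-life ln2/k."""
    if len(tc.times) < 4:
        raise ValueError("need >= 4 time points")
    y = tc.fraction_crosslinked
    flags = []
    if np.ptp(y) < 1e-12:
        return FitResult({"C": float(y.mean()), "k": np.nan, "half_life": np.nan},
                         {}, y - y.mean(), ["flat-timecourse"], False)

    def resid(theta):
        C, k = theta
        return C * (1.0 - np.exp(-k * tc.times)) - y

    c0 = float(max(y.max(), 1e-3))
    # crude rate guess from the earliest point past half of the plateau
    above = np.nonzero(y >= 0.5 * c0)[0]
    t_half0 = tc.times[above[0]] if len(above) and tc.times[above[0]] > 0 else \
        max(tc.times[len(tc.times) // 2], 1e-3)
    x0 = np.array([c0, math.log(2.0) / t_half0])
    sol = optimize.least_squares(resid, x0, bounds=([0.0, 1e-12], [1.05, np.inf]),
                                 xtol=1e-15, ftol=1e-15, gtol=1e-15)
    C, k = sol.x
    if not sol.success:
        flags.append("non-converged")
    if k <= 1e-10:
        flags.append("non-positive-rate")
    se = _asymptotic_se(sol)
    params = {"C": float(C), "k": float(k),
              "half_life": math.log(2.0) / k if k > 0 else np.nan}
    return FitResult(params, {"C": se[0], "k": se[1]}, sol.fun, flags,
                     bool(sol.success))


# --- BH3 profiling: depolarization and EC50 -------------------------------

def percent_depolarization(times, sample_series, dmso_series, fccp_series):
    """Percent depolarization from JC-1 fluorescence time series.

    Trapezoidal AUC of each series over the common time grid, normalized so
    the DMSO (no-depolarization) control reads 0% and the FCCP (complete
    depolarization) control reads 100%.
    """
    t = np.asarray(times, float)
    auc = lambda y: float(np.trapezoid(np.asarray(y, float), t))
    a_s, a_d, a_f = auc(sample_series), auc(dmso_series), auc(fccp_series)
    if math.isclose(a_d, a_f, rel_tol=1e-12, abs_tol=1e-12):
        raise ValueError("DMSO and FCCP AUCs coincide: normalization undefined")
    return 100.0 * (a_d - a_s) / (a_d - a_f)


def fit_ec50(doses, response) -> FitResult:
    """Four-parameter logistic on log-dose; returns EC50 with asymptotic CI.

    response(d) = bottom + (top - bottom) / (1 + (EC50/d)^hill)
    """
    doses = np.asarray(doses, float)
    response = np.asarray(response, float)
    if len(doses) < 5:
        raise ValueError("need >= 5 doses")
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0 for a log-dose fit")
    logd = np.log10(doses)

    def model(theta):
        bottom, top, logec50, hill = theta
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - logd) * hill))

    def resid(theta):
        return model(theta) - response

    x0 = np.array([response.min(), response.max(), float(np.median(logd)), 1.0])
    sol = optimize.least_squares(resid, x0,
                                 bounds=([-np.inf, -np.inf, logd.min() - 3, 0.05],
                                         [np.inf, np.inf, logd.max() + 3, 20.0]),
                                 xtol=1e-15, ftol=1e-15, gtol=1e-15)
    bottom, top, logec50, hill = sol.x
    flags = []
    if not sol.success:
        flags.append("non-converged")
    if logec50 <= logd.min() or logec50 >= logd.max():
        flags.append("ec50-outside-dose-range")
    if abs(top - bottom) < 0.05 * max(np.ptp(response), 1e-12):
        flags.append("no-transition")
    se = _asymptotic_se(sol)
    ci = (10.0 ** (logec50 - 1.96 * se[2]), 10.0 ** (logec50 + 1.96 * se[2]))
    params = {"ec50": 10.0 ** logec50, "hill": float(hill),
              "bottom": float(bottom), "top": float(top), "ec50_ci95": ci}
    return FitResult(params, {"log10_ec50": se[2], "hill": se[3]},
                     sol.fun, flags, bool(sol.success))


# --- iBH3 cytochrome-c release --------------------------------------------

def cytc_release(mfi_sample, mfi_alamethicin, mfi_dmso):
    """Cytochrome-c release fraction from median fluorescence intensities.

    release = 1 - (MFI_sample - MFI_alamethicin) / (MFI_DMSO - MFI_alamethicin)

    Not clamped: values outside [0, 1] are returned as computed (callers may
    flag them); degenerate controls raise.
    """
    denom = mfi_dmso - mfi_alamethicin
    if denom == 0:
        raise ValueError("DMSO and alamethicin controls coincide")
    return 1.0 - (mfi_sample - mfi_alamethicin) / denom
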