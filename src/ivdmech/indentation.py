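"""Viscoelastic analysis of ramp-hold spherical indentation.

The material is a standard linear solid (SLS): a spring ``E0`` in parallel
with a Maxwell arm (spring ``E1`` + dashpot, time constant ``tau1``), giving
the relaxation modulus ``G(t) = E0 + E1 exp(-t/tau1)``.  By
elastic-viscoelastic correspondence the elastic operator of the Hertzian
contact solution ``P = 4 sqrt(R) E h^{3/2} / (3 (1 - nu^2))`` is replaced by
a Boltzmann hereditary integral over ``G``:

    P(t) = 4 sqrt(R) / (3 (1 - nu^2)) * int_0^t G(t - u) d[h(u)^{3/2}]/du du

which is solved separately for the loading ramp (``h = v t``) and the hold
(``h = h_max``).  Both phases reduce to the integral
``int_0^t exp(u/tau) sqrt(u) du``, evaluated here in closed form through the
Dawson function, with an adaptive-quadrature route kept as a cross-check.

Unit convention: user-facing quantities are um, uN, kPa, s (the instrument's
units); everything is converted to SI internally.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize, special

from .models import (
    AmbiguousContactError,
    ContactPoint,
    IndentProfile,
    IndentationRecord,
    InsufficientDataError,
    NoContactError,
    SLSFit,
    SLSParams,
    ValidityReport,
)

__all__ = [
    "hertz_force",
    "sls_relaxation",
    "forward_ramp_hold",
    "detect_contact",
    "fit_sls",
    "derived_moduli",
    "check_validity",
]

# unit conversions at the API boundary
_UM = 1e-6  # um -> m
_KPA = 1e3  # kPa -> Pa
_N_TO_UN = 1e6  # N -> uN


def _hertz_prefactor(R_um: float, nu: float) -> float:
    """K = 4 sqrt(R) / (3 (1 - nu^2)) in SI, for R given in um."""
    return 4.0 * np.sqrt(R_um * _UM) / (3.0 * (1.0 - nu**2))


def hertz_force(h, R: float, E: float, nu: float = 0.5):
    """Elastic Hertzian force for a rigid sphere on a half-space.

    Parameters
    ----------
    h : float or ndarray
        Indentation depth, um; must be non-negative.
    R : float
        Tip radius, um.
    E : float
        Young's modulus, kPa.
    nu : float
        Poisson's ratio.

    Returns
    -------
    float or ndarray
        Force in uN: ``P = 4 sqrt(R) E h^{3/2} / (3 (1 - nu^2))``.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("indentation depth must be non-negative")
    K = _hertz_prefactor(R, nu)
    P = K * (E * _KPA) * (h * _UM) ** 1.5 * _N_TO_UN
    return float(P) if P.ndim == 0 else P


def sls_relaxation(t, params: SLSParams):
    """Relaxation modulus G(t) = E0 + E1 exp(-t/tau1) in kPa."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    G = params.E0 + params.E1 * np.exp(-t / params.tau1)
    return float(G) if G.ndim == 0 else G


def _ramp_integral_closed(t: np.ndarray, tau: float) -> np.ndarray:
    """exp(-t/tau) * int_0^t exp(u/tau) sqrt(u) du, closed form.

    Substituting s = u/tau gives tau^{3/2} exp(-x) int_0^x e^s sqrt(s) ds with
    x = t/tau, and int_0^x e^s sqrt(s) ds = e^x sqrt(x) - (sqrt(pi)/2) erfi(sqrt(x)),
    so the damped product is tau^{3/2} (sqrt(x) - dawsn(sqrt(x))) — numerically
    stable for any x >= 0.
    """
    x = np.sqrt(np.maximum(t, 0.0) / tau)
    return tau**1.5 * (x - special.dawsn(x))


def forward_ramp_hold(
    profile: IndentProfile,
    params: SLSParams,
    R: float,
    nu: float,
    t,
    *,
    method: str = "closed",
):
    """Hereditary-integral force response over the loading ramp and hold.

    Parameters
    ----------
    profile : IndentProfile
        Trapezoidal displacement command; only ramp + hold are modelled.
    params : SLSParams
        SLS relaxation parameters in kPa / s.
    R, nu : float
        Tip radius (um) and Poisson's ratio.
    t : array_like
        Times in [0, t_ramp + t_hold], s.
    method : {"closed", "quad"}
        Closed-form (Dawson function) or adaptive-quadrature evaluation of
        the ramp integral.  The two agree to ~1e-12 relative and "quad"
        exists as an independent numerical route.

    Returns
    -------
    ndarray
        Force in uN.
    """
    scalar_input = np.isscalar(t) or np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    t_R = profile.t_ramp
    t_end = t_R + profile.t_hold
    if np.any(t < -1e-12) or np.any(t > t_end + 1e-9):
        raise ValueError("t must lie within [0, t_ramp + t_hold]")
    t = np.clip(t, 0.0, t_end)

    K = _hertz_prefactor(R, nu)
    E0 = params.E0 * _KPA
    E1 = params.E1 * _KPA
    tau = params.tau1
    v = profile.v_load * _UM  # m/s
    h_max = profile.h_max * _UM

    if method == "closed":
        damped = _ramp_integral_closed(np.minimum(t, t_R), tau)
        # hold phase: integral frozen at t_R, then exponential decay
        hold = t > t_R
        damped[hold] = _ramp_integral_closed(np.array([t_R]), tau)[0] * np.exp(
            -(t[hold] - t_R) / tau
        )
    elif method == "quad":
        damped = np.empty_like(t)
        for i, ti in enumerate(t):
            upper = min(ti, t_R)
            val, _ = integrate.quad(
                lambda u, ti=ti: np.exp((u - ti) / tau) * np.sqrt(u),
                0.0,
                upper,
                epsabs=1e-14,
                epsrel=1e-12,
                limit=200,
            )
            damped[i] = val
    else:
        raise ValueError(f"unknown method {method!r}")

    h = np.minimum(v * t, h_max)
    P = K * (E0 * h**1.5 + 1.5 * E1 * v**1.5 * damped)
    P_uN = P * _N_TO_UN
    return float(P_uN[0]) if scalar_input else P_uN


def forward_hereditary_numeric(
    t: np.ndarray,
    h: np.ndarray,
    params: SLSParams,
    R: float,
    nu: float,
) -> np.ndarray:
    """Trapezoid-rule hereditary integral for an arbitrary depth history.

    Used by the synthetic generator for the unload segment, where the
    piecewise closed form above does not apply.  ``h`` in um, output in uN.
    """
    t = np.asarray(t, dtype=float)
    g = np.maximum(np.asarray(h, dtype=float) * _UM, 0.0) ** 1.5
    dgdt = np.gradient(g, t)
    K = _hertz_prefactor(R, nu)
    P = np.empty_like(t)
    for i, ti in enumerate(t):
        Gt = params.E0 * _KPA + params.E1 * _KPA * np.exp(-(ti - t[: i + 1]) / params.tau1)
        P[i] = K * np.trapezoid(Gt * dgdt[: i + 1], t[: i + 1])
    return np.maximum(P, 0.0) * _N_TO_UN


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")
    return out[pad : pad + x.size] if pad else out


def detect_contact(
    record: IndentationRecord,
    abs_threshold: float = 0.003,
    rel_threshold: float = 0.005,
    smooth_window: int = 5,
    persistence: int = 5,
    refine: bool = True,
) -> ContactPoint:
    """Locate tip-sample contact as a sustained force rise above baseline.

    The criterion follows the instrument convention for soft samples: contact
    is called at the first sample where the smoothed force exceeds the
    pre-contact baseline by ``delta = max(abs_threshold,
    rel_threshold * (P_max - baseline))`` — i.e. 0.003 uN or about 0.5 % of
    the maximum force — and stays above for ``persistence`` samples.

    The baseline (mean + linear trend) is estimated in two passes: a first
    crossing found against the leading samples, then the baseline refit on
    everything safely before that crossing.

    With ``refine=True`` (default) the threshold crossing is back-
    extrapolated to the true touch time: the early post-threshold force
    follows the Hertzian power law ``P - P0 ~ (t - t0)^{3/2}``, so
    ``(P - P0)^{2/3}`` is fit linearly in t and its root taken as t0.
    Without refinement the crossing itself is systematically late by the
    time the force needs to build up to the threshold.

    Returns
    -------
    ContactPoint
        Contact index plus (t0, h0, P0) offsets that zero the curve at
        contact.

    Raises
    ------
    NoContactError
        If the force never exceeds the threshold.
    AmbiguousContactError
        If the curve starts above the threshold (no usable baseline).
    """
    P = record.P
    n = P.size
    smooth = _moving_average(P, smooth_window)

    def _crossing(baseline: np.ndarray) -> tuple[int, float]:
        resid = smooth - baseline
        p_max = float(np.max(resid))
        delta = max(abs_threshold, rel_threshold * p_max)
        above = resid > delta
        # first index with `persistence` consecutive True
        run = 0
        for i, flag in enumerate(above):
            run = run + 1 if flag else 0
            if run >= persistence:
                idx = i - persistence + 1
                return idx, delta
        if not above.any():
            raise NoContactError("force never exceeds the contact threshold")
        raise NoContactError("force exceeds the threshold only transiently")

    n0 = max(10, n // 20)
    base0 = np.full(n, np.median(P[:n0]))
    idx0, delta0 = _crossing(base0)
    if idx0 < persistence:
        raise AmbiguousContactError(
            "curve starts above the contact threshold; no pre-contact baseline"
        )

    # refit baseline (mean + drift) on the region safely before the rise
    pre = max(idx0 - smooth_window, 2)
    coeffs = np.polyfit(record.t[:pre], P[:pre], 1)
    # a pre-contact region that itself rises by many thresholds means the
    # record opens already in contact
    if abs(coeffs[0]) * (record.t[pre - 1] - record.t[0]) > 5.0 * delta0:
        raise AmbiguousContactError(
            "force rises steadily from the first sample; curve starts in contact"
        )
    baseline = np.polyval(coeffs, record.t)
    idx, delta = _crossing(baseline)

    t0 = float(record.t[idx])
    if refine:
        resid = P - baseline
        rise = float(np.max(resid))
        # fit P - P0 = A * max(t - t0, 0)^{3/2} over the early rise,
        # including some pre-crossing baseline so t0 is well constrained
        smooth_resid = smooth - baseline
        past = np.where(smooth_resid[idx:] >= 0.25 * rise)[0]
        i_hi = idx + (int(past[0]) if past.size else 10)
        i_hi = int(np.clip(i_hi, idx + 10, min(idx + 200, n - 1)))
        i_lo = max(idx - 50, 0)
        tw, rw = record.t[i_lo : i_hi + 1], resid[i_lo : i_hi + 1]

        def _power_law(x):
            return x[0] * np.maximum(tw - x[1], 0.0) ** 1.5 - rw

        A0 = max(resid[i_hi], delta) / max((record.t[i_hi] - t0 + 1e-9) ** 1.5, 1e-12)
        sol = optimize.least_squares(
            _power_law,
            [A0, t0],
            bounds=([0.0, float(record.t[i_lo])], [np.inf, float(record.t[i_hi])]),
        )
        if sol.success:
            t0 = float(sol.x[1])
            idx = int(np.searchsorted(record.t, t0))

    return ContactPoint(
        index=idx,
        t0=t0,
        h0=float(np.interp(t0, record.t, record.h)),
        P0=float(np.polyval(coeffs, t0)),
        threshold_used=delta,
    )


def _find_ramp_bounds(t: np.ndarray, h: np.ndarray) -> tuple[int, int, float]:
    """Locate ramp end and hold end from the displacement command.

    Ramp end = first sample with h >= 0.99 * h_max (earlier sample on ties);
    hold end = last sample before the displacement drops below that level.
    """
    h_max = float(np.max(h))
    at_top = h >= 0.99 * h_max
    i_ramp_end = int(np.argmax(at_top))
    i_hold_end = int(np.where(at_top)[0][-1])
    return i_ramp_end, i_hold_end, h_max


def fit_sls(
    record: IndentationRecord,
    contact: ContactPoint,
    *,
    hold_only: bool = False,
    max_nfev: int = 2000,
) -> SLSFit:
    """Bounded nonlinear least-squares fit of the ramp-hold SLS model.

    Fits ``forward_ramp_hold`` to the measured force over the loading and
    holding segments only (the unload is excluded, as in the protocol).
    Bounds: E0, E1 >= 0; tau1 in [sample interval, 10 * t_hold].
    Initialised from the hold plateau (E0), the early-ramp secant (E0 + E1)
    and a log-linear fit of the hold decay (tau1); a coarse multi-start grid
    is tried if the first attempt fails to converge.

    Parameters
    ----------
    record : IndentationRecord
    contact : ContactPoint
        From :func:`detect_contact` (or index 0 for pre-zeroed curves).
    hold_only : bool
        Restrict the fit to the hold segment (not the default; the standard
        protocol fits loading + holding).

    Returns
    -------
    SLSFit
    """
    t, h, P = contact.zeroed(record)
    if t.size < 20:
        raise InsufficientDataError("fewer than 20 post-contact samples")

    i_ramp, i_hold, h_max = _find_ramp_bounds(t, h)
    if i_ramp < 3 or i_hold <= i_ramp:
        raise InsufficientDataError("could not identify ramp and hold segments")
    t_H = float(t[i_hold])
    # ramp speed from a mid-ramp regression (the 99 % crossing alone would
    # bias the ramp duration by up to one threshold width)
    mid = (h >= 0.1 * h_max) & (h <= 0.9 * h_max) & (t <= t[i_ramp])
    if mid.sum() >= 5:
        v_load = float(np.polyfit(t[mid], h[mid], 1)[0])
    else:
        v_load = h_max / float(t[i_ramp])
    t_R = h_max / v_load
    profile = IndentProfile(
        v_load=v_load, h_max=h_max, t_hold=max(t_H - t_R, 1e-6), v_unload=v_load
    )

    lo = 1 if hold_only else 0
    sel = slice(i_ramp if hold_only else 0, i_hold + 1)
    t_fit, P_fit = t[sel], P[sel]
    dt = float(np.median(np.diff(t)))
    R, nu = record.tip_radius, record.poisson_ratio

    # --- initial guesses -------------------------------------------------
    K_h = hertz_force(h_max, R, 1.0, nu)  # force per kPa at full depth
    P_plateau = float(np.mean(P[max(i_hold - 5, i_ramp) : i_hold + 1]))
    E0_init = max(P_plateau / K_h, 1e-3)
    # early-ramp secant: at t << tau1 the response is quasi-elastic with E_ins
    i_early = max(3, i_ramp // 4)
    E_ins_init = max(
        float(P[i_early]) / hertz_force(h[i_early], R, 1.0, nu), E0_init * 1.01
    )
    E1_init = E_ins_init - E0_init
    # log-linear hold decay
    decay = P[i_ramp : i_hold + 1] - P_plateau
    pos = decay > max(1e-4 * abs(P_plateau), 1e-12)
    if pos.sum() >= 5:
        slope = np.polyfit(t[i_ramp : i_hold + 1][pos], np.log(decay[pos]), 1)[0]
        tau_init = -1.0 / slope if slope < 0 else profile.t_hold / 5.0
    else:
        tau_init = profile.t_hold / 5.0
    tau_lo, tau_hi = dt, 10.0 * profile.t_hold
    tau_init = float(np.clip(tau_init, tau_lo * 1.5, tau_hi / 1.5))

    def residuals(x: np.ndarray) -> np.ndarray:
        p = SLSParams(E0=x[0], E1=x[1], tau1=x[2])
        return forward_ramp_hold(profile, p, R, nu, t_fit, method="closed") - P_fit

    bounds = ([0.0, 0.0, tau_lo], [np.inf, np.inf, tau_hi])
    scale_E = max(E_ins_init, 1.0)

    def _solve(x0):
        x0 = np.clip(x0, bounds[0], bounds[1])
        return optimize.least_squares(
            residuals,
            x0,
            bounds=bounds,
            x_scale=[scale_E, scale_E, max(tau_init, 1.0)],
            max_nfev=max_nfev,
        )

    result = _solve([E0_init, max(E1_init, 1e-3), tau_init])
    if not result.success or not np.isfinite(result.cost):
        # multi-start fallback over a coarse tau / modulus-split grid
        best = result if np.isfinite(result.cost) else None
        for tau0 in (0.1, 0.5, 2.0, 5.0, 20.0):
            for f0 in (0.1, 0.5, 0.9):
                r = _solve([f0 * E_ins_init, (1 - f0) * E_ins_init, tau0])
                if r.success and (best is None or r.cost < best.cost):
                    best = r
        if best is not None:
            result = best

    x = result.x
    params = SLSParams(E0=float(x[0]), E1=float(x[1]), tau1=float(x[2]))
    pred = residuals(x) + P_fit
    rmse = float(np.sqrt(np.mean((pred - P_fit) ** 2)))
    ss_res = float(np.sum((pred - P_fit) ** 2))
    ss_tot = float(np.sum((P_fit - np.mean(P_fit)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    at_bounds = bool(
        np.isclose(x[2], tau_lo, rtol=1e-3) or np.isclose(x[2], tau_hi, rtol=1e-3)
    )
    return SLSFit.from_params(
        params,
        rmse=rmse,
        r_squared=r2,
        t_ramp_end=t_R,
        t_hold_end=t_H,
        converged=bool(result.success),
        at_bounds=at_bounds,
        n_points=int(t_fit.size - lo),
    )


def derived_moduli(params: SLSParams) -> tuple[float, float, float]:
    """Instantaneous modulus, equilibrium modulus, elastic fraction.

    ``E_ins = E0 + E1`` (kPa), ``E_eq = E0`` (kPa), ``f = E_eq / E_ins``.
    An elastic fraction of 1 is a purely elastic material; 0 is purely
    viscous.
    """
    if params.E_ins == 0:
        raise ZeroDivisionError("elastic fraction undefined for E0 + E1 = 0")
    return params.E_ins, params.E_eq, params.f


def check_validity(
    h_max: float, R: float, section_thickness: float
) -> ValidityReport:
    """Strain and substrate-effect validity checks for one indent.

    Representative strain is Tabor's 0.2 * a / R with contact radius
    a = sqrt(R * h_max); it must stay below 5 %.  The indentation depth must
    stay below 10 % of the section thickness to avoid substrate effects.
    All lengths in um.
    """
    if h_max <= 0 or R <= 0 or section_thickness <= 0:
        raise ValueError("inputs must be positive")
    a = np.sqrt(R * h_max)
    strain = 0.2 * a / R
    ratio = h_max / section_thickness
    return ValidityReport(
        representative_strain=float(strain),
        depth_to_thickness=float(ratio),
        strain_ok=bool(strain < ValidityReport.STRAIN_LIMIT),
        substrate_ok=bool(ratio < ValidityReport.DEPTH_RATIO_LIMIT),
    )
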