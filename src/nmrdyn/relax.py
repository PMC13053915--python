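"""Per-residue relaxation observables from intensity data.

Fits R1/R2 monoexponential decays, computes R2eff and hetNOE ratios with
first-order (Gaussian) error propagation, and fits two-site exchange models
to CPMG dispersion curves with flat-vs-exchange model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exchange import (
    BranchCutError,
    CpmgSchedule,
    DispersionCurve,
    ExchangeParams,
    carver_richards,
    model_rex,
    propagate_cpmg,
)

__all__ = [
    "DecaySeries",
    "NoePair",
    "RateEstimate",
    "DispersionFitResult",
    "InsufficientDataError",
    "fit_monoexponential",
    "compute_r2eff",
    "compute_hetnoe",
    "fit_dispersion",
    "estimate_rex",
]


class InsufficientDataError(ValueError):
    """Too few usable data points for the requested fit."""


@dataclass
class RateEstimate:
    """A fitted rate (or ratio) with its uncertainty and fit quality."""

    value: float
    sigma: float
    quality: float = np.nan  # reduced chi^2 of the parent fit
    flag: str | None = None  # e.g. "non-convergent", "unreliable-ratio"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class DecaySeries:
    """Intensity-vs-delay series for a monoexponential relaxation fit."""

    residue_id: int
    delays: np.ndarray
    intensities: np.ndarray
    sigma_i: float

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(np.unique(self.delays)) < 4:
            raise InsufficientDataError("need >= 4 distinct delays")
        if self.sigma_i <= 0:
            raise ValueError("sigma_i must be positive")


@dataclass
class NoePair:
    """Saturated/reference intensity pair for the steady-state hetNOE."""

    residue_id: int
    i_sat: float
    i_ref: float
    sigma_sat: float
    sigma_ref: float

    def __post_init__(self) -> None:
        if self.i_ref == 0:
            raise ValueError("i_ref must be nonzero")
        if self.sigma_sat <= 0 or self.sigma_ref <= 0:
            raise ValueError("sigmas must be positive")


@dataclass
class DispersionFitResult:
    """Outcome of flat-vs-two-site model selection on a dispersion curve."""

    residue_id: int
    model: str  # "flat" | "two_site"
    rex: RateEstimate
    r2_0: float
    chi2_red: float
    params: ExchangeParams | None = None
    cov: np.ndarray | None = field(default=None, repr=False)


def fit_monoexponential(series: DecaySeries) -> tuple[RateEstimate, RateEstimate]:
    """Weighted least-squares fit of I(t) = I0 exp(-R t).

    Returns (I0 estimate, rate estimate); sigmas come from the fit
    covariance with absolute intensity noise, quality is the reduced chi^2.
    Non-convergence yields a flagged estimate with infinite sigma.
    """
    t, y = series.delays, series.intensities
    if len(t) < 4:
        raise InsufficientDataError("need >= 4 points")
    # log-linear start; guard non-positive intensities
    ypos = np.clip(y, 1e-12 * max(abs(y).max(), 1.0), None)
    slope, intercept = np.polyfit(t, np.log(ypos), 1)
    p0 = (float(np.exp(intercept)), float(max(-slope, 1e-6)))
    try:
        popt, pcov = optimize.curve_fit(
            lambda t, i0, r: i0 * np.exp(-r * t),
            t, y, p0=p0, sigma=np.full_like(y, series.sigma_i),
            absolute_sigma=True, maxfev=10000,
        )
    except RuntimeError:
        bad = RateEstimate(np.nan, np.inf, flag="non-convergent")
        return bad, bad
    resid = (y - popt[0] * np.exp(-popt[1] * t)) / series.sigma_i
    dof = max(len(t) - 2, 1)
    chi2_red = float(resid @ resid) / dof
    perr = np.sqrt(np.diag(pcov))
    i0 = RateEstimate(float(popt[0]), float(perr[0]), chi2_red)
    rate = RateEstimate(float(popt[1]), float(perr[1]), chi2_red)
    return i0, rate


def compute_r2eff(
    i: float, i0: float, t_relax: float, sigma_i: float, sigma_i0: float
) -> RateEstimate:
    """Effective transverse rate from a single constant-time plane.

    R2eff = -ln(i/i0)/t_relax; sigma by first-order propagation of the two
    intensity uncertainties.
    """
    if i <= 0 or i0 <= 0:
        raise ValueError("intensities must be positive (drop the plane upstream)")
    if t_relax <= 0:
        raise ValueError("t_relax must be positive")
    value = -np.log(i / i0) / t_relax
    sigma = (1.0 / t_relax) * np.sqrt((sigma_i / i) ** 2 + (sigma_i0 / i0) ** 2)
    return RateEstimate(float(value), float(sigma))


def compute_hetnoe(pair: NoePair) -> RateEstimate:
    """Steady-state heteronuclear NOE ratio I_sat/I_ref.

    Sigma by first-order ratio propagation; negative ratios (flexible tails)
    are legitimate.  Flags the estimate when i_ref is within 3 sigma of zero.
    """
    value = pair.i_sat / pair.i_ref
    sigma = abs(value) * np.sqrt(
        (pair.sigma_sat / pair.i_sat) ** 2 + (pair.sigma_ref / pair.i_ref) ** 2
    ) if pair.i_sat != 0 else pair.sigma_sat / abs(pair.i_ref)
    flag = "unreliable-ratio" if abs(pair.i_ref) < 3 * pair.sigma_ref else None
    return RateEstimate(float(value), float(sigma), flag=flag)


# multi-start grid for the two-site dispersion fit
_KEX_STARTS = np.geomspace(100.0, 1e4, 5)
_DW_STARTS = np.geomspace(50.0, 3000.0, 4)
_PB_STARTS = (0.01, 0.03, 0.1)


def _two_site_forward(
    nu: np.ndarray, p_b: float, k_ex: float, d_omega: float, r2_0: float,
    t_relax: float,
) -> np.ndarray:
    params = ExchangeParams(p_b=p_b, k_ex=k_ex, delta_omega=d_omega, r2_a=r2_0)
    try:
        return np.asarray(carver_richards(params, nu, t_relax=t_relax))
    except BranchCutError:
        return np.array([propagate_cpmg(params, t_relax, x) for x in nu])


def fit_dispersion(
    curve: DispersionCurve,
    schedule: CpmgSchedule,
    alpha: float = 0.01,
    n_refine: int = 3,
) -> DispersionFitResult:
    """Fit flat and two-site exchange models; keep the exchange model only
    when an F-test on the weighted residual sums supports it at level alpha.

    The two-site model (equal intrinsic rates for both states) is fitted by
    bounded weighted least squares from a multi-start grid over
    (p_b, k_ex, delta_omega); the best ``n_refine`` grid points are refined.
    Rex and its sigma come from the fitted parameters by first-order
    propagation of the parameter covariance through the model.
    """
    nu, y, sig = curve.nu_cpmg, curve.r2_eff, curve.sigma_r2_eff
    if len(nu) < 6:
        raise InsufficientDataError("need >= 6 dispersion points")

    # flat model: weighted mean
    w = 1.0 / sig**2
    flat = float(np.sum(w * y) / np.sum(w))
    chi2_flat = float(np.sum(((y - flat) / sig) ** 2))
    dof_flat = len(nu) - 1
    sigma_flat = float(np.sqrt(1.0 / np.sum(w)))
    flat_quality = chi2_flat / max(dof_flat, 1)

    def residuals(theta: np.ndarray) -> np.ndarray:
        pb, kex, dw, r20 = theta
        return (_two_site_forward(nu, pb, kex, dw, r20, schedule.t_relax) - y) / sig

    # coarse grid scan, then refine the best few starts
    r20_start = float(np.min(y))
    grid = [
        np.array([pb, kex, dw, r20_start])
        for pb in _PB_STARTS for kex in _KEX_STARTS for dw in _DW_STARTS
    ]
    scores = []
    for theta in grid:
        with np.errstate(all="ignore"):
            r = residuals(theta)
        scores.append(np.sum(r**2) if np.all(np.isfinite(r)) else np.inf)
    # when no grid start improves on the flat chi^2 the curve is likely
    # flat; one refinement suffices to let the F-test decide
    if min(scores) >= chi2_flat:
        n_refine = 1
    order = np.argsort(scores)[:n_refine]

    bounds = ([1e-4, 10.0, 1.0, 0.0], [0.5, 1e5, 2e4, 200.0])
    best = None
    for idx in order:
        try:
            sol = optimize.least_squares(
                residuals, grid[idx], bounds=bounds, xtol=1e-10, ftol=1e-10,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    def flat_result() -> DispersionFitResult:
        return DispersionFitResult(
            residue_id=curve.residue_id, model="flat",
            rex=RateEstimate(0.0, sigma_flat, flat_quality),
            r2_0=flat, chi2_red=flat_quality,
        )

    if best is None:
        warnings.warn(f"residue {curve.residue_id}: two-site fit did not converge")
        return flat_result()

    chi2_two = float(2.0 * best.cost)
    dof_two = len(nu) - 4
    if dof_two < 1:
        return flat_result()

    # F-test: does the 3 extra parameters' improvement exceed noise?
    num = (chi2_flat - chi2_two) / (dof_flat - dof_two)
    den = chi2_two / dof_two
    if den <= 0:
        p_val = 0.0 if chi2_flat > chi2_two else 1.0
    else:
        f_stat = num / den
        p_val = float(stats.f.sf(f_stat, dof_flat - dof_two, dof_two))
    if not (chi2_two < chi2_flat and p_val < alpha):
        return flat_result()

    pb, kex, dw, r20 = best.x
    params = ExchangeParams(p_b=float(pb), k_ex=float(kex),
                            delta_omega=float(dw), r2_a=float(r20))
    # covariance from J^T J (residuals already noise-whitened)
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(J.T @ J)

    rex_val = model_rex(params, schedule)
    grad = _rex_gradient(best.x, schedule)
    rex_sig = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    chi2_red = chi2_two / dof_two
    return DispersionFitResult(
        residue_id=curve.residue_id, model="two_site",
        rex=RateEstimate(float(max(rex_val, 0.0)), rex_sig, chi2_red),
        r2_0=float(r20), chi2_red=chi2_red, params=params, cov=cov,
    )


def _rex_gradient(theta: np.ndarray, schedule: CpmgSchedule) -> np.ndarray:
    """Numerical gradient of model Rex with respect to the fit parameters."""

    def rex_of(th: np.ndarray) -> float:
        p = ExchangeParams(p_b=th[0], k_ex=th[1], delta_omega=th[2], r2_a=th[3])
        return model_rex(p, schedule)

    grad = np.zeros(4)
    for i in range(4):
        h = max(1e-6 * abs(theta[i]), 1e-8)
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] = max(dn[i] - h, 0.0 if i != 0 else 1e-6)
        grad[i] = (rex_of(up) - rex_of(dn)) / (up[i] - dn[i])
    return grad


def fit_dispersion_global(
    curves: list[DispersionCurve],
    schedule: CpmgSchedule,
    alpha: float = 0.01,
) -> list[DispersionFitResult]:
    """Grouped two-site fit sharing (p_b, k_ex) across residues.

    Residues reporting on a single exchange process share its population and
    rate; only delta_omega and the intrinsic rate are site-specific.
    Fitting the group jointly is the standard way to stabilise k_ex when a
    single curve leaves it poorly determined.  Parameters:
    (p_b, k_ex, dw_1..dw_m, r20_1..r20_m).

    Curves whose individual fit prefers the flat model are excluded from the
    group and returned with their per-curve (flat) result.
    """
    singles = [fit_dispersion(c, schedule, alpha=alpha) for c in curves]
    group = [i for i, f in enumerate(singles) if f.model == "two_site"]
    if len(group) < 2:
        return singles

    m = len(group)
    sel = [curves[i] for i in group]
    pb0 = float(np.median([singles[i].params.p_b for i in group]))
    kex0 = float(np.median([singles[i].params.k_ex for i in group]))
    dw0 = [singles[i].params.delta_omega for i in group]
    r200 = [singles[i].r2_0 for i in group]
    theta0 = np.concatenate([[pb0, kex0], dw0, r200])

    def residuals(theta: np.ndarray) -> np.ndarray:
        pb, kex = theta[0], theta[1]
        out = []
        for j, c in enumerate(sel):
            dw, r20 = theta[2 + j], theta[2 + m + j]
            pred = _two_site_forward(c.nu_cpmg, pb, kex, dw, r20, schedule.t_relax)
            out.append((pred - c.r2_eff) / c.sigma_r2_eff)
        return np.concatenate(out)

    lo = [1e-4, 10.0] + [1.0] * m + [0.0] * m
    hi = [0.5, 1e5] + [2e4] * m + [200.0] * m
    sol = optimize.least_squares(residuals, theta0, bounds=(lo, hi),
                                 xtol=1e-10, ftol=1e-10)
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(J.T @ J)
    n_obs = sum(len(c.nu_cpmg) for c in sel)
    dof = max(n_obs - len(theta0), 1)
    chi2_red = float(2.0 * sol.cost) / dof

    results = list(singles)
    for j, i in enumerate(group):
        params = ExchangeParams(
            p_b=float(sol.x[0]), k_ex=float(sol.x[1]),
            delta_omega=float(sol.x[2 + j]), r2_a=float(sol.x[2 + m + j]),
        )
        theta_j = np.array([params.p_b, params.k_ex, params.delta_omega,
                            params.r2_a])
        idx = [0, 1, 2 + j, 2 + m + j]
        cov_j = cov[np.ix_(idx, idx)]
        grad = _rex_gradient(theta_j, schedule)
        rex_sig = float(np.sqrt(max(grad @ cov_j @ grad, 0.0)))
        rex_val = model_rex(params, schedule)
        results[i] = DispersionFitResult(
            residue_id=curves[i].residue_id, model="two_site",
            rex=RateEstimate(float(max(rex_val, 0.0)), rex_sig, chi2_red),
            r2_0=params.r2_a, chi2_red=chi2_red, params=params, cov=cov_j,
        )
    return results


def estimate_rex(fit: DispersionFitResult, schedule: CpmgSchedule) -> RateEstimate:
    """Exchange contribution between the schedule's frequency endpoints.

    For a two-site fit this is model Rex at the fitted parameters with the
    covariance-propagated sigma; a flat fit reports 0 with the flat-fit
    uncertainty.
    """
    if fit.model == "flat":
        return RateEstimate(0.0, fit.rex.sigma, fit.chi2_red)
    assert fit.params is not None
    value = model_rex(fit.params, schedule)
    return RateEstimate(float(max(value, 0.0)), fit.rex.sigma, fit.chi2_red)
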