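"""Two-site chemical-exchange CPMG relaxation dispersion.

The transverse magnetisation of an amide nitrogen exchanging between two
conformations A ⇌ B (populations ``pA = 1 - p_b``, ``pB = p_b``, exchange
rate ``k_ex = k_AB + k_BA``, chemical-shift difference ``delta_omega``)
evolves under the Bloch–McConnell equations.  In a constant-time CPMG
experiment the decay of the summed magnetisation over the relaxation delay
``t_relax``, sampled at different refocusing frequencies ``nu_cpmg``, yields
an effective transverse rate R2eff(nu) whose dispersion encodes the exchange
parameters.

Three routes to R2eff are provided:

``propagate_cpmg``
    exact numerical propagation of the 2×2 complex evolution matrix through
    the pulse train (the reference implementation used by the synthetic-data
    engine);
``carver_richards``
    the standard closed-form expression for two-site CPMG exchange, valid in
    all exchange regimes, used as the fast forward model for fitting;
``luz_meiboom``
    the fast-exchange (k_ex >> delta_omega) limit.

Conventions: ``nu_cpmg = n / (2 t_relax)`` with ``n`` refocusing pulses,
inter-pulse delay ``tau = 1/(2 nu)``, echo element tau/2 – 180° – tau/2; the
180° pulses are instantaneous and perfect (complex conjugation of the
magnetisation).  ``delta_omega`` is stored in rad/s; conversion from ppm
requires a spectrometer frequency (see :func:`ppm_to_rad_per_s`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "ExchangeParams",
    "CpmgSchedule",
    "DispersionCurve",
    "ScheduleError",
    "BranchCutError",
    "ppm_to_rad_per_s",
    "propagate_cpmg",
    "carver_richards",
    "luz_meiboom",
    "model_rex",
    "simulate_dispersion",
    "DEFAULT_N15_LARMOR_MHZ",
]

#: 15N Larmor frequency (MHz) at a 600 MHz (1H) spectrometer.
DEFAULT_N15_LARMOR_MHZ = 60.8


def ppm_to_rad_per_s(delta_ppm: float, larmor_mhz: float = DEFAULT_N15_LARMOR_MHZ) -> float:
    """Convert a 15N chemical-shift difference from ppm to rad/s."""
    return 2.0 * np.pi * larmor_mhz * delta_ppm


class ScheduleError(ValueError):
    """CPMG frequency incompatible with the constant relaxation delay."""


class BranchCutError(ArithmeticError):
    """Closed-form expression numerically unstable; use the propagator."""


@dataclass(frozen=True)
class ExchangeParams:
    """Ground-truth or fitted parameters of a two-site exchange process.

    Attributes
    ----------
    p_b : population of state B (fraction); by convention B is the minor
        state (p_b < 0.5), but any value in [0, 1) is accepted so that the
        physics is expressible under state relabeling
    k_ex : exchange rate constant k_AB + k_BA (1/s)
    delta_omega : shift difference between states (rad/s)
    r2_a, r2_b : intrinsic transverse rates of the two states (1/s)
    """

    p_b: float
    k_ex: float
    delta_omega: float
    r2_a: float
    r2_b: float | None = None

    def __post_init__(self) -> None:
        if self.r2_b is None:
            object.__setattr__(self, "r2_b", self.r2_a)
        if not 0.0 <= self.p_b < 1.0:
            raise ValueError(f"p_b must be in [0, 1), got {self.p_b}")
        if self.k_ex < 0:
            raise ValueError(f"k_ex must be >= 0, got {self.k_ex}")
        if self.r2_a < 0 or self.r2_b < 0:
            raise ValueError("intrinsic R2 rates must be >= 0")
        if not np.isfinite(self.delta_omega):
            raise ValueError("delta_omega must be finite")

    @property
    def p_a(self) -> float:
        return 1.0 - self.p_b


@dataclass(frozen=True)
class CpmgSchedule:
    """Constant-time CPMG sampling schedule.

    ``nu_cpmg`` lists the refocusing frequencies (Hz); every nu must imply an
    integer pulse count ``n = 2 nu t_relax``.  The reference plane (no pulse
    train, nu = 0 sentinel in data files) is implicit and not listed here.
    """

    t_relax: float = 0.04
    nu_cpmg: tuple[float, ...] = field(
        default_factory=lambda: (25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0,
                                 400.0, 500.0, 700.0, 1000.0, 1500.0, 2000.0)
    )

    def __post_init__(self) -> None:
        if self.t_relax <= 0:
            raise ValueError("t_relax must be positive")
        object.__setattr__(self, "nu_cpmg", tuple(sorted(self.nu_cpmg)))
        for nu in self.nu_cpmg:
            self.n_pulses(nu)

    def n_pulses(self, nu: float, tol: float = 1e-6) -> int:
        if nu <= 0:
            raise ScheduleError(f"nu_cpmg must be positive, got {nu}")
        n = 2.0 * nu * self.t_relax
        n_int = int(round(n))
        if n_int < 1 or abs(n - n_int) > tol:
            raise ScheduleError(
                f"nu={nu} Hz implies non-integer pulse count {n:.6f} "
                f"for t_relax={self.t_relax} s"
            )
        return n_int

    @property
    def nu_min(self) -> float:
        return self.nu_cpmg[0]

    @property
    def nu_max(self) -> float:
        return self.nu_cpmg[-1]


@dataclass
class DispersionCurve:
    """Per-residue R2eff(nu_cpmg) with uncertainties."""

    residue_id: int
    nu_cpmg: np.ndarray
    r2_eff: np.ndarray
    sigma_r2_eff: np.ndarray

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2_eff = np.asarray(self.r2_eff, dtype=float)
        self.sigma_r2_eff = np.asarray(self.sigma_r2_eff, dtype=float)
        if not (len(self.nu_cpmg) == len(self.r2_eff) == len(self.sigma_r2_eff)):
            raise ValueError("nu_cpmg, r2_eff, sigma_r2_eff must have equal length")
        if np.any(self.sigma_r2_eff <= 0):
            raise ValueError("sigma_r2_eff must be positive")


def _evolution_matrix(params: ExchangeParams) -> np.ndarray:
    """2×2 complex Bloch–McConnell evolution matrix (free precession).

    The rotating frame is placed on the major-state resonance; the minor
    state precesses at +delta_omega.
    """
    k_ab = params.p_b * params.k_ex
    k_ba = params.p_a * params.k_ex
    return np.array(
        [
            [-params.r2_a - k_ab, k_ba],
            [k_ab, -params.r2_b - k_ba + 1j * params.delta_omega],
        ],
        dtype=complex,
    )


def propagate_cpmg(params: ExchangeParams, t_relax: float, nu: float) -> float:
    """R2eff at one CPMG frequency by numerical Bloch–McConnell propagation.

    The pulse train is n repeats of (tau/2 – 180° – tau/2), tau = 1/(2 nu),
    n = 2 nu t_relax.  Starting from equilibrium magnetisation (pA, pB), the
    observable is the magnitude of the summed site magnetisations and

        R2eff = -(1/t_relax) * ln(|M(t_relax)| / |M(0)|).
    """
    schedule = CpmgSchedule(t_relax=t_relax, nu_cpmg=(nu,))
    n = schedule.n_pulses(nu)
    tau = 1.0 / (2.0 * nu)

    L = _evolution_matrix(params)
    P = expm(L * (tau / 2.0))
    # One echo element maps M -> P conj(P M) = P conj(P) conj(M) =: A conj(M);
    # two consecutive elements are the linear map B = A conj(A).
    A = P @ np.conj(P)
    m0 = np.array([params.p_a, params.p_b], dtype=complex)

    B = A @ np.conj(A)
    m = np.linalg.matrix_power(B, n // 2) @ m0
    if n % 2:
        m = A @ np.conj(m)

    signal = abs(m.sum())
    if signal <= 0 or not np.isfinite(signal):
        raise ArithmeticError("magnetisation underflow/overflow in CPMG propagation")
    return -np.log(signal) / t_relax


def _expm2_analytic(L: np.ndarray, t: float) -> np.ndarray:
    """Closed-form matrix exponential of a 2×2 complex matrix times t.

    exp(Lt) = e^{mu t} [cosh(q t) I + sinh(q t)/q (L - mu I)], with
    mu = tr(L)/2 and q^2 = ((a-d)/2)^2 + bc.
    """
    mu = 0.5 * (L[0, 0] + L[1, 1])
    q2 = (0.5 * (L[0, 0] - L[1, 1])) ** 2 + L[0, 1] * L[1, 0]
    q = np.sqrt(q2)
    eye = np.eye(2, dtype=complex)
    if abs(q * t) < 1e-12:
        core = eye + t * (L - mu * eye)
    else:
        core = np.cosh(q * t) * eye + (np.sinh(q * t) / q) * (L - mu * eye)
    return np.exp(mu * t) * core


def _matpow2_analytic(B: np.ndarray, k: int) -> np.ndarray:
    """B^k for a 2×2 complex matrix via its characteristic polynomial."""
    tr = B[0, 0] + B[1, 1]
    det = B[0, 0] * B[1, 1] - B[0, 1] * B[1, 0]
    disc = np.sqrt(tr * tr - 4.0 * det)
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    eye = np.eye(2, dtype=complex)
    if abs(l1 - l2) < 1e-14 * max(abs(l1), 1.0):
        lam = 0.5 * (l1 + l2)
        return (lam**k) * eye + k * lam ** (k - 1) * (B - lam * eye)
    return ((l1**k) * (B - l2 * eye) - (l2**k) * (B - l1 * eye)) / (l1 - l2)


def _exact_closed_form(params: ExchangeParams, t_relax: float, nus) -> np.ndarray:
    """Exact finite-train R2eff via analytic diagonalisation (vectorised).

    Same observable and pulse-train convention as :func:`propagate_cpmg`,
    but every step (matrix exponential, echo-train accumulation) is
    evaluated in closed form rather than numerically, so the two routes are
    independent.
    """
    nus = np.atleast_1d(np.asarray(nus, dtype=float))
    schedule = CpmgSchedule(t_relax=t_relax, nu_cpmg=tuple(np.unique(nus)))
    n = np.array([schedule.n_pulses(x) for x in nus])
    tau = 1.0 / (2.0 * nus)

    L = _evolution_matrix(params)
    mu = 0.5 * (L[0, 0] + L[1, 1])
    q = np.sqrt((0.5 * (L[0, 0] - L[1, 1])) ** 2 + L[0, 1] * L[1, 0])
    t = tau / 2.0
    eye = np.eye(2, dtype=complex)[None, :, :]
    core = L[None, :, :] - mu * eye
    qt = q * t
    sinc = np.where(np.abs(qt) < 1e-12, t, np.sinh(qt) / np.where(q == 0, 1, q))
    P = np.exp(mu * t)[:, None, None] * (
        np.cosh(qt)[:, None, None] * eye + sinc[:, None, None] * core
    )
    A = P @ np.conj(P)
    B = A @ np.conj(A)

    # B^K per plane via the characteristic polynomial (K = n // 2)
    tr = B[:, 0, 0] + B[:, 1, 1]
    det = B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] * B[:, 1, 0]
    disc = np.sqrt(tr * tr - 4.0 * det)
    l1, l2 = 0.5 * (tr + disc), 0.5 * (tr - disc)
    K = n // 2
    m0 = np.array([params.p_a, params.p_b], dtype=complex)
    degen = np.abs(l1 - l2) < 1e-14 * np.maximum(np.abs(l1), 1.0)
    eyeB = np.eye(2, dtype=complex)[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        pow_nd = (
            (l1**K)[:, None, None] * (B - l2[:, None, None] * eyeB)
            - (l2**K)[:, None, None] * (B - l1[:, None, None] * eyeB)
        ) / (l1 - l2)[:, None, None]
    lam = 0.5 * (l1 + l2)
    pow_d = (lam**K)[:, None, None] * eyeB + (K * lam ** np.maximum(K - 1, 0))[
        :, None, None
    ] * (B - lam[:, None, None] * eyeB)
    Bk = np.where(degen[:, None, None], pow_d, pow_nd)
    m = Bk @ m0
    odd = n % 2 == 1
    if np.any(odd):
        m[odd] = np.einsum("nij,nj->ni", A[odd], np.conj(m[odd]))
    signal = np.abs(m.sum(axis=1))
    if np.any(signal <= 0) or not np.all(np.isfinite(signal)):
        raise BranchCutError("closed-form signal underflow")
    return -np.log(signal) / t_relax


def carver_richards(params: ExchangeParams, nu, t_relax: float | None = None):
    """Closed-form R2eff for two-site CPMG exchange (Carver–Richards).

    With ``t_relax`` given, evaluates the exact closed-form solution for the
    finite pulse train (analytic diagonalisation of the echo-train operator;
    equivalent to Baldwin's exact two-site expression), which includes the
    amplitude factor that the asymptotic formula drops and therefore matches
    the constant-time experiment at every pulse count.

    Without ``t_relax``, evaluates the classic large-n asymptotic expression
    (Carver & Richards 1972, in the algebraic form of Davis, Perlman &
    London 1994):

        R2eff = 1/2 [ R2A + R2B + kex
                      - 2 nu * acosh( D+ cosh(eta+) - D- cos(eta-) ) ]

    with Psi, zeta, D± and eta± as defined below and inter-pulse delay
    tau_cp = 1/(2 nu).  Raises :class:`BranchCutError` when the expression
    is numerically unstable, signalling the caller to fall back to
    :func:`propagate_cpmg`.

    ``nu`` may be a scalar or array (Hz, > 0).
    """
    if t_relax is not None:
        out = _exact_closed_form(params, t_relax, nu)
        return out if np.ndim(nu) else float(out[0])
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("nu must be positive")
    pa, pb = params.p_a, params.p_b
    kex, dw = params.k_ex, params.delta_omega
    r2a, r2b = params.r2_a, params.r2_b

    if pb == 0.0 or kex == 0.0:
        out = np.full_like(nu, r2a)
        return out if out.ndim else float(out)
    if pa == 0.0:
        out = np.full_like(nu, r2b)
        return out if out.ndim else float(out)
    if dw == 0.0 and r2a == r2b:
        out = np.full_like(nu, r2a)
        return out if out.ndim else float(out)

    dr = r2a - r2b - pa * kex + pb * kex
    psi = dr * dr - dw * dw + 4.0 * pa * pb * kex * kex
    zeta = 2.0 * dw * dr
    root = np.sqrt(psi * psi + zeta * zeta)

    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw * dw) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw * dw) / root)

    tau_cp = 1.0 / (2.0 * nu)
    eta_plus = (tau_cp / np.sqrt(2.0)) * np.sqrt(np.maximum(psi + root, 0.0))
    eta_minus = (tau_cp / np.sqrt(2.0)) * np.sqrt(np.maximum(root - psi, 0.0))

    with np.errstate(over="raise"):
        try:
            arg = d_plus * np.cosh(eta_plus) - d_minus * np.cos(eta_minus)
        except FloatingPointError as exc:
            raise BranchCutError("cosh overflow in Carver-Richards") from exc
    if np.any(arg < 1.0):
        raise BranchCutError(
            "acosh argument below 1; closed form unstable for these parameters"
        )
    r2eff = 0.5 * (r2a + r2b + kex - 2.0 * nu * np.arccosh(arg))
    if not np.all(np.isfinite(r2eff)):
        raise BranchCutError("non-finite Carver-Richards result")
    return r2eff if r2eff.ndim else float(r2eff)


def luz_meiboom(params: ExchangeParams, nu) -> float | np.ndarray:
    """Fast-exchange-limit R2eff (Luz–Meiboom).

        R2eff = R2_0 + (pA pB dw^2 / kex) * [1 - (4 nu / kex) tanh(kex / (4 nu))]

    with R2_0 the population-weighted intrinsic rate.  Intended for
    k_ex >> delta_omega.
    """
    nu = np.asarray(nu, dtype=float)
    r2_0 = params.p_a * params.r2_a + params.p_b * params.r2_b
    if params.k_ex == 0.0:
        out = np.full_like(nu, r2_0)
        return out if out.ndim else float(out)
    x = params.k_ex / (4.0 * nu)
    phi = params.p_a * params.p_b * params.delta_omega**2
    r2eff = r2_0 + (phi / params.k_ex) * (1.0 - np.tanh(x) / x)
    return r2eff if r2eff.ndim else float(r2eff)


def model_rex(params: ExchangeParams, schedule: CpmgSchedule) -> float:
    """Exchange contribution Rex = R2eff(nu_min) - R2eff(nu_max).

    Both endpoints are evaluated with the numerical propagator, so the value
    is exact for the stated pulse-train convention.
    """
    lo = propagate_cpmg(params, schedule.t_relax, schedule.nu_min)
    hi = propagate_cpmg(params, schedule.t_relax, schedule.nu_max)
    return lo - hi


def simulate_dispersion(
    params: ExchangeParams,
    schedule: CpmgSchedule,
    noise_fraction: float,
    rng_seed: int,
    i0: float = 1.0,
) -> DispersionCurve:
    """Generate a noisy dispersion curve with propagated uncertainties.

    Plane intensities I(nu) = I0 exp(-R2eff(nu) t_relax) receive additive
    Gaussian noise of sd = noise_fraction * I0, as does the reference plane.
    Noisy planes with non-positive intensity are dropped from the curve.
    Deterministic for a given seed.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    rng = np.random.default_rng(rng_seed)
    nus = np.array(schedule.nu_cpmg)
    r2 = np.array([propagate_cpmg(params, schedule.t_relax, nu) for nu in nus])
    ideal = i0 * np.exp(-r2 * schedule.t_relax)

    sigma_i = noise_fraction * i0
    if noise_fraction == 0.0:
        intensities, i_ref = ideal, i0
        # report the floor uncertainty so the curve remains well formed
        sigma_eff = np.full_like(ideal, 1e-12)
        return DispersionCurve(0, nus, r2, sigma_eff)

    i_ref = i0 + rng.normal(0.0, sigma_i)
    intensities = ideal + rng.normal(0.0, sigma_i, size=ideal.shape)
    keep = (intensities > 0) & (i_ref > 0)
    intensities, nus_kept = intensities[keep], nus[keep]

    r2_eff = -np.log(intensities / i_ref) / schedule.t_relax
    sigma_r2 = (1.0 / schedule.t_relax) * np.sqrt(
        (sigma_i / intensities) ** 2 + (sigma_i / i_ref) ** 2
    )
    return DispersionCurve(0, nus_kept, r2_eff, sigma_r2)
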