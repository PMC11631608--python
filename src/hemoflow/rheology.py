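"""Carreau–Yasuda blood rheology and single-tube flow.

The constitutive law is

    η(γ̇) = η∞ + (η0 − η∞) · [1 + (λ γ̇)^a]^((n−1)/a)

which interpolates between a zero-shear Newtonian plateau η0 and an
infinite-shear plateau η∞, shear-thinning in between for 0 < n ≤ 1.

Steady fully developed flow of such a fluid through a rigid circular tube is
obtained from the Weissenberg–Rabinowitsch–Mooney relation

    Q = (π R³ / τ_w³) ∫₀^{τ_w} τ² γ̇(τ) dτ ,   τ_w = Δp·R / (2L),

where γ̇(τ) inverts the (strictly increasing) stress law τ = η(γ̇)·γ̇.
Inertia is neglected throughout; at capillary scale the Reynolds number is
far below unity (reported as a diagnostic by the network solver).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "RheologyParams",
    "CYFitResult",
    "cy_viscosity",
    "shear_rate_from_stress",
    "tube_flow",
    "fit_cy_params",
    "FlowTable",
]

#: whole-blood density, kg/m³
BLOOD_DENSITY = 1050.0

#: widely used whole-blood Carreau–Yasuda constants
DEFAULT_ETA0 = 0.16        # Pa·s, zero-shear plateau
DEFAULT_ETA_INF = 0.0035   # Pa·s, infinite-shear plateau
DEFAULT_LAMBDA = 8.2       # s, relaxation time
DEFAULT_A = 0.64           # Yasuda transition exponent
DEFAULT_N = 0.2128         # power-law index


class RheologyError(ValueError):
    """Invalid rheological parameters or inputs."""


@dataclass(frozen=True)
class RheologyParams:
    """Carreau–Yasuda constants plus fluid density.

    Invariants: ``eta0 >= eta_inf > 0``, ``lam >= 0``, ``a > 0``,
    ``0 < n <= 1``, ``rho > 0``.
    """

    eta0: float = DEFAULT_ETA0
    eta_inf: float = DEFAULT_ETA_INF
    lam: float = DEFAULT_LAMBDA
    a: float = DEFAULT_A
    n: float = DEFAULT_N
    rho: float = BLOOD_DENSITY

    def __post_init__(self) -> None:
        if not (self.eta0 >= self.eta_inf > 0):
            raise RheologyError("require eta0 >= eta_inf > 0")
        if self.lam < 0:
            raise RheologyError("relaxation time lam must be >= 0")
        if self.a <= 0:
            raise RheologyError("Yasuda exponent a must be > 0")
        if not (0 < self.n <= 1):
            raise RheologyError("power index n must lie in (0, 1]")
        if self.rho <= 0:
            raise RheologyError("density rho must be > 0")

    @property
    def is_newtonian(self) -> bool:
        return self.lam == 0.0 or self.eta0 == self.eta_inf

    @classmethod
    def newtonian(cls, eta: float, rho: float = BLOOD_DENSITY) -> "RheologyParams":
        return cls(eta0=eta, eta_inf=eta, lam=0.0, a=1.0, n=1.0, rho=rho)


def cy_viscosity(gamma_dot, params: RheologyParams):
    """Apparent viscosity η(γ̇) in Pa·s; accepts scalars or arrays, γ̇ >= 0."""
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise RheologyError("shear rate must be >= 0")
    eta = params.eta_inf + (params.eta0 - params.eta_inf) * (
        1.0 + (params.lam * g) ** params.a
    ) ** ((params.n - 1.0) / params.a)
    return float(eta) if np.isscalar(gamma_dot) else eta


def _stress(gamma_dot, params: RheologyParams):
    return cy_viscosity(gamma_dot, params) * np.asarray(gamma_dot, dtype=float)


def shear_rate_from_stress(tau_w: float, params: RheologyParams, rtol: float = 1e-10) -> float:
    """Invert τ = η(γ̇)·γ̇ for the unique γ̇ >= 0 giving wall stress ``tau_w``.

    The map γ̇ ↦ η(γ̇)·γ̇ is strictly increasing for 0 < n <= 1, so the root is
    bracketed by [τ/η0, τ/η∞] and found with Brent's method.
    """
    if tau_w < 0:
        raise RheologyError("wall shear stress must be >= 0")
    if tau_w == 0.0:
        return 0.0
    if params.is_newtonian:
        return tau_w / params.eta0
    lo = tau_w / params.eta0
    hi = tau_w / params.eta_inf
    return float(
        optimize.brentq(lambda g: _stress(g, params) - tau_w, lo, hi, rtol=max(rtol, 4e-16))
    )


def _shear_rate_many(tau: np.ndarray, params: RheologyParams, iters: int = 90) -> np.ndarray:
    """Vectorised inversion of the stress law by bisection on [τ/η0, τ/η∞]."""
    tau = np.asarray(tau, dtype=float)
    lo = tau / params.eta0
    hi = tau / params.eta_inf
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        too_low = _stress(mid, params) < tau
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def tube_flow(R: float, L: float, dp: float, params: RheologyParams) -> float:
    """Volumetric flow (m³/s) through a tube of radius ``R`` and length ``L`` (m)
    under pressure drop ``dp`` (Pa), via the WRM integral.

    Antisymmetric in ``dp``; reduces to Hagen–Poiseuille for Newtonian
    parameters.  Adaptive quadrature at relative tolerance 1e-8.
    """
    if R <= 0 or L <= 0:
        raise RheologyError("tube radius and length must be > 0")
    if dp == 0.0:
        return 0.0
    sign = 1.0 if dp > 0 else -1.0
    tau_w = abs(dp) * R / (2.0 * L)
    if params.is_newtonian:
        return sign * math.pi * R**4 * abs(dp) / (8.0 * params.eta0 * L)
    integral, _ = integrate.quad(
        lambda t: t * t * shear_rate_from_stress(t, params),
        0.0,
        tau_w,
        epsabs=0.0,
        epsrel=1e-8,
        limit=200,
    )
    return sign * math.pi * R**3 * integral / tau_w**3


class FlowTable:
    """Fast vectorised tube flow for one parameter set.

    Precomputes γ̇(τ) on a dense logarithmic grid of wall stresses, integrates
    the WRM kernel cumulatively (Simpson), and interpolates log–log.  Below the
    grid the fluid is on its zero-shear plateau and the Hagen–Poiseuille
    closed form with η0 applies.  Agreement with :func:`tube_flow` is at the
    1e-6 relative level (covered by tests); the network solver uses this table
    for its inner iterations.
    """

    TAU_MIN = 1e-8   # Pa
    TAU_MAX = 1e7    # Pa
    N_POINTS = 8193

    def __init__(self, params: RheologyParams):
        self.params = params
        if params.is_newtonian:
            return
        log_tau = np.linspace(math.log(self.TAU_MIN), math.log(self.TAU_MAX), self.N_POINTS)
        tau = np.exp(log_tau)
        gamma = _shear_rate_many(tau, params)
        # I(τ_w) = ∫ t² γ̇ dt = ∫ t³ γ̇ d(log t); start value from the η0 plateau
        kernel = tau**3 * gamma
        cum = integrate.cumulative_simpson(kernel, x=log_tau, initial=0.0)
        i0 = self.TAU_MIN**4 / (4.0 * params.eta0)
        self._log_tau = log_tau
        self._log_i = np.log(cum + i0)

    def wrm_integral(self, tau_w: np.ndarray) -> np.ndarray:
        """∫₀^{τ_w} τ² γ̇(τ) dτ, vectorised."""
        tau_w = np.asarray(tau_w, dtype=float)
        out = np.empty_like(tau_w)
        small = tau_w <= self.TAU_MIN
        out[small] = tau_w[small] ** 4 / (4.0 * self.params.eta0)
        if np.any(~small):
            out[~small] = np.exp(
                np.interp(np.log(tau_w[~small]), self._log_tau, self._log_i)
            )
        return out

    def tube_flow_many(self, R: np.ndarray, L: np.ndarray, dp: np.ndarray) -> np.ndarray:
        """Signed volumetric flows for arrays of tubes (SI units)."""
        R = np.asarray(R, dtype=float)
        L = np.asarray(L, dtype=float)
        dp = np.asarray(dp, dtype=float)
        if self.params.is_newtonian:
            return math.pi * R**4 * dp / (8.0 * self.params.eta0 * L)
        tau_w = np.abs(dp) * R / (2.0 * L)
        q = np.zeros_like(tau_w)
        nz = tau_w > 0
        q[nz] = math.pi * R[nz] ** 3 * self.wrm_integral(tau_w[nz]) / tau_w[nz] ** 3
        return np.sign(dp) * q


@dataclass
class CYFitResult:
    """Outcome of a Carreau–Yasuda least-squares fit."""

    params: RheologyParams
    residual_norm: float
    n_samples: int
    degenerate: bool = False  # eta0 ≈ eta_inf: λ, a, n are not identifiable
    message: str = ""


class FitError(RuntimeError):
    """Least-squares fit failed to converge; carries solver diagnostics."""


def fit_cy_params(
    gamma_dot,
    eta,
    rho: float = BLOOD_DENSITY,
) -> CYFitResult:
    """Fit (η0, η∞, λ, a, n) to rheometry samples by least squares on log η.

    Requires at least 5 samples spanning at least 3 decades of shear rate.
    Residuals are taken on log viscosity so that both plateaus carry equal
    weight despite their ~50x magnitude difference.
    """
    g = np.asarray(gamma_dot, dtype=float)
    e = np.asarray(eta, dtype=float)
    if g.shape != e.shape or g.ndim != 1:
        raise RheologyError("gamma_dot and eta must be 1-D arrays of equal length")
    if g.size < 5:
        raise RheologyError("need at least 5 samples")
    if np.any(g <= 0) or np.any(e <= 0):
        raise RheologyError("samples must be strictly positive")
    span = math.log10(g.max() / g.min())
    if span < 3.0:
        raise RheologyError(f"samples span only {span:.2f} decades of shear rate; need >= 3")

    log_e = np.log(e)

    def model(x):
        l_eta0, l_eta_inf, l_lam, a, n = x
        eta0, eta_inf, lam = np.exp([l_eta0, l_eta_inf, l_lam])
        visc = eta_inf + (eta0 - eta_inf) * (1.0 + (lam * g) ** a) ** ((n - 1.0) / a)
        return np.log(visc)

    def residuals(x):
        return model(x) - log_e

    x0 = np.array(
        [
            math.log(e.max()),
            math.log(max(e.min() * 0.9, 1e-12)),
            math.log(1.0 / math.sqrt(g.max() * g.min())),
            1.0,
            0.4,
        ]
    )
    lower = np.array([math.log(1e-6), math.log(1e-6), math.log(1e-6), 0.05, 0.01])
    upper = np.array([math.log(1e3), math.log(1e3), math.log(1e6), 5.0, 1.0])
    x0 = np.clip(x0, lower, upper)
    res = optimize.least_squares(residuals, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise FitError(f"Carreau–Yasuda fit did not converge: {res.message}")
    l_eta0, l_eta_inf, l_lam, a, n = res.x
    eta0, eta_inf, lam = np.exp([l_eta0, l_eta_inf, l_lam])
    eta0 = max(eta0, eta_inf)  # enforce ordering at the boundary
    degenerate = eta0 / eta_inf < 1.05
    params = RheologyParams(eta0=float(eta0), eta_inf=float(eta_inf), lam=float(lam), a=float(a), n=float(n), rho=rho)
    return CYFitResult(
        params=params,
        residual_norm=float(np.linalg.norm(res.fun)),
        n_samples=int(g.size),
        degenerate=degenerate,
        message=str(res.message),
    )
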