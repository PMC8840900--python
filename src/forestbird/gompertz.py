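"""Spatial Gompertz model for point-count biomass.

Observed biomass ``b_i`` in sample ``i`` (area ``a``) is gamma- or
lognormally-distributed around the expected density ``d(s_i, t_i)`` of the
nearest spatial knot ``s_i`` in year ``t_i``:

    b_i ~ Gamma(mean = a·d(s_i,t_i), dispersion σm²)
    log d(s,t) = β(t) + ω(s) + ε(s,t) + γ₁·tit + γ₂·tit² + γ₃·PC [+ γ₄·control]

with a spatial Gaussian random field ω ~ MVN(0, σω²·R), a spatio-temporal
field ε following a first-order autoregression over years with Matérn-
correlated innovations (ε(·,t) = ρε·ε(·,t−1) + MVN(0, σε²·R)), and R the
Matérn ν=1 correlation among knots.  Fixed effects are estimated by
maximizing the Laplace-approximated marginal likelihood; random fields are
set to their conditional modes (empirical Bayes); standard errors come from
the inverse Hessian of the marginal negative log-likelihood with the delta
method for transformed parameters.

The annual intercepts β(t), the covariate effects γ, the dispersion σm², the
Matérn decorrelation parameter κ (and optional geometric anisotropy), the
autocorrelation ρε and the field variances σω², σε² are all outer
(marginal-ML) parameters; ω and ε are integrated out.

By default σm² is a squared coefficient of variation (observation variance
σm²·μ²); ``obs_variance="absolute"`` switches to a constant absolute
variance.  The initial year of ε uses the stationary variance
σε²/(1−ρε²)·R by default; ``epsilon_init="literal"`` uses MVN(0, R).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky
from scipy.optimize import minimize
from scipy.special import gammaln, kv, polygamma, psi

from ._laplace import factor_block_arrow
from .errors import ComparisonError, DataError, FitError, NumericError
from .matern import KnotMesh, matern_correlation

__all__ = [
    "GompertzModelSpec",
    "FixedEffects",
    "RandomFields",
    "FitResult",
    "Z_95",
    "observation_nll",
    "linear_predictor",
    "joint_nll",
    "marginal_nll",
    "fit_model",
    "select_quadratic",
    "significance",
    "response_curve",
    "trim_extremes",
]

Z_95 = 1.959964  # two-sided 95% normal quantile, as used throughout

# covariate column name -> canonical coefficient slot
GAMMA_SLOT = {"tit": "gamma1", "tit2": "gamma2", "PC": "gamma3", "control": "gamma4"}
LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GompertzModelSpec:
    """What to fit: covariates, family, mesh size, parameterization switches."""

    include_quadratic: bool = True
    include_pc: bool = True
    family: str = "gamma"  # "gamma" | "lognormal"
    n_knots: int = 100
    area: float = 0.031  # sampled area per point count, km^2
    anisotropy: bool = False
    covariate_set: tuple[str, ...] | None = None
    obs_variance: str = "cv"  # "cv" | "absolute"
    epsilon_init: str = "stationary"  # "stationary" | "literal"

    def __post_init__(self):
        if self.family not in ("gamma", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_knots < 1:
            raise ValueError("n_knots must be >= 1")
        if self.obs_variance not in ("cv", "absolute"):
            raise ValueError(f"unknown obs_variance {self.obs_variance!r}")
        if self.epsilon_init not in ("stationary", "literal"):
            raise ValueError(f"unknown epsilon_init {self.epsilon_init!r}")

    @property
    def covariates(self) -> tuple[str, ...]:
        if self.covariate_set is not None:
            return tuple(self.covariate_set)
        cols = ["tit"]
        if self.include_quadratic:
            cols.append("tit2")
        if self.include_pc:
            cols.append("PC")
        return tuple(cols)


@dataclass
class FixedEffects:
    """Outer parameters on their natural scale (β in log g/km²)."""

    beta: np.ndarray  # one intercept per year
    gamma1: float | None = None
    gamma2: float | None = None
    gamma3: float | None = None
    gamma4: float | None = None
    sigma_m2: float = 0.5
    log_kappa: float = -4.0
    aniso: np.ndarray | None = None
    rho_eps: float = 0.0
    sigma_omega2: float = 0.5
    sigma_eps2: float = 0.2

    def gamma_for(self, cov_name: str) -> float:
        val = getattr(self, GAMMA_SLOT[cov_name])
        return 0.0 if val is None else float(val)


@dataclass
class RandomFields:
    """Empirical-Bayes modes (or simulated values) of ω and ε."""

    omega: np.ndarray  # (x,)
    epsilon: np.ndarray  # (T, x)


@dataclass
class FitResult:
    spec: GompertzModelSpec
    fixed: FixedEffects
    fields: RandomFields
    se: dict[str, float]
    fixed_cov: np.ndarray  # covariance of (beta..., gammas in covariate order)
    fixed_cov_names: list[str]
    nll: float
    aic: float
    converged: bool
    d_hat: np.ndarray  # (x, T) predicted density g/km^2
    years: np.ndarray
    n_params: int
    data_fingerprint: str
    n_samples: int
    max_grad: float = np.nan

    def ci(self, name: str) -> tuple[float, float]:
        est = self.estimate(name)
        s = self.se[name]
        return est - Z_95 * s, est + Z_95 * s

    def report(self, seed: int | None = None) -> dict:
        """Machine-readable fit summary (estimates, SEs, CIs, AIC, diagnostics)."""
        params = {}
        for t in range(len(self.fixed.beta)):
            params[f"beta{t}"] = {"estimate": float(self.fixed.beta[t]),
                                  "year": int(self.years[t])}
        for nm in ("gamma1", "gamma2", "gamma3", "gamma4"):
            v = getattr(self.fixed, nm)
            if v is not None:
                params[nm] = {"estimate": float(v)}
        params["sigma_m2"] = {"estimate": float(self.fixed.sigma_m2)}
        params["kappa"] = {"estimate": float(np.exp(self.fixed.log_kappa))}
        params["rho_eps"] = {"estimate": float(self.fixed.rho_eps)}
        params["sigma_omega"] = {"estimate": float(np.sqrt(self.fixed.sigma_omega2))}
        params["sigma_eps"] = {"estimate": float(np.sqrt(self.fixed.sigma_eps2))}
        for nm, entry in params.items():
            s = self.se.get(nm)
            if s is not None and np.isfinite(s) and s > 0:
                entry["se"] = float(s)
                est = entry["estimate"]
                entry["ci"] = [est - Z_95 * s, est + Z_95 * s]
        return {
            "model": {
                "family": self.spec.family,
                "covariates": list(self.spec.covariates),
                "n_knots": self.spec.n_knots,
                "area_km2": self.spec.area,
                "obs_variance": self.spec.obs_variance,
            },
            "parameters": params,
            "nll": float(self.nll),
            "aic": float(self.aic),
            "n_fixed_effects": int(self.n_params),
            "converged": bool(self.converged),
            "max_gradient": float(self.max_grad),
            "n_samples": int(self.n_samples),
            "data_fingerprint": self.data_fingerprint,
            "seed": seed,
        }

    def estimate(self, name: str) -> float:
        if name.startswith("beta"):
            return float(self.fixed.beta[int(name[4:])])
        if name in ("sigma_omega", "sigma_eps"):
            return float(np.sqrt(getattr(self.fixed, name + "2")))
        return float(getattr(self.fixed, name))


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def _obs_terms(b, log_mu, sigma_m2, family, obs_variance):
    """Per-sample nll and first/second derivatives w.r.t. log mean.

    Returns (nll, d1, d2) arrays; derivatives are with respect to the linear
    predictor (log μ differs from it by the constant log a).
    """
    b = np.asarray(b, dtype=float)
    s2 = float(sigma_m2)
    if family == "lognormal":
        r = np.log(b) - (log_mu - s2 / 2.0)
        nll = 0.5 * np.log(2 * np.pi * s2) + np.log(b) + r * r / (2 * s2)
        d1 = -r / s2
        d2 = np.full_like(b, 1.0 / s2)
        return nll, d1, d2
    # gamma
    if obs_variance == "cv":
        k = 1.0 / s2
        w = b * np.exp(-log_mu) / s2  # b / (mu * s2)
        nll = gammaln(k) + k * (log_mu + np.log(s2)) - (k - 1.0) * np.log(b) + w
        d1 = k - w
        d2 = w
        return nll, d1, d2
    # absolute variance: shape mu^2/s2, scale s2/mu
    mu = np.exp(log_mu)
    k = mu * mu / s2
    A = psi(k) + np.log(s2) - log_mu - np.log(b)
    nll = gammaln(k) + k * (np.log(s2) - log_mu) - (k - 1.0) * np.log(b) + b * mu / s2
    d1 = 2 * k * A - k + b * mu / s2
    d2 = 4 * k * A + 4 * k * k * polygamma(1, k) - 4 * k + b * mu / s2
    return nll, d1, np.maximum(d2, 1e-10)


def observation_nll(b, d, a, sigma_m2, family="gamma", obs_variance="cv"):
    """Negative log-likelihood contribution of observations ``b``.

    ``d`` is expected density (g/km²) and ``a`` the sampled area, so the
    observation mean is μ = a·d.  Returns the per-sample nll array.
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    d = np.broadcast_to(np.asarray(d, dtype=float), b.shape)
    if np.any(d <= 0):
        raise DataError("expected density d must be positive")
    if family == "gamma" and np.any(b <= 0):
        raise DataError("gamma family requires b > 0; remove zero samples upstream")
    if sigma_m2 <= 0:
        raise DataError("sigma_m2 must be positive")
    log_mu = np.log(a) + np.log(d)
    nll, _, _ = _obs_terms(b, log_mu, sigma_m2, family, obs_variance)
    return nll


# ---------------------------------------------------------------------------
# linear predictor and joint likelihood
# ---------------------------------------------------------------------------

def linear_predictor(
    fixed: FixedEffects,
    fields: RandomFields | None,
    covariates: Mapping[str, np.ndarray | float],
    year_index: np.ndarray | int = 0,
    knot_index: np.ndarray | int = 0,
    spec: GompertzModelSpec | None = None,
) -> np.ndarray:
    """log d(s,t) = β(t) + ω(s) + ε(s,t) + Σ γ·covariate.

    Covariates absent from the model specification contribute nothing; with
    ``fields=None`` both random fields contribute zero.
    """
    t = np.atleast_1d(np.asarray(year_index, dtype=int))
    s = np.broadcast_to(np.atleast_1d(np.asarray(knot_index, dtype=int)), t.shape)
    eta = np.asarray(fixed.beta, dtype=float)[t].astype(float).copy()
    if fields is not None:
        eta += fields.omega[s] + fields.epsilon[t, s]
    active = spec.covariates if spec is not None else tuple(covariates.keys())
    for name, vals in covariates.items():
        if name not in active:
            continue
        eta = eta + fixed.gamma_for(name) * np.broadcast_to(
            np.asarray(vals, dtype=float), eta.shape
        )
    return eta


def _ar1_precision(T, rho, sigma_eps2, epsilon_init):
    """T×T precision of the AR(1) over years (to be Kronecker'd with R⁻¹)."""
    sig1sq = 1.0 if epsilon_init == "literal" else sigma_eps2 / (1.0 - rho * rho)
    M = np.zeros((T, T))
    for t in range(T):
        M[t, t] = (1.0 / sig1sq if t == 0 else 1.0 / sigma_eps2) + (
            rho * rho / sigma_eps2 if t < T - 1 else 0.0
        )
        if t < T - 1:
            M[t, t + 1] = M[t + 1, t] = -rho / sigma_eps2
    logdet = -(np.log(sig1sq) + (T - 1) * np.log(sigma_eps2))
    return M, logdet


class _Context:
    """Per-fit workspace: data arrays, caches, warm-started inner modes."""

    def __init__(self, b, area, knot, year_idx, X, cov_names, mesh, spec, years):
        self.b = np.asarray(b, dtype=float)
        self.area = float(area)
        self.knot = np.asarray(knot, dtype=int)
        self.year_idx = np.asarray(year_idx, dtype=int)
        self.X = np.asarray(X, dtype=float)
        self.cov_names = list(cov_names)
        self.mesh = mesh
        self.spec = spec
        self.years = np.asarray(years)
        self.T = len(years)
        self.x = mesh.n_knots
        self.n = len(self.b)
        self.ky = self.year_idx * self.x + self.knot  # (t, s) flat index
        self._R_key = None
        self._R_data = None
        self.warm = np.zeros((self.T + 1, self.x))  # rows 0..T-1: eps, row T: omega

    # -- parameter packing -------------------------------------------------
    def param_names(self):
        names = [f"beta{t}" for t in range(self.T)]
        names += [GAMMA_SLOT[c] for c in self.cov_names]
        names.append("log_sigma_m2")
        names.append("log_kappa")
        if self.spec.anisotropy:
            names += ["aniso0", "aniso1"]
        names += ["log_sigma_omega2", "log_sigma_eps2", "z_rho"]
        return names

    def pack(self, fx: FixedEffects):
        v = list(np.asarray(fx.beta, dtype=float))
        v += [fx.gamma_for(c) for c in self.cov_names]
        v.append(np.log(fx.sigma_m2))
        v.append(fx.log_kappa)
        if self.spec.anisotropy:
            an = fx.aniso if fx.aniso is not None else np.zeros(2)
            v += [float(an[0]), float(an[1])]
        v += [np.log(fx.sigma_omega2), np.log(fx.sigma_eps2), np.arctanh(fx.rho_eps)]
        return np.array(v, dtype=float)

    def unpack(self, theta):
        T, p = self.T, len(self.cov_names)
        beta = theta[:T]
        gammas = dict.fromkeys(("gamma1", "gamma2", "gamma3", "gamma4"))
        for j, c in enumerate(self.cov_names):
            gammas[GAMMA_SLOT[c]] = float(theta[T + j])
        i = T + p
        sigma_m2 = float(np.exp(theta[i])); i += 1
        log_kappa = float(theta[i]); i += 1
        aniso = None
        if self.spec.anisotropy:
            aniso = np.array([theta[i], theta[i + 1]]); i += 2
        sigma_omega2 = float(np.exp(theta[i])); i += 1
        sigma_eps2 = float(np.exp(theta[i])); i += 1
        rho = float(np.tanh(theta[i]))
        return FixedEffects(
            beta=np.asarray(beta, dtype=float).copy(),
            sigma_m2=sigma_m2, log_kappa=log_kappa, aniso=aniso,
            rho_eps=rho, sigma_omega2=sigma_omega2, sigma_eps2=sigma_eps2,
            **gammas,
        )

    # -- cached correlation algebra ---------------------------------------
    def R_terms(self, log_kappa, aniso):
        key = (round(float(log_kappa), 14), None if aniso is None
               else (round(float(aniso[0]), 14), round(float(aniso[1]), 14)))
        if key == self._R_key:
            return self._R_data
        R = matern_correlation(self.mesh, log_kappa, aniso)
        try:
            L = cholesky(R, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - jitter path
            raise NumericError(
                f"Matérn correlation not positive-definite at kappa={np.exp(log_kappa):.4g}"
            ) from exc
        logdetR = 2.0 * float(np.sum(np.log(np.diag(L))))
        Qr = cho_solve((L, True), np.eye(self.x))
        Qr = 0.5 * (Qr + Qr.T)
        self._R_key = key
        self._R_data = (R, L, Qr, logdetR)
        return self._R_data

    # -- joint negative log-likelihood ------------------------------------
    def eta(self, fx: FixedEffects, eps, omega):
        base = fx.beta[self.year_idx] + omega[self.knot] + eps[self.year_idx, self.knot]
        if self.X.size:
            g = np.array([fx.gamma_for(c) for c in self.cov_names])
            base = base + self.X @ g
        return base

    def joint(self, fx: FixedEffects, eps, omega, R_terms=None):
        x, T = self.x, self.T
        if R_terms is None:
            R_terms = self.R_terms(fx.log_kappa, fx.aniso)
        _, _, Qr, logdetR = R_terms
        log_mu = np.log(self.area) + self.eta(fx, eps, omega)
        nll_obs, d1, d2 = _obs_terms(
            self.b, log_mu, fx.sigma_m2, self.spec.family, self.spec.obs_variance
        )
        f = float(np.sum(nll_obs))
        # omega prior
        Qw = Qr @ omega
        f += 0.5 * float(omega @ Qw) / fx.sigma_omega2
        f += 0.5 * (x * np.log(fx.sigma_omega2) + logdetR) + 0.5 * x * LOG2PI
        # epsilon prior
        M, logdetM = _ar1_precision(T, fx.rho_eps, fx.sigma_eps2, self.spec.epsilon_init)
        QE = eps @ Qr
        f += 0.5 * float(np.sum(eps * (M @ QE)))
        f += 0.5 * (-x * logdetM + T * logdetR) + 0.5 * T * x * LOG2PI
        return f, d1, d2, QE, Qw, M

    def inner_newton(self, fx: FixedEffects, tol=1e-8, max_iter=60):
        """Minimize the joint nll over (ε, ω); returns modes, value, logdet H."""
        x, T = self.x, self.T
        R_terms = self.R_terms(fx.log_kappa, fx.aniso)
        _, _, Qr, _ = R_terms
        eps = self.warm[:T].copy()
        omega = self.warm[T].copy()
        f, d1, d2, QE, Qw, M = self.joint(fx, eps, omega, R_terms)
        factor = None
        for _ in range(max_iter):
            G = np.bincount(self.ky, weights=d1, minlength=T * x).reshape(T, x)
            W = np.bincount(self.ky, weights=d2, minlength=T * x).reshape(T, x)
            grad_eps = M @ QE + G
            grad_om = Qw / fx.sigma_omega2 + G.sum(axis=0)
            gmax = max(np.abs(grad_eps).max(), np.abs(grad_om).max())
            # scale the tolerance with curvature: near-degenerate dispersions
            # make smaller gradients unattainable in double precision, while
            # the value error stays quadratic in the gradient residual
            curv = 1.0 + W.max() + 1.0 / fx.sigma_eps2 + 1.0 / fx.sigma_omega2
            if gmax < tol * curv:
                break
            D = [M[t, t] * Qr + np.diag(W[t]) for t in range(T)]
            A = [M[t + 1, t] * Qr for t in range(T - 1)]
            D_tail = Qr / fx.sigma_omega2 + np.diag(W.sum(axis=0))
            try:
                factor = factor_block_arrow(D, A, list(W), D_tail)
            except np.linalg.LinAlgError as exc:
                raise NumericError(
                    "inner Hessian not positive-definite "
                    f"(kappa={np.exp(fx.log_kappa):.4g})"
                ) from exc
            step_eps, step_om = factor.solve(grad_eps, grad_om)
            smax = max(np.abs(step_eps).max(), np.abs(step_om).max())
            if smax < 1e-12 * (1.0 + np.abs(eps).max() + np.abs(omega).max()):
                break  # machine-precision-limited; mode located
            alpha = 1.0
            for _ls in range(25):
                new_eps = eps - alpha * step_eps
                new_om = omega - alpha * step_om
                f_new, d1n, d2n, QEn, Qwn, _ = self.joint(fx, new_eps, new_om, R_terms)
                if f_new <= f + 1e-12 * (1 + abs(f)):
                    break
                alpha *= 0.5
            eps, omega, f, d1, d2, QE, Qw = new_eps, new_om, f_new, d1n, d2n, QEn, Qwn
        else:
            raise FitError(
                f"inner optimization did not reach gradient tolerance (|g|max={gmax:.3g})"
            )
        # Hessian at the mode (recompute with final curvature)
        W = np.bincount(self.ky, weights=d2, minlength=T * x).reshape(T, x)
        D = [M[t, t] * Qr + np.diag(W[t]) for t in range(T)]
        A = [M[t + 1, t] * Qr for t in range(T - 1)]
        D_tail = Qr / fx.sigma_omega2 + np.diag(W.sum(axis=0))
        factor = factor_block_arrow(D, A, list(W), D_tail)
        self.warm[:T] = eps
        self.warm[T] = omega
        return eps, omega, f, factor

    def marginal(self, theta):
        fx = self.unpack(np.asarray(theta, dtype=float))
        eps, omega, f, factor = self.inner_newton(fx)
        dim = self.x * (self.T + 1)
        return f + 0.5 * factor.logdet - 0.5 * dim * LOG2PI

    @property
    def analytic_grad_ok(self) -> bool:
        """Closed-form outer gradient is available for the default model forms."""
        return (
            not self.spec.anisotropy
            and self.spec.epsilon_init == "stationary"
            and self.T >= 2
            and (self.spec.family == "lognormal" or self.spec.obs_variance == "cv")
        )

    def marginal_and_grad(self, theta):
        """Laplace marginal nll and its exact gradient in the outer parameters.

        Uses the implicit-function theorem at the inner mode û:
        dL/dθ = ∂f/∂θ + ½·tr(H⁻¹ ∂H/∂θ) − (H⁻¹g₃)ᵀ ∂²f/∂u∂θ, where g₃ is the
        ½·tr(H⁻¹ ∂H/∂u) vector.  The observation part of H is a sum of
        rank-one terms d2ᵢ·vᵢvᵢᵀ, so all traces reduce to the selected
        inverse of H on the factor's fill pattern.
        """
        theta = np.asarray(theta, dtype=float)
        if not self.analytic_grad_ok:
            f0 = self.marginal(theta)
            return f0, _fd_gradient(self.marginal, theta, f0)
        fx = self.unpack(theta)
        x, T, s2 = self.x, self.T, fx.sigma_m2
        eps, omega, f, factor = self.inner_newton(fx)
        dim = x * (T + 1)
        value = f + 0.5 * factor.logdet - 0.5 * dim * LOG2PI

        _, _, Qr, _ = self.R_terms(fx.log_kappa, fx.aniso)
        M, _ = _ar1_precision(T, fx.rho_eps, fx.sigma_eps2, self.spec.epsilon_init)
        log_mu = np.log(self.area) + self.eta(fx, eps, omega)
        b, kyi = self.b, self.ky
        if self.spec.family == "lognormal":
            r = np.log(b) - (log_mu - s2 / 2.0)
            d1 = -r / s2
            d2 = np.full_like(b, 1.0 / s2)
            d3 = np.zeros_like(b)
            e0 = 0.5 + r / 2.0 - r * r / (2 * s2)
            e1 = r / s2 - 0.5
            e2 = np.full_like(b, -1.0 / s2)
        else:  # gamma, CV parameterization
            k = 1.0 / s2
            w = b * np.exp(-log_mu) / s2
            d1 = k - w
            d2 = w
            d3 = -w
            e0 = -k * psi(k) - k * (log_mu + np.log(s2)) + k + k * np.log(b) - w
            e1 = w - k
            e2 = -w

        Z_diag, Z_sub, Z_arrow, Z_tail = factor.selected_inverse()
        # per-sample quadratic form c_i = v_i' H^{-1} v_i
        a_ts = np.stack([np.diag(Z_diag[t]) for t in range(T)])  # (T, x)
        b_ts = np.stack([np.diag(Z_arrow[t]) for t in range(T)])
        c_s = np.diag(Z_tail)
        cvec = (a_ts + 2.0 * b_ts)[self.year_idx, self.knot] + c_s[self.knot]

        # w = H^{-1} g3 with g3 the field-gradient of ½ logdet H
        g3 = 0.5 * np.bincount(kyi, weights=d3 * cvec, minlength=T * x).reshape(T, x)
        w_eps, w_om = factor.solve(g3, g3.sum(axis=0))
        uvec = w_eps[self.year_idx, self.knot] + w_om[self.knot]

        grad = np.empty_like(theta)
        # linear-predictor parameters: per-sample weight then design sums
        lin = d1 + 0.5 * d3 * cvec - d2 * uvec
        grad[:T] = np.bincount(self.year_idx, weights=lin, minlength=T)
        p = len(self.cov_names)
        if p:
            grad[T : T + p] = self.X.T @ lin
        i = T + p
        # log sigma_m2
        grad[i] = float(np.sum(e0 + 0.5 * e2 * cvec - e1 * uvec)); i += 1

        # shared prior quantities
        Et = eps @ Qr  # rows Qr @ eps_t
        MEt = M @ Et
        om_t = Qr @ omega
        tzd = np.array([float(np.sum(Z_diag[t] * Qr)) for t in range(T)])
        tzs = np.array([float(np.sum(Z_sub[t] * Qr)) for t in range(T - 1)])
        Md = M.diagonal().copy()
        Ms = M.diagonal(-1).copy()

        # log kappa: dR/dlogkappa = -(kd)^2 K0(kd)
        kappa = np.exp(fx.log_kappa)
        dmat = self.mesh.distances(fx.aniso)
        kd = kappa * dmat
        Rdot = np.zeros_like(kd)
        pos = kd > 0
        Rdot[pos] = -(kd[pos] ** 2) * kv(0, kd[pos])
        QRdot = Qr @ Rdot
        # explicit df/dlogkappa (fields fixed)
        gk = -0.5 * (float(np.sum(MEt * (Et @ Rdot))) + float(om_t @ (Rdot @ om_t)) / fx.sigma_omega2)
        gk += 0.5 * (T + 1) * float(np.trace(QRdot))
        # trace terms: dQr = -Qr Rdot Qr, so tr(Z dQr) = -sum(Z * K), K = Qr Rdot Qr
        K = QRdot @ Qr  # symmetric
        tk = float(np.sum(Md * [np.sum(Z_diag[t] * K) for t in range(T)]))
        tk += 2.0 * float(np.sum(Ms * [np.sum(Z_sub[t] * K) for t in range(T - 1)]))
        tk += float(np.sum(Z_tail * K)) / fx.sigma_omega2
        gk += -0.5 * tk
        # implicit term
        m_eps = -(MEt @ Rdot) @ Qr
        m_om = -(Qr @ (Rdot @ om_t)) / fx.sigma_omega2
        gk -= float(np.sum(w_eps * m_eps)) + float(w_om @ m_om)
        grad[i] = gk; i += 1

        # log sigma_omega2
        go = -0.5 * float(omega @ om_t) / fx.sigma_omega2 + 0.5 * x
        go += -0.5 * float(np.sum(Z_tail * Qr)) / fx.sigma_omega2
        go -= float(w_om @ (-om_t / fx.sigma_omega2))
        grad[i] = go; i += 1

        # log sigma_eps2 (stationary AR(1): dM/dlog sigma_eps2 = -M)
        quadM = float(np.sum(eps * MEt))
        trM = float(np.sum(Md * tzd)) + 2.0 * float(np.sum(Ms * tzs))
        ge = -0.5 * quadM + 0.5 * x * T - 0.5 * trM
        ge -= float(np.sum(w_eps * (-MEt)))
        grad[i] = ge; i += 1

        # z_rho (rho = tanh z); stationary M has dM/drho: interior diag 2rho,
        # off-diagonal -1, all over sigma_eps2; first/last diag 0
        rho, se2 = fx.rho_eps, fx.sigma_eps2
        dMd = np.zeros(T)
        dMd[1 : T - 1] = 2.0 * rho / se2
        dMs = np.full(T - 1, -1.0 / se2)
        jac_rho = 1.0 - rho * rho
        # quadratic form with dM
        qd = np.einsum("ti,ti->t", eps, Et)
        qs = np.einsum("ti,ti->t", eps[1:], Et[:-1])
        gz = 0.5 * (float(np.sum(dMd * qd)) + 2.0 * float(np.sum(dMs * qs)))
        gz += 0.5 * (float(np.sum(dMd * tzd)) + 2.0 * float(np.sum(dMs * tzs)))
        # implicit: m_eps = dM @ Et
        dM_Et = dMd[:, None] * Et
        dM_Et[:-1] += dMs[:, None] * Et[1:]
        dM_Et[1:] += dMs[:, None] * Et[:-1]
        gz += -float(np.sum(w_eps * dM_Et))
        gz *= jac_rho
        gz += x * rho  # normalizer: -x/2 dlogdetM/dz
        grad[i] = gz
        return value, grad


# ---------------------------------------------------------------------------
# public likelihood wrappers
# ---------------------------------------------------------------------------

def _context_from_samples(samples: pd.DataFrame, mesh: KnotMesh, spec: GompertzModelSpec):
    req = {"b", "year"}
    missing = req - set(samples.columns)
    if missing:
        raise DataError(f"samples missing columns: {sorted(missing)}")
    cov_names = [c for c in spec.covariates if c in samples.columns]
    absent = set(spec.covariates) - set(cov_names)
    if absent:
        raise DataError(f"spec covariates absent from samples: {sorted(absent)}")
    years = np.sort(samples["year"].unique())
    year_idx = np.searchsorted(years, samples["year"].to_numpy())
    if len(mesh.assignment) != len(samples):
        raise DataError("mesh assignment length does not match samples")
    X = samples[cov_names].to_numpy(dtype=float) if cov_names else np.empty((len(samples), 0))
    if spec.family == "gamma" and (samples["b"] <= 0).any():
        raise DataError("gamma family requires b > 0; apply zero-sample removal first")
    return _Context(
        b=samples["b"].to_numpy(dtype=float), area=spec.area,
        knot=mesh.assignment, year_idx=year_idx, X=X, cov_names=cov_names,
        mesh=mesh, spec=spec, years=years,
    )


def joint_nll(fixed: FixedEffects, fields: RandomFields, samples: pd.DataFrame,
              mesh: KnotMesh, spec: GompertzModelSpec) -> float:
    """Joint negative log-likelihood of data and random fields."""
    ctx = _context_from_samples(samples, mesh, spec)
    f, *_ = ctx.joint(fixed, np.asarray(fields.epsilon, float),
                      np.asarray(fields.omega, float))
    return float(f)


def marginal_nll(fixed: FixedEffects, samples: pd.DataFrame, mesh: KnotMesh,
                 spec: GompertzModelSpec) -> float:
    """Laplace-approximated marginal negative log-likelihood of fixed effects."""
    ctx = _context_from_samples(samples, mesh, spec)
    return float(ctx.marginal(ctx.pack(fixed)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fd_gradient(fun, theta, f0, rel_step=1e-6):
    g = np.empty_like(theta)
    for j in range(len(theta)):
        h = rel_step * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        g[j] = (fun(tp) - f0) / h
    return g


def _fd_hessian_from_grad(grad_fun, theta, rel_step=1e-5):
    """Central finite differences of an (exact) gradient; symmetrized."""
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        h = rel_step * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        H[:, j] = (grad_fun(tp) - grad_fun(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _fd_hessian(fun, theta, rel_step=1e-4):
    k = len(theta)
    H = np.empty((k, k))
    hs = np.array([rel_step * max(1.0, abs(t)) for t in theta])
    f0 = fun(theta)
    fp = np.empty(k)
    fm = np.empty(k)
    for j in range(k):
        tp = theta.copy(); tp[j] += hs[j]
        tm = theta.copy(); tm[j] -= hs[j]
        fp[j] = fun(tp)
        fm[j] = fun(tm)
        H[j, j] = (fp[j] + fm[j] - 2 * f0) / hs[j] ** 2
    for j in range(k):
        for l in range(j + 1, k):
            tpp = theta.copy(); tpp[j] += hs[j]; tpp[l] += hs[l]
            tmm = theta.copy(); tmm[j] -= hs[j]; tmm[l] -= hs[l]
            H[j, l] = H[l, j] = (
                fun(tpp) + fun(tmm) + 2 * f0 - fp[j] - fm[j] - fp[l] - fm[l]
            ) / (2 * hs[j] * hs[l])
    return 0.5 * (H + H.T)


def _default_start(ctx: _Context) -> np.ndarray:
    """Moment-based starting values: yearly log mean density, zero effects."""
    log_dens = np.log(ctx.b / ctx.area)
    beta0 = np.array([
        float(np.mean(log_dens[ctx.year_idx == t])) if np.any(ctx.year_idx == t)
        else float(np.mean(log_dens))
        for t in range(ctx.T)
    ])
    resid_var = float(np.var(log_dens - beta0[ctx.year_idx]))
    span = float(np.ptp(ctx.mesh.knot_coords, axis=0).max()) or 1.0
    fx = FixedEffects(
        beta=beta0,
        sigma_m2=min(max(0.5 * resid_var, 0.05), 2.0),
        log_kappa=float(np.log(np.sqrt(8.0) / (0.4 * span))),
        aniso=np.zeros(2) if ctx.spec.anisotropy else None,
        rho_eps=0.3,
        sigma_omega2=min(max(0.3 * resid_var, 0.05), 2.0),
        sigma_eps2=min(max(0.15 * resid_var, 0.02), 1.0),
    )
    for c in ctx.cov_names:
        setattr(fx, GAMMA_SLOT[c], 0.0)
    return ctx.pack(fx)


def _fingerprint(samples: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(samples["b"].to_numpy(float)).tobytes())
    h.update(np.ascontiguousarray(samples["year"].to_numpy(int)).tobytes())
    return h.hexdigest()[:16]


def fit_model(
    samples: pd.DataFrame,
    mesh: KnotMesh,
    spec: GompertzModelSpec,
    start: FixedEffects | None = None,
    seed: int = 0,
    compute_se: bool = True,
    gtol: float = 1e-4,
    max_outer: int = 400,
) -> FitResult:
    """Maximum marginal-likelihood fit with empirical-Bayes random fields.

    Outer optimization is quasi-Newton (L-BFGS-B) on the Laplace marginal
    negative log-likelihood with forward-difference gradients; convergence
    requires a relative gradient max-norm below ``gtol``.  On failure the fit
    is retried from up to 3 seeded perturbed starts before ``converged`` is
    set to False (the result is still returned for downstream screening).
    """
    ctx = _context_from_samples(samples, mesh, spec)
    if ctx.T < 2:
        raise DataError("at least 2 years of data are required")
    theta0 = ctx.pack(start) if start is not None else _default_start(ctx)

    def run(theta_init):
        cache = {}

        def value_and_grad(th):
            key = th.tobytes()
            if key not in cache:
                try:
                    cache[key] = ctx.marginal_and_grad(th)
                except (NumericError, FitError, np.linalg.LinAlgError):
                    cache[key] = (1e12, np.zeros_like(th))
                if len(cache) > 8:
                    cache.pop(next(iter(cache)))
            return cache[key]

        # wide safety-rail bounds keeping transforms in numerically sane regions
        bounds = []
        for nm in ctx.param_names():
            if nm.startswith("log_sigma"):
                bounds.append((-16.0, 6.0))
            elif nm == "log_kappa":
                bounds.append((-14.0, 6.0))
            elif nm == "z_rho":
                bounds.append((-7.0, 7.0))
            elif nm.startswith("aniso"):
                bounds.append((-3.0, 3.0))
            else:
                bounds.append((None, None))
        res = minimize(
            lambda th: value_and_grad(th)[0], theta_init,
            jac=lambda th: value_and_grad(th)[1], method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_outer, "ftol": 1e-11, "gtol": 1e-6},
        )
        f_scale = max(1.0, abs(res.fun))
        gmax = float(np.abs(res.jac).max())
        ok = np.isfinite(res.fun) and res.fun < 1e11 and gmax < gtol * f_scale
        return res, ok, gmax

    rng = np.random.default_rng(seed)
    res, ok, gmax = run(theta0)
    tries = 0
    while not ok and tries < 3:
        tries += 1
        jitter = rng.normal(scale=0.2, size=len(theta0))
        ctx.warm[:] = 0.0
        res2, ok2, gmax2 = run(theta0 + jitter)
        if ok2 or res2.fun < res.fun:
            res, ok, gmax = res2, ok2, gmax2
        if ok:
            break

    theta_hat = res.x
    fx = ctx.unpack(theta_hat)
    eps, omega, _, _ = ctx.inner_newton(fx)
    nll = float(res.fun)
    names = ctx.param_names()
    k = len(theta_hat)
    aic = 2.0 * k + 2.0 * nll

    se: dict[str, float] = {}
    cov = np.full((k, k), np.nan)
    converged = bool(ok)
    if compute_se and converged:
        if ctx.analytic_grad_ok:
            H = _fd_hessian_from_grad(
                lambda th: ctx.marginal_and_grad(th)[1], theta_hat
            )
        else:
            H = _fd_hessian(ctx.marginal, theta_hat)
        # variance parameters that collapsed to ~0 leave a flat direction in
        # the information matrix; hold them fixed at the boundary when
        # inverting (their own SEs are undefined)
        free = np.ones(k, dtype=bool)
        at_boundary = {
            nm for j, nm in enumerate(names)
            if nm.startswith("log_sigma") and theta_hat[j] < -12.0
        }
        for j, nm in enumerate(names):
            if nm in at_boundary:
                free[j] = False
            if nm == "z_rho" and (
                abs(theta_hat[j]) > 5.0 or "log_sigma_eps2" in at_boundary
            ):
                free[j] = False
            # with no field variance left, the decorrelation scale is flat too
            if nm in ("log_kappa", "aniso0", "aniso1") and {
                "log_sigma_omega2", "log_sigma_eps2"
            } <= at_boundary:
                free[j] = False
        Hf = H[np.ix_(free, free)]
        try:
            Hc = cholesky(0.5 * (Hf + Hf.T), lower=True)
            cov_f = cho_solve((Hc, True), np.eye(Hf.shape[0]))
        except np.linalg.LinAlgError:
            # near-singular information: project to nearest PD
            w, V = np.linalg.eigh(0.5 * (Hf + Hf.T))
            if np.any(w <= 0):
                converged = False
                w = np.maximum(w, 1e-8)
            cov_f = (V / w) @ V.T
        cov = np.zeros((k, k))
        cov[np.ix_(free, free)] = cov_f
        dse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        dse[~free] = np.nan
        for nm, s in zip(names, dse):
            se[nm] = float(s)
        # natural-scale and SD-scale deltas
        se["sigma_m2"] = fx.sigma_m2 * se["log_sigma_m2"]
        se["sigma_omega2"] = fx.sigma_omega2 * se["log_sigma_omega2"]
        se["sigma_eps2"] = fx.sigma_eps2 * se["log_sigma_eps2"]
        se["sigma_omega"] = 0.5 * np.sqrt(fx.sigma_omega2) * se["log_sigma_omega2"]
        se["sigma_eps"] = 0.5 * np.sqrt(fx.sigma_eps2) * se["log_sigma_eps2"]
        se["rho_eps"] = (1.0 - fx.rho_eps**2) * se["z_rho"]
        se["kappa"] = np.exp(fx.log_kappa) * se["log_kappa"]

    # covariance over (beta..., gammas) block for response curves
    nb = ctx.T + len(ctx.cov_names)
    fixed_cov = cov[:nb, :nb]
    fixed_cov_names = names[:nb]

    d_hat = _predict_density(ctx, fx, eps, omega)
    return FitResult(
        spec=spec, fixed=fx,
        fields=RandomFields(omega=omega, epsilon=eps),
        se=se, fixed_cov=fixed_cov, fixed_cov_names=fixed_cov_names,
        nll=nll, aic=aic, converged=converged, d_hat=d_hat, years=ctx.years,
        n_params=k, data_fingerprint=_fingerprint(samples),
        n_samples=ctx.n, max_grad=float(gmax),
    )


def _predict_density(ctx: _Context, fx: FixedEffects, eps, omega) -> np.ndarray:
    """d(s,t) over knots × years, using knot-year mean covariates (0 where unsampled)."""
    x, T = ctx.x, ctx.T
    eta = fx.beta[None, :] + omega[:, None] + eps.T  # (x, T)
    if ctx.X.size:
        g = np.array([fx.gamma_for(c) for c in ctx.cov_names])
        contrib = ctx.X @ g
        sums = np.bincount(ctx.ky, weights=contrib, minlength=T * x).reshape(T, x)
        cnts = np.bincount(ctx.ky, minlength=T * x).reshape(T, x)
        mean = np.divide(sums, cnts, out=np.zeros_like(sums), where=cnts > 0)
        eta = eta + mean.T
    return np.exp(eta)


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------

def significance(estimate: float, se: float) -> tuple[bool, tuple[float, float]]:
    """Wald 95% CI; significant iff the closed interval excludes zero."""
    if se <= 0:
        raise DataError("standard error must be positive")
    lo, hi = estimate - Z_95 * se, estimate + Z_95 * se
    return not (lo <= 0.0 <= hi), (lo, hi)


def select_quadratic(fit_linear: FitResult, fit_quadratic: FitResult) -> FitResult:
    """AIC + significance rule for keeping the quadratic indicator term.

    The quadratic model is chosen iff its AIC is strictly lower and the
    quadratic coefficient's 95% CI excludes zero; otherwise the linear model.
    """
    if fit_linear.data_fingerprint != fit_quadratic.data_fingerprint:
        raise ComparisonError("model comparison requires identical data")
    if not (fit_linear.converged and fit_quadratic.converged):
        raise ComparisonError("both fits must have converged")
    g2 = fit_quadratic.fixed.gamma2
    sig = False
    if g2 is not None and fit_quadratic.se.get("gamma2", 0) > 0:
        sig, _ = significance(g2, fit_quadratic.se["gamma2"])
    if fit_quadratic.aic < fit_linear.aic and sig:
        return fit_quadratic
    return fit_linear


def response_curve(
    fit: FitResult,
    grid: np.ndarray,
    n_draws: int = 1000,
    seed: int = 0,
    year_index: int = 0,
) -> pd.DataFrame:
    """Median and 95% band of log d versus standardized indicator biomass.

    Draws (β(t₁), γ₁[, γ₂]) from their joint normal sampling distribution and
    evaluates the predictor over ``grid``; returns percentiles 2.5/50/97.5.
    """
    grid = np.asarray(grid, dtype=float)
    names = fit.fixed_cov_names
    want = [f"beta{year_index}", "gamma1"]
    if fit.fixed.gamma2 is not None and "gamma2" in names:
        want.append("gamma2")
    idx = [names.index(w) for w in want]
    mean = np.array([
        fit.fixed.beta[year_index] if w.startswith("beta") else getattr(fit.fixed, w)
        for w in want
    ])
    cov = fit.fixed_cov[np.ix_(idx, idx)]
    cov = 0.5 * (cov + cov.T)
    w, V = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise NumericError("fixed-effect covariance is not positive-semidefinite")
    w = np.maximum(w, 0.0)
    rng = np.random.default_rng(seed)
    draws = mean + rng.standard_normal((n_draws, len(mean))) @ (V * np.sqrt(w)).T
    curves = draws[:, [0]] + draws[:, [1]] * grid[None, :]
    if len(want) == 3:
        curves = curves + draws[:, [2]] * grid[None, :] ** 2
    lo, med, hi = np.percentile(curves, [2.5, 50.0, 97.5], axis=0)
    point = mean[0] + mean[1] * grid + (mean[2] * grid**2 if len(want) == 3 else 0.0)
    return pd.DataFrame({"tit": grid, "log_d": point, "lo": lo, "median": med, "hi": hi})


def trim_extremes(samples: pd.DataFrame, fraction: float = 0.025) -> pd.DataFrame:
    """Drop samples with response biomass in the extreme tails.

    Removes rows whose ``b`` lies strictly below the ``fraction`` quantile or
    strictly above the ``1-fraction`` quantile (linear-interpolation
    quantiles); used for the extreme-observation sensitivity refit.
    """
    if not 0.0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    if fraction == 0.0:
        return samples
    b = samples["b"].to_numpy(dtype=float)
    lo, hi = np.quantile(b, [fraction, 1.0 - fraction])
    return samples[(b >= lo) & (b <= hi)].copy()
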