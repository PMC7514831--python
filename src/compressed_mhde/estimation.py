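"""Hellinger affinity objective, BFGS optimizer and the MHDE estimator.

For each channel i the objective is the Hellinger affinity

    Psi(i, theta) = integral sqrt( g_B(y | mu) * phi(y | sigma) ) dy,

between the parameter-dependent kernel density of the centered residuals
and the N(0, sigma^2) local-limit target.  Maximizing Psi is equivalent
to minimizing the squared Hellinger distance, HD^2 = 2 (1 - Psi).  The
maximization uses a quasi-Newton method with BFGS curvature updates and
a backtracking (Armijo) line search; per-channel estimates are averaged
into the overall estimate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from compressed_mhde.compression import CompressedDataset
from compressed_mhde.density import (
    DensityEstimate,
    bandwidth,
    bandwidth_scale,
    center_scale_residuals,
    kde,
    make_grid,
)

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class LocationScaleParams:
    """The estimation target theta = (mu, sigma), sigma > 0."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0.0:
            raise ValueError("sigma must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.sigma], dtype=float)

    @classmethod
    def from_array(cls, x) -> "LocationScaleParams":
        return cls(mu=float(x[0]), sigma=float(x[1]))


@dataclass(frozen=True)
class OptimizerConfig:
    """Quasi-Newton settings.

    ``zeta`` is the sufficient-decrease (Armijo) constant in (0, 0.5),
    ``kappa`` the geometric step shrink in (0, 1); iteration stops when
    the absolute objective change drops below ``threshold``.  Trial
    points with second coordinate below ``sigma_min`` (when set) are
    rejected inside the line search, keeping sigma positive without
    reparametrizing.
    """

    zeta: float = 0.25
    kappa: float = 0.5
    threshold: float = 1e-8
    max_iter: int = 200
    fd_step: float = 1e-5
    sigma_min: float | None = None
    t_min: float = 1e-12

    def __post_init__(self) -> None:
        if not 0.0 < self.zeta < 0.5:
            raise ValueError("zeta must lie in (0, 0.5)")
        if not 0.0 < self.kappa < 1.0:
            raise ValueError("kappa must lie in (0, 1)")
        if self.threshold <= 0.0 or self.max_iter < 1 or self.fd_step <= 0.0:
            raise ValueError("threshold, max_iter and fd_step must be positive")


@dataclass
class OptimizerState:
    """Terminal state of one quasi-Newton run (on the minimized objective)."""

    theta: np.ndarray
    psi: float
    grad: np.ndarray
    H_inv: np.ndarray
    iteration: int
    converged: bool
    n_evals: int = 0
    message: str = ""

    @property
    def H(self) -> np.ndarray:
        """The BFGS curvature approximation (inverse of the stored H_inv)."""
        return np.linalg.inv(self.H_inv)


@dataclass
class ChannelEstimate:
    channel: int
    params: LocationScaleParams
    psi: float
    iterations: int
    converged: bool


@dataclass
class EstimationResult:
    """Per-channel MHD estimates and their componentwise average."""

    per_channel: list[ChannelEstimate]
    averaged: LocationScaleParams
    h: float
    config: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return all(c.converged for c in self.per_channel)

    def to_dict(self) -> dict:
        return {
            "averaged": {"mu": self.averaged.mu, "sigma": self.averaged.sigma},
            "per_channel": [
                {
                    "channel": c.channel,
                    "mu": c.params.mu,
                    "sigma": c.params.sigma,
                    "psi": c.psi,
                    "iterations": c.iterations,
                    "converged": c.converged,
                }
                for c in self.per_channel
            ],
            "h": self.h,
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def normal_density(grid, sigma: float) -> np.ndarray:
    """Density of N(0, sigma^2) on ``grid``."""
    if sigma <= 0.0:
        raise ValueError("sigma must be positive")
    y = np.asarray(grid, dtype=float)
    return np.exp(-0.5 * np.square(y / sigma)) / (sigma * _SQRT_2PI)


def affinity(g: DensityEstimate, f_vals) -> float:
    """Hellinger affinity: the trapezoid integral of sqrt(g * f) on g's grid."""
    f_vals = np.asarray(f_vals, dtype=float)
    if f_vals.shape != g.values.shape:
        raise ValueError("f_vals must be evaluated on the density's grid")
    integrand = np.sqrt(np.clip(g.values, 0.0, None) * np.clip(f_vals, 0.0, None))
    return float(np.trapezoid(integrand, g.grid))


def hellinger_sq(g: DensityEstimate, f_vals) -> float:
    """Squared Hellinger distance HD^2 = 2 (1 - A), in [0, 2]."""
    return 2.0 * (1.0 - affinity(g, f_vals))


def objective_psi(
    dataset: CompressedDataset,
    i: int,
    theta: LocationScaleParams | Sequence[float],
    kernel: str,
    h: float,
    n_grid: int = 1025,
) -> float:
    """Psi(i, theta): affinity of channel-i residual KDE and N(0, sigma^2).

    The quadrature grid is rebuilt from the current mu's residuals at
    every evaluation; the bandwidth ``h`` stays fixed for the run.
    """
    mu, sigma = (theta.mu, theta.sigma) if isinstance(theta, LocationScaleParams) else (
        float(theta[0]),
        float(theta[1]),
    )
    u = center_scale_residuals(dataset, i, mu)
    grid = make_grid(u, h, sigma_hint=sigma, n_points=n_grid)
    g = kde(u, kernel, h, grid)
    return affinity(g, normal_density(grid, sigma))


def _fd_gradient(
    f: Callable[[np.ndarray], float], x: np.ndarray, cfg: OptimizerConfig
) -> tuple[np.ndarray, int]:
    """Central finite-difference gradient with componentwise relative steps."""
    g = np.empty_like(x)
    for i in range(x.size):
        step = cfg.fd_step * max(1.0, abs(x[i]))
        e = np.zeros_like(x)
        e[i] = step
        g[i] = (f(x + e) - f(x - e)) / (2.0 * step)
    return g, 2 * x.size


def _feasible(x: np.ndarray, cfg: OptimizerConfig) -> bool:
    return cfg.sigma_min is None or x[1] >= cfg.sigma_min


def backtracking_search(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    direction: np.ndarray,
    grad: np.ndarray,
    f0: float,
    cfg: OptimizerConfig,
) -> tuple[float, float, int] | None:
    """Largest t in {1, kappa, kappa^2, ...} meeting the Armijo condition.

    Trial points violating the sigma floor count as condition failures.
    Returns ``(t, f(x + t d), evals)`` or None if no step above
    ``cfg.t_min`` is acceptable.
    """
    slope = float(grad @ direction)
    if slope >= 0.0:
        raise ValueError("backtracking requires a descent direction")
    t = 1.0
    evals = 0
    while t >= cfg.t_min:
        trial = x + t * direction
        if _feasible(trial, cfg):
            f_trial = f(trial)
            evals += 1
            if f_trial <= f0 + cfg.zeta * t * slope:
                return t, f_trial, evals
        t *= cfg.kappa
    return None


def quasi_newton_bfgs(
    f: Callable[[np.ndarray], float],
    theta0,
    cfg: OptimizerConfig | None = None,
) -> OptimizerState:
    """Minimize ``f`` by quasi-Newton iteration with BFGS curvature updates.

    The search direction is ``-H_inv grad`` with ``H_0 = I``; ``H_inv``
    is maintained directly through the inverse BFGS update.  The step
    length comes from the backtracking line search, so accepted steps
    never increase the objective.  Iteration stops when the objective
    change ``e_k`` falls below ``cfg.threshold``.
    """
    cfg = cfg or OptimizerConfig()
    x = np.asarray(theta0, dtype=float).copy()
    if not _feasible(x, cfg):
        raise ValueError("infeasible starting point (sigma below floor)")
    n = x.size
    H_inv = np.eye(n)
    fx = f(x)
    grad, ge = _fd_gradient(f, x, cfg)
    n_evals = 1 + ge
    converged = False
    message = "max_iter reached"
    k = 0
    for k in range(1, cfg.max_iter + 1):
        d = -H_inv @ grad
        if float(grad @ d) >= 0.0:
            # curvature approximation lost descent: reset to steepest descent
            H_inv = np.eye(n)
            d = -grad
            if float(grad @ d) >= 0.0:
                converged = True
                message = "zero gradient"
                break
        ls = backtracking_search(f, x, d, grad, fx, cfg)
        if ls is None:
            message = "line-search failure"
            break
        t, f_new, evals = ls
        n_evals += evals
        x_new = x + t * d
        grad_new, ge = _fd_gradient(f, x_new, cfg)
        n_evals += ge
        dk = x_new - x
        qk = grad_new - grad
        qd = float(qk @ dk)
        if qd > 1e-14 * float(np.linalg.norm(qk) * np.linalg.norm(dk) + 1e-300):
            # inverse BFGS update: H^-1 <- (I - d q'/q'd) H^-1 (I - q d'/q'd) + d d'/q'd
            rho = 1.0 / qd
            V = np.eye(n) - rho * np.outer(dk, qk)
            H_inv = V @ H_inv @ V.T + rho * np.outer(dk, dk)
        e_k = abs(f_new - fx)
        x, fx, grad = x_new, f_new, grad_new
        if e_k < cfg.threshold:
            converged = True
            message = "objective change below threshold"
            break
    return OptimizerState(
        theta=x,
        psi=fx,
        grad=grad,
        H_inv=H_inv,
        iteration=k,
        converged=converged,
        n_evals=n_evals,
        message=message,
    )


def initial_values(dataset: CompressedDataset) -> LocationScaleParams:
    """Robust starting values from the pooled stored values.

    Gaussian/gamma/degenerate sensing:  mu0 = median(y_tilde)/J and
    sigma0 = 1.48 MAD(y_tilde)/B; Bernoulli sensing (mean p = S/J puts
    y_tilde on the raw scale already) drops both divisors.
    """
    y = dataset.y_tilde.ravel()
    med = float(np.median(y))
    s = bandwidth_scale(dataset)  # already family-aware about the divisor
    if dataset.spec.family == "bernoulli":
        return LocationScaleParams(mu=med, sigma=s)
    return LocationScaleParams(mu=med / dataset.spec.J, sigma=s)


def initial_sigma_moment(
    dataset: CompressedDataset, mu0: float | None = None
) -> float:
    """Moment-based starting scale for Gaussian/gamma sensing.

    Inverts the identity Var(y_tilde) = J [sigma^2 (1 + gamma0^2)
    + mu^2 gamma0^2] for sigma.  Falls back to the MAD initializer with
    a warning when the radicand is not positive.
    """
    spec = dataset.spec
    if spec.family == "bernoulli":
        raise ValueError("moment initializer is defined for mean-1 sensing families")
    if mu0 is None:
        mu0 = initial_values(dataset).mu
    g2 = spec.variance
    var_hat = float(np.var(dataset.y_tilde.ravel()))
    radicand = (var_hat / spec.J - mu0**2 * g2) / (1.0 + g2)
    if radicand <= 0.0:
        warnings.warn(
            "moment initializer radicand not positive; using the MAD initializer",
            stacklevel=2,
        )
        return initial_values(dataset).sigma
    return float(np.sqrt(radicand))


def estimate(
    dataset: CompressedDataset,
    kernel: str = "gaussian",
    c_B: float = 0.3,
    cfg: OptimizerConfig | None = None,
    n_grid: int = 1025,
    theta0: LocationScaleParams | None = None,
) -> EstimationResult:
    """MHDE of (mu, sigma): per-channel affinity maximization, then averaging.

    Every channel starts from the common initializer and maximizes
    Psi(i, theta) (by minimizing -Psi); the overall estimate is the
    arithmetic mean of the per-channel estimates.  Non-convergent
    channels are flagged, still averaged, and raise a warning.
    """
    h = bandwidth(dataset, c_B)
    s_B = bandwidth_scale(dataset)
    if theta0 is None:
        theta0 = initial_values(dataset)
    cfg = cfg or OptimizerConfig()
    if cfg.sigma_min is None:
        cfg = replace(cfg, sigma_min=1e-4 * s_B)

    per_channel: list[ChannelEstimate] = []
    for i in range(1, dataset.S + 1):

        def neg_psi(x, _i=i):
            return -objective_psi(dataset, _i, x, kernel, h, n_grid)

        state = quasi_newton_bfgs(neg_psi, theta0.as_array(), cfg)
        per_channel.append(
            ChannelEstimate(
                channel=i,
                params=LocationScaleParams(
                    mu=float(state.theta[0]),
                    sigma=max(float(state.theta[1]), cfg.sigma_min),
                ),
                psi=-state.psi,
                iterations=state.iteration,
                converged=state.converged,
            )
        )
    bad = [c.channel for c in per_channel if not c.converged]
    if bad:
        warnings.warn(f"channel(s) {bad} did not converge", stacklevel=2)
    averaged = LocationScaleParams(
        mu=float(np.mean([c.params.mu for c in per_channel])),
        sigma=float(np.mean([c.params.sigma for c in per_channel])),
    )
    return EstimationResult(
        per_channel=per_channel,
        averaged=averaged,
        h=h,
        config={
            "kernel": kernel,
            "c_B": c_B,
            "n_grid": n_grid,
            "theta0": {"mu": theta0.mu, "sigma": theta0.sigma},
            "optimizer": {
                "zeta": cfg.zeta,
                "kappa": cfg.kappa,
                "threshold": cfg.threshold,
                "max_iter": cfg.max_iter,
                "fd_step": cfg.fd_step,
                "sigma_min": cfg.sigma_min,
            },
            "sensing": dataset.spec.to_dict(),
            "B": dataset.B,
        },
    )


def effective_block_size(dataset: CompressedDataset) -> float:
    """Mean of (r_sum / omega)^2 over informative records; equals J for degenerate sensing."""
    keep = dataset.omega > 0.0
    return float(np.mean(np.square(dataset.r_sum[keep] / dataset.omega[keep])))


def confidence_interval(
    result: EstimationResult,
    dataset: CompressedDataset,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Wald intervals from the Gaussian-limit Fisher information.

    Standard errors use the compressed-design scaling
    ``se(mu) = sigma / sqrt(B * J_eff)`` with
    ``J_eff = mean (r_sum/omega)^2``, and ``se(sigma) = sigma / sqrt(2B)``.
    """
    if not result.converged:
        raise RuntimeError("refusing to build intervals from a non-converged fit")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    mu, sigma = result.averaged.mu, result.averaged.sigma
    z = float(norm.ppf(0.5 * (1.0 + level)))
    j_eff = effective_block_size(dataset)
    se_mu = sigma / np.sqrt(dataset.B * j_eff)
    se_sigma = sigma / np.sqrt(2.0 * dataset.B)
    return {
        "mu": (mu - z * se_mu, mu + z * se_mu),
        "sigma": (sigma - z * se_sigma, sigma + z * se_sigma),
    }
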