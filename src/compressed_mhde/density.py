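"""Kernels, robust scale, bandwidth rule and the residual kernel density.

The estimator works with the centered-scaled residuals of one channel,

    U_l = (y_tilde_l - mu * r_sum_l) / omega_l,

which, conditional on the sensing matrix, have mean 0 and variance
sigma^2 under the model.  Because the unknown location mu enters the
residuals, the kernel density estimate itself is parameter dependent:

    g_B(y | mu) = (1 / (B h)) * sum_l K((y - U_l(mu)) / h).

The bandwidth is h = c_B * s_B with the robust scale s_B built from
1.48 x MAD of the pooled stored values y_tilde.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from compressed_mhde.compression import CompressedDataset

_SQRT_2PI = np.sqrt(2.0 * np.pi)

#: kernel name -> (evaluator, variance of the kernel density)
KERNELS = {
    "gaussian": (lambda u: np.exp(-0.5 * np.square(u)) / _SQRT_2PI, 1.0),
    "epanechnikov": (
        lambda u: 0.75 * np.clip(1.0 - np.square(u), 0.0, None) * (np.abs(u) <= 1.0),
        0.2,
    ),
}


class DegenerateScaleError(ValueError):
    """Robust scale of the data is zero (all values equal)."""


def kernel_eval(kernel: str, u) -> np.ndarray | float:
    """Evaluate the named kernel at ``u`` (scalar or array)."""
    try:
        fn, _ = KERNELS[kernel]
    except KeyError:
        raise ValueError(f"unknown kernel {kernel!r}") from None
    out = fn(np.asarray(u, dtype=float))
    return float(out) if np.isscalar(u) else out


def robust_scale(values) -> float:
    """1.48 x median absolute deviation about the median.

    The factor 1.48 ~ 1/Phi^-1(0.75) makes the statistic consistent for
    the standard deviation at the Gaussian model.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("robust_scale needs at least 2 values")
    s = 1.48 * float(np.median(np.abs(v - np.median(v))))
    if s == 0.0:
        raise DegenerateScaleError("all values equal: robust scale is zero")
    return s


def bandwidth_scale(dataset: CompressedDataset) -> float:
    """Robust scale s_B of the stored values, with the family's divisor.

    Gaussian/gamma/degenerate sensing uses ``1.48 * MAD(y_tilde) / B``;
    Bernoulli sensing (mean p = S/J, so y_tilde is on the raw scale)
    drops the divisor.  The MAD pools all channels and blocks.
    """
    s = robust_scale(dataset.y_tilde.ravel())
    if dataset.spec.family == "bernoulli":
        return s
    return s / dataset.B


def bandwidth(dataset: CompressedDataset, c_B: float) -> float:
    """Bandwidth h = c_B * s_B."""
    if c_B <= 0.0:
        raise ValueError("c_B must be positive")
    return c_B * bandwidth_scale(dataset)


def center_scale_residuals(
    dataset: CompressedDataset, i: int, mu: float
) -> np.ndarray:
    """Residuals U_l = (y_tilde - mu * r_sum) / omega of channel ``i`` (1-based).

    Empty projection rows (omega = 0, Bernoulli sensing) carry no
    residual information and are skipped.
    """
    y, rs, om = dataset.channel(i)
    keep = om > 0.0
    if not keep.any():
        raise ValueError(f"channel {i} has no records with positive omega")
    return (y[keep] - mu * rs[keep]) / om[keep]


@dataclass
class DensityEstimate:
    """A kernel density evaluated on a quadrature grid."""

    grid: np.ndarray
    values: np.ndarray
    h: float
    channel: int | None = None
    mu_used: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape or self.grid.ndim != 1:
            raise ValueError("grid and values must be 1-d arrays of equal length")

    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.grid))


def make_grid(
    residuals, h: float, sigma_hint: float, n_points: int = 1025
) -> np.ndarray:
    """Equally spaced quadrature grid for the residual density.

    Spans the residual range padded by 6 bandwidths, unioned with
    ``[-8 * sigma_hint, 8 * sigma_hint]`` so the parametric target is
    always covered.
    """
    if h <= 0.0:
        raise ValueError("bandwidth must be positive")
    u = np.asarray(residuals, dtype=float)
    lo = min(float(u.min()) - 6.0 * h, -8.0 * sigma_hint)
    hi = max(float(u.max()) + 6.0 * h, 8.0 * sigma_hint)
    return np.linspace(lo, hi, n_points)


def kde(residuals, kernel: str, h: float, grid) -> DensityEstimate:
    """Kernel density g(y) = (1/(B h)) sum_l K((y - U_l)/h) on ``grid``."""
    u = np.asarray(residuals, dtype=float)
    if u.size == 0:
        raise ValueError("kde needs at least one residual")
    if h <= 0.0:
        raise ValueError("bandwidth must be positive")
    grid = np.asarray(grid, dtype=float)
    fn, _ = KERNELS[kernel]
    vals = fn((grid[:, None] - u[None, :]) / h).sum(axis=1) / (u.size * h)
    return DensityEstimate(grid=grid, values=vals, h=h)
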