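"""Preprocessing pipeline for raw single-column data.

The workflow mirrors a typical heavy-tailed payments analysis: drop
non-positive values, log-transform, keep a window of the log scale,
apply a scaled Box-Cox transformation toward normality, then split the
result randomly into B equal blocks ready for compression.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)


def log_window_filter(values, lo: float = 6.1, hi: float = 13.0) -> np.ndarray:
    """Drop non-positive values, take natural logs, keep logs strictly in (lo, hi)."""
    if not lo < hi:
        raise ValueError("lo must be below hi")
    v = np.asarray(values, dtype=float)
    positive = v[v > 0.0]
    logs = np.log(positive)
    kept = logs[(logs > lo) & (logs < hi)]
    dropped = v.size - kept.size
    if dropped:
        logger.info("log_window_filter dropped %d of %d values", dropped, v.size)
    if kept.size == 0:
        raise ValueError("no values survive the log window filter")
    return kept


def scaled_boxcox(L, lam: float = 2.0, divisor: float = 19.9091):
    """Scaled Box-Cox transform (L**lam - 1) / divisor."""
    if divisor == 0.0:
        raise ValueError("divisor must be nonzero")
    L = np.asarray(L, dtype=float)
    out = (np.power(L, lam) - 1.0) / divisor
    return float(out) if out.ndim == 0 else out


def random_block_split(values, B: int, seed: int) -> np.ndarray:
    """Randomly permute ``values`` and split into B blocks of J = floor(n/B).

    Leftover values after the equal split are dropped (with a log
    message).  Returns a (B, J) array.  Deterministic given ``seed``.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if B < 2:
        raise ValueError("B must be at least 2")
    if n < 2 * B:
        raise ValueError(f"need at least 2B={2 * B} values, got {n}")
    J = n // B
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    dropped = n - B * J
    if dropped:
        logger.info("random_block_split dropped %d leftover value(s)", dropped)
    return v[perm[: B * J]].reshape(B, J)
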