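"""Storey positive-FDR q-values.

The q-value of a test is the minimum positive false discovery rate at which
it would be called significant.  The estimator has two stages: (1) the
proportion of true nulls pi0 is estimated from the flat right tail of the
p-value histogram over a grid of tuning points lambda, smoothed with a cubic
polynomial and read off at the largest lambda; (2) q-values are the running
minimum of pi0 * m * p_(j) / j down the sorted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ValidationError

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.0, 0.96, 0.05), 2)


@dataclass
class QValueResult:
    p: np.ndarray
    pi0_hat: float
    q: np.ndarray
    lambda_grid: np.ndarray


def estimate_pi0(p: np.ndarray, lambda_grid=DEFAULT_LAMBDA_GRID) -> float:
    """Estimate the true-null proportion from the p-value tail.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the grid, smoothed by
    a cubic fit evaluated at the grid maximum and clipped into (0, 1].  Falls
    back to pi0 = 1 (with a warning) on degenerate input such as identical
    p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 10:
        raise ValidationError(f"need >= 10 p-values to estimate pi0, got {p.size}")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    lam = np.asarray(lambda_grid, dtype=float)
    if np.ptp(p) == 0:
        warnings.warn("all p-values identical; falling back to pi0 = 1", stacklevel=2)
        return 1.0
    m = p.size
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    coef = np.polynomial.polynomial.polyfit(lam, pi0_lam, 3)
    pi0 = float(np.polynomial.polynomial.polyval(lam.max(), coef))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def qvalues(p: np.ndarray, pi0: float | None = None,
            lambda_grid=DEFAULT_LAMBDA_GRID) -> QValueResult:
    """Positive-FDR q-values in the input order.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j on the sorted scale, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    lam = np.asarray(lambda_grid, dtype=float)
    if pi0 is None:
        pi0 = estimate_pi0(p, lam) if p.size >= 10 else 1.0
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    raw = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return QValueResult(p=p, pi0_hat=float(pi0), q=q, lambda_grid=lam)


def apply_gate(results: pd.DataFrame, q_threshold: float,
               column: str = "q") -> pd.DataFrame:
    """Rows whose q-value is strictly below the threshold."""
    if q_threshold <= 0:
        raise ValidationError("q_threshold must be positive")
    if len(results) == 0:
        return results
    if results[column].isna().any():
        raise ValidationError(f"column {column!r} has missing values; fill q first")
    return results[results[column] < q_threshold].copy()
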