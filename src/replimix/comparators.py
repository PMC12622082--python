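"""Baseline decision rules: sample-size-weighted meta-analysis and the
fixed p-value threshold rule.

Meta-analysis combines per-cohort z-statistics with weights proportional to
the square root of the (effective) sample size,

    z_meta = sum_k sqrt(N_k) z_k / sqrt(sum_k N_k),

which reduces to Stouffer's method for equal N.  It tests the *global* null
(all effects zero), a strictly smaller hypothesis than the replication
composite null, so a strong signal in a single cohort can reach significance
without replicating anywhere else.

The threshold rule declares replication only when every cohort's two-sided
p-value falls below a fixed cutoff (optionally also requiring a shared effect
direction); it tests the composite null but is not data-adaptive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "MetaResult",
    "ThresholdResult",
    "meta_analyze",
    "threshold_rule",
    "effective_sample_size",
    "z_to_p",
]


@dataclass
class MetaResult:
    """Per-variant meta z, two-sided p and significance at level alpha."""

    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float


@dataclass
class ThresholdResult:
    """Per-variant flag: all cohort p-values below t (and signs consistent)."""

    significant: np.ndarray
    threshold: float
    sign_consistent: np.ndarray


def z_to_p(Z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-values, kept strictly positive."""
    return np.clip(2.0 * norm.sf(np.abs(Z)), np.finfo(float).tiny, 1.0)


def effective_sample_size(n_cases, n_controls):
    """Effective N for a case-control cohort: 4 / (1/cases + 1/controls)."""
    n_cases = np.asarray(n_cases, dtype=float)
    n_controls = np.asarray(n_controls, dtype=float)
    if np.any(n_cases <= 0) or np.any(n_controls <= 0):
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def meta_analyze(Z: np.ndarray, N: np.ndarray, alpha: float = 1e-8) -> MetaResult:
    """Sample-size-weighted meta-analysis of per-cohort z-statistics.

    Variants with any missing z are excluded (NaN statistics, flag False)
    and counted in the log.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    N = np.asarray(N, dtype=float)
    if N.shape != (Z.shape[1],):
        raise ValueError("need one sample size per cohort")
    if np.any(N <= 0) or not np.all(np.isfinite(N)):
        raise ValueError("sample sizes must be positive and finite")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    w = np.sqrt(N)
    missing = ~np.all(np.isfinite(Z), axis=1)
    if missing.any():
        logger.info("meta-analysis: excluded %d variants with missing z", int(missing.sum()))
    with np.errstate(invalid="ignore"):
        z_meta = Z @ w / np.sqrt(np.sum(w**2))
    z_meta = np.where(missing, np.nan, z_meta)
    p = np.where(missing, np.nan, z_to_p(np.nan_to_num(z_meta)))
    significant = np.where(missing, False, p < alpha)
    return MetaResult(z=z_meta, p=p, significant=significant.astype(bool), alpha=float(alpha))


def threshold_rule(
    P: np.ndarray,
    signs: np.ndarray,
    t: float,
    require_sign_consistency: bool = True,
) -> ThresholdResult:
    """Flag variants whose p-value beats t in every cohort.

    With ``require_sign_consistency`` (the default), a variant whose effect
    directions disagree across cohorts is never flagged, matching the
    replication definition of the composite null.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    signs = np.atleast_2d(np.asarray(signs, dtype=float))
    if signs.shape != P.shape:
        raise ValueError("signs must have the same shape as P")
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    flag = np.all(P < t, axis=1)
    s = np.sign(signs)
    consistent = np.all(s == s[:, [0]], axis=1) & np.all(s != 0, axis=1)
    if require_sign_consistency:
        flag &= consistent
    return ThresholdResult(significant=flag, threshold=float(t), sign_consistent=consistent)
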