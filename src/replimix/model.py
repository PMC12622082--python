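"""Empirical-Bayes replication testing via a conditionally symmetric Gaussian mixture.

The replication composite null for a variant observed in K cohorts states that
its effect is zero in at least one cohort, or that two cohorts disagree in
sign.  Each variant j carries a latent configuration vector
``H_j in {-1, 0, +1}^K`` giving the association status per cohort; exactly two
of the 3^K configurations (all +1, all -1) constitute the alternative.

The two-group model places a prior over configurations and a per-cohort
density on z-statistics: standard normal where ``H_jk = 0`` and a Gaussian
mixture with positive location parameters, reflected to the sign of
``H_jk``, where it is non-null.  Two constraints make the mixture
*conditionally symmetric* and rule out frequentist/Bayesian ranking
contradictions (larger same-sign |z| can never look less replicated):

* all sign patterns sharing a binary non-null pattern are equiprobable, and
* alternative component variances are floored at the null variance of 1.

The local false discovery rate of a variant is the posterior mass of the
null configuration set given its z-vector; sorting variants by lfdr and
rejecting the longest prefix whose running mean stays below q controls the
Bayes FDR at q.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ConfigurationSet",
    "CsmGmmFit",
    "ReplicationResult",
    "enumerate_configurations",
    "config_density",
    "fit_em",
    "lfdr",
    "reject_at_fdr",
    "replication_analysis",
]

_LOG_2PI = np.log(2.0 * np.pi)
_MU_FLOOR = 1e-3
_TAU2_FLOOR = 1.0


@dataclass(frozen=True)
class ConfigurationSet:
    """All 3^K association configurations with their null/alternative split.

    Configurations are ordered canonically: binary non-null patterns in
    lexicographic order (null cohorts first), and within a pattern the sign
    assignments in lexicographic order with -1 before +1.  For K=2 this is
    (0,0), (0,-1), (0,+1), (-1,0), (+1,0), (-1,-1), (-1,+1), (+1,-1), (+1,+1).
    """

    K: int
    configs: np.ndarray  # (L+1, K) int8
    is_alternative: np.ndarray  # (L+1,) bool

    @property
    def n_configs(self) -> int:
        return self.configs.shape[0]

    @property
    def null_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_alternative)

    @property
    def alternative_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_alternative)

    @property
    def pattern_codes(self) -> np.ndarray:
        """Integer code of each configuration's binary non-null pattern.

        Bit i (from the left cohort) set iff cohort i is non-null, so codes
        index an array of length 2^K.
        """
        nonzero = (self.configs != 0).astype(np.int64)
        weights = 1 << np.arange(self.K - 1, -1, -1)
        return nonzero @ weights

    @property
    def n_nonzero(self) -> np.ndarray:
        return (self.configs != 0).sum(axis=1)


def enumerate_configurations(K: int) -> ConfigurationSet:
    """Enumerate the 3^K configurations for K cohorts.

    Replication requires at least two cohorts; K is capped at 8 because the
    lfdr sums over all 3^K configurations per variant.
    """
    if not isinstance(K, (int, np.integer)) or isinstance(K, bool):
        raise TypeError("K must be an integer")
    if K < 2 or K > 8:
        raise ValueError(f"K must be between 2 and 8, got {K}")
    rows = []
    for pattern in itertools.product((0, 1), repeat=K):
        nonzero = [i for i, b in enumerate(pattern) if b]
        for signs in itertools.product((-1, 1), repeat=len(nonzero)):
            h = [0] * K
            for i, s in zip(nonzero, signs):
                h[i] = s
            rows.append(h)
    configs = np.asarray(rows, dtype=np.int8)
    is_alt = np.all(configs == 1, axis=1) | np.all(configs == -1, axis=1)
    return ConfigurationSet(K=K, configs=configs, is_alternative=is_alt)


@dataclass
class CsmGmmFit:
    """Fitted conditionally symmetric Gaussian mixture two-group model.

    ``pattern_weights[b]`` is the prior mass of the binary non-null pattern
    with code b (see :meth:`ConfigurationSet.pattern_codes`); it is split
    equally across the 2^(#non-null) sign patterns sharing it.  Per cohort k
    the alternative magnitude distribution is an M-component mixture with
    locations ``mu[k]`` (> 0), variances ``tau2[k]`` (>= 1) and weights
    ``lam[k]``; the non-null density at sign s is the mixture reflected to
    locations ``s * mu``.  The null density is standard normal.
    """

    K: int
    M: int
    pattern_weights: np.ndarray  # (2^K,)
    mu: np.ndarray  # (K, M)
    tau2: np.ndarray  # (K, M)
    lam: np.ndarray  # (K, M)
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self):
        self.pattern_weights = np.asarray(self.pattern_weights, dtype=float)
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.tau2 = np.atleast_2d(np.asarray(self.tau2, dtype=float))
        self.lam = np.atleast_2d(np.asarray(self.lam, dtype=float))
        if self.pattern_weights.shape != (2**self.K,):
            raise ValueError("pattern_weights must have length 2^K")
        if not np.isclose(self.pattern_weights.sum(), 1.0):
            raise ValueError("pattern_weights must sum to 1")
        if np.any(self.pattern_weights < 0):
            raise ValueError("pattern_weights must be non-negative")
        for name, arr in (("mu", self.mu), ("tau2", self.tau2), ("lam", self.lam)):
            if arr.shape != (self.K, self.M):
                raise ValueError(f"{name} must have shape (K, M)")
        if np.any(self.mu <= 0):
            raise ValueError("alternative locations must be positive")
        if np.any(self.tau2 < _TAU2_FLOOR):
            raise ValueError("alternative variances must be >= 1")
        if not np.allclose(self.lam.sum(axis=1), 1.0):
            raise ValueError("per-cohort mixture weights must sum to 1")

    @property
    def configurations(self) -> ConfigurationSet:
        return enumerate_configurations(self.K)

    def config_priors(self, cfg: ConfigurationSet | None = None) -> np.ndarray:
        """Implied prior over configurations: Pr(H = h_l) = w_b / 2^(#non-null)."""
        cfg = cfg if cfg is not None else self.configurations
        return self.pattern_weights[cfg.pattern_codes] / (2.0 ** cfg.n_nonzero)

    def log_config_priors(self, cfg: ConfigurationSet | None = None) -> np.ndarray:
        cfg = cfg if cfg is not None else self.configurations
        with np.errstate(divide="ignore"):
            return np.log(self.pattern_weights[cfg.pattern_codes]) - (
                cfg.n_nonzero * np.log(2.0)
            )

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "M": self.M,
            "pattern_weights": self.pattern_weights.tolist(),
            "mu": self.mu.tolist(),
            "tau2": self.tau2.tolist(),
            "lam": self.lam.tolist(),
            "loglik_trace": [float(x) for x in self.loglik_trace],
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CsmGmmFit":
        return cls(
            K=d["K"],
            M=d["M"],
            pattern_weights=np.asarray(d["pattern_weights"]),
            mu=np.asarray(d["mu"]),
            tau2=np.asarray(d["tau2"]),
            lam=np.asarray(d["lam"]),
            loglik_trace=list(d.get("loglik_trace", [])),
            n_iter=d.get("n_iter", 0),
            converged=d.get("converged", True),
        )


@dataclass
class ReplicationResult:
    """Per-variant lfdr values and the rejection set at nominal FDR q."""

    lfdr: np.ndarray
    rejected: np.ndarray
    rank: np.ndarray  # ascending-lfdr rank (0 = smallest), ties by input index
    q: float

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


# ---------------------------------------------------------------------------
# densities


def _component_log_pdf(x: np.ndarray, mu: np.ndarray, tau2: np.ndarray) -> np.ndarray:
    """(J, M) log Normal(x_j; mu_m, tau2_m)."""
    x = x[:, None]
    return -0.5 * (_LOG_2PI + np.log(tau2)[None, :]) - (x - mu[None, :]) ** 2 / (
        2.0 * tau2[None, :]
    )


def _dim_log_tables(Z: np.ndarray, fit: CsmGmmFit):
    """Per-cohort log densities under h_k = 0, +1, -1.

    Returns (lognull, logpos, logneg), each (J, K).  The -1 table is the +1
    mixture evaluated at -z (reflection symmetry).
    """
    J, K = Z.shape
    lognull = -0.5 * (_LOG_2PI + Z**2)
    logpos = np.empty((J, K))
    logneg = np.empty((J, K))
    for k in range(K):
        loglam = np.log(fit.lam[k])[None, :]
        logpos[:, k] = logsumexp(
            loglam + _component_log_pdf(Z[:, k], fit.mu[k], fit.tau2[k]), axis=1
        )
        logneg[:, k] = logsumexp(
            loglam + _component_log_pdf(-Z[:, k], fit.mu[k], fit.tau2[k]), axis=1
        )
    return lognull, logpos, logneg


def _config_log_density(tables, configs: np.ndarray) -> np.ndarray:
    """(J, L+1) log f(z_j | H_j = h_l), the product density over cohorts."""
    lognull, logpos, logneg = tables
    J = lognull.shape[0]
    out = np.empty((J, configs.shape[0]))
    for l, h in enumerate(configs):
        acc = np.zeros(J)
        for k, hk in enumerate(h):
            if hk == 0:
                acc += lognull[:, k]
            elif hk == 1:
                acc += logpos[:, k]
            else:
                acc += logneg[:, k]
        out[:, l] = acc
    return out


def config_density(z: np.ndarray, h: np.ndarray, fit: CsmGmmFit) -> np.ndarray:
    """Density f(z | H = h): product over cohorts of the per-cohort density.

    ``z`` may be a single K-vector or a (J, K) matrix; returns a scalar or a
    length-J vector accordingly.
    """
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 1
    Z = np.atleast_2d(z)
    if Z.shape[1] != fit.K:
        raise ValueError(f"z must have K={fit.K} columns, got {Z.shape[1]}")
    if not np.all(np.isfinite(Z)):
        raise ValueError("z must be finite")
    h = np.asarray(h, dtype=np.int8)
    if h.shape != (fit.K,) or not np.all(np.isin(h, (-1, 0, 1))):
        raise ValueError("h must be a K-vector with entries in {-1, 0, +1}")
    tables = _dim_log_tables(Z, fit)
    dens = np.exp(_config_log_density(tables, h[None, :])[:, 0])
    return float(dens[0]) if scalar else dens


# ---------------------------------------------------------------------------
# lfdr and rejection


def lfdr(Z: np.ndarray, fit: CsmGmmFit) -> np.ndarray:
    """Posterior probability that each variant's configuration is null.

    lfdr_j = sum over null configurations of prior * density, divided by the
    same sum over all configurations, evaluated in log space.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != fit.K:
        raise ValueError(f"Z must have K={fit.K} columns, got {Z.shape[1]}")
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z must be finite")
    cfg = fit.configurations
    log_post = _config_log_density(_dim_log_tables(Z, fit), cfg.configs)
    log_post += fit.log_config_priors(cfg)[None, :]
    log_num = logsumexp(log_post[:, cfg.null_indices], axis=1)
    log_den = logsumexp(log_post, axis=1)
    return np.clip(np.exp(log_num - log_den), 0.0, 1.0)


def reject_at_fdr(lfdrs: np.ndarray, q: float) -> ReplicationResult:
    """Reject the longest ascending-lfdr prefix whose running mean is <= q.

    The running mean of the rejected lfdr values estimates the Bayes FDR of
    the rejection set, so the rule targets FDR control at q.  Ties are broken
    by input index (stable sort).
    """
    lfdrs = np.asarray(lfdrs, dtype=float)
    if lfdrs.ndim != 1:
        raise ValueError("lfdrs must be one-dimensional")
    if np.any(~np.isfinite(lfdrs)) or np.any(lfdrs < 0) or np.any(lfdrs > 1):
        raise ValueError("lfdr values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    n = lfdrs.size
    order = np.argsort(lfdrs, kind="stable")
    rejected = np.zeros(n, dtype=bool)
    if n:
        running_mean = np.cumsum(lfdrs[order]) / np.arange(1, n + 1)
        passing = np.flatnonzero(running_mean <= q)
        n_rej = passing[-1] + 1 if passing.size else 0
        rejected[order[:n_rej]] = True
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    return ReplicationResult(lfdr=lfdrs, rejected=rejected, rank=rank, q=float(q))


# ---------------------------------------------------------------------------
# EM fitting


def _initial_fit(Z: np.ndarray, M: int) -> CsmGmmFit:
    """Method-of-moments start: locations from |z| > 2 tail quantiles, a small
    symmetric prior mass on every non-null binary pattern."""
    J, K = Z.shape
    mu0 = np.empty((K, M))
    for k in range(K):
        tail = np.abs(Z[:, k])
        tail = tail[tail > 2.0]
        if tail.size >= M:
            qs = (np.arange(M) + 1.0) / (M + 1.0)
            mu0[k] = np.quantile(tail, qs)
        else:
            mu0[k] = 2.0 + np.arange(M)
    mu0 = np.maximum(mu0, _MU_FLOOR)
    # distinct starts per component even when the tail quantiles coincide
    if M > 1:
        mu0 += 0.05 * np.arange(M)[None, :]
    n_patterns = 2**K
    w0 = np.full(n_patterns, 1e-4)
    w0[0] = 1.0 - 1e-4 * (n_patterns - 1)
    return CsmGmmFit(
        K=K,
        M=M,
        pattern_weights=w0,
        mu=mu0,
        tau2=np.full((K, M), _TAU2_FLOOR),
        lam=np.full((K, M), 1.0 / M),
    )


def fit_em(
    Z: np.ndarray,
    M: int = 2,
    init: CsmGmmFit | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 42,
    min_variants: int = 10_000,
) -> CsmGmmFit:
    """Fit the conditionally symmetric mixture by constrained EM.

    The complete-data labels are (configuration, per-cohort mixture
    component).  The E-step computes configuration responsibilities from the
    current priors and densities; the M-step pools sign patterns within each
    binary pattern (the conditional-symmetry constraint) to update the
    pattern weights, and pools +/- responsibilities on reflected data to
    update per-cohort locations (kept positive), variances (floored at the
    null variance 1) and weights.

    Stops when the relative observed-data log-likelihood change drops below
    ``tol`` or after ``max_iter`` iterations; non-convergence is a warning,
    not an error.  ``min_variants`` guards against unstable mixture fits on
    short inputs.  ``seed`` is accepted for interface stability; the default
    initialization is deterministic and does not consume randomness.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    J, K = Z.shape
    if np.any(np.isnan(Z)):
        raise ValueError("Z contains NaNs")
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z must be finite")
    if J < min_variants:
        raise ValueError(
            f"need at least {min_variants} variants for a stable fit, got {J}"
        )
    if M < 1:
        raise ValueError("M must be >= 1")
    cfg = enumerate_configurations(K)
    fit = init if init is not None else _initial_fit(Z, M)
    if fit.K != K or fit.M != M:
        raise ValueError("init fit dimensions do not match Z and M")

    if np.ptp(Z) == 0.0:
        warnings.warn("degenerate input: all z-statistics identical", RuntimeWarning)
        fit.converged = False
        return fit

    pattern_codes = cfg.pattern_codes
    pos_masks = [cfg.configs[:, k] == 1 for k in range(K)]
    neg_masks = [cfg.configs[:, k] == -1 for k in range(K)]

    w = fit.pattern_weights.copy()
    mu, tau2, lam = fit.mu.copy(), fit.tau2.copy(), fit.lam.copy()
    trace: list[float] = []
    converged = False
    prev_ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        work = CsmGmmFit(K=K, M=M, pattern_weights=w, mu=mu, tau2=tau2, lam=lam)
        log_dens = _config_log_density(_dim_log_tables(Z, work), cfg.configs)
        log_post = log_dens + work.log_config_priors(cfg)[None, :]
        ll_j = logsumexp(log_post, axis=1)
        ll = float(ll_j.sum())
        trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
        resp = np.exp(log_post - ll_j[:, None])  # (J, L+1)

        w_new = np.zeros_like(w)
        np.add.at(w_new, pattern_codes, resp.sum(axis=0))
        w = np.maximum(w_new / J, 0.0)
        w /= w.sum()

        for k in range(K):
            a_pos = resp[:, pos_masks[k]].sum(axis=1)
            a_neg = resp[:, neg_masks[k]].sum(axis=1)
            loglam = np.log(np.maximum(lam[k], 1e-300))[None, :]
            gam_sum = np.zeros(M)
            s1 = np.zeros(M)
            gam_x2 = np.zeros(M)
            for a, x in ((a_pos, Z[:, k]), (a_neg, -Z[:, k])):
                lp = loglam + _component_log_pdf(x, mu[k], tau2[k])
                lp -= logsumexp(lp, axis=1, keepdims=True)
                gamma = a[:, None] * np.exp(lp)  # (J, M)
                gam_sum += gamma.sum(axis=0)
                s1 += gamma.T @ x
                gam_x2 += gamma.T @ (x**2)
            ok = gam_sum > 1e-12
            mu_k = np.where(ok, s1 / np.maximum(gam_sum, 1e-300), mu[k])
            mu_k = np.maximum(mu_k, _MU_FLOOR)
            # E[(x - mu)^2] from pooled sufficient statistics
            tau2_k = np.where(
                ok,
                gam_x2 / np.maximum(gam_sum, 1e-300)
                - 2.0 * mu_k * s1 / np.maximum(gam_sum, 1e-300)
                + mu_k**2,
                tau2[k],
            )
            mu[k] = mu_k
            tau2[k] = np.maximum(tau2_k, _TAU2_FLOOR)
            if gam_sum.sum() > 1e-12:
                lam[k] = np.maximum(gam_sum / gam_sum.sum(), 1e-12)
                lam[k] /= lam[k].sum()

    if not converged:
        warnings.warn(
            f"EM did not converge within {it} iterations", RuntimeWarning
        )
    return CsmGmmFit(
        K=K,
        M=M,
        pattern_weights=w,
        mu=mu,
        tau2=tau2,
        lam=lam,
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
    )


def replication_analysis(
    Z: np.ndarray,
    q: float = 0.1,
    M: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 42,
    min_variants: int = 10_000,
) -> tuple[CsmGmmFit, ReplicationResult]:
    """Fit the model, compute per-variant lfdr and reject at nominal FDR q."""
    fit = fit_em(Z, M=M, tol=tol, max_iter=max_iter, seed=seed, min_variants=min_variants)
    return fit, reject_at_fdr(lfdr(Z, fit), q)
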