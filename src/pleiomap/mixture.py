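"""Beta-Uniform mixture models for GWAS p-values, fitted by EM.

Two models are provided:

* a marginal two-group model ``pi1 * Beta(alpha, 1) + (1 - pi1) * U(0, 1)``
  for a single trait (the factor of the factorized independence null), and
* the four-group two-trait model with latent states ``{00, 10, 01, 11}``
  and product emissions: a trait's p-value follows ``Beta(alpha_k, 1)`` when
  the state says that trait is associated, and Uniform(0, 1) otherwise.

All density work is done in log space; the E-step normalizes with
log-sum-exp. The complete-data M-step for a Beta(alpha, 1) shape is the
weighted MLE ``alpha = -sum(w) / sum(w * log p)``, clamped away from the
boundary of (0, 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "EMConfig",
    "PairData",
    "MarginalFit",
    "PairMixtureFit",
    "beta_log_density",
    "fit_marginal_em",
    "fit_pair_em",
    "posterior_z",
    "local_fdr_11",
    "STATE_LABELS",
]

logger = logging.getLogger(__name__)

STATE_LABELS = ("00", "10", "01", "11")

P_FLOOR = 1e-30  # p-values clipped to [P_FLOOR, 1] before any log
ALPHA_MIN = 1e-4  # alpha clamped to [ALPHA_MIN, 1 - ALPHA_MIN]


@dataclass(frozen=True)
class EMConfig:
    """EM settings shared by the marginal and pair fits."""

    tol: float = 1e-6  # relative log-likelihood change declaring convergence
    max_iter: int = 2000
    init_pi: tuple[float, float, float, float] = (0.7, 0.1, 0.1, 0.1)
    init_alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if abs(sum(self.init_pi) - 1.0) > 1e-9 or min(self.init_pi) < 0:
            raise ValueError("init_pi must be a probability 4-vector")


@dataclass(frozen=True)
class PairData:
    """Aligned p-value vectors for one phenotype pair."""

    p1: np.ndarray
    p2: np.ndarray
    snp_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        p1 = np.asarray(self.p1, dtype=float)
        p2 = np.asarray(self.p2, dtype=float)
        if p1.ndim != 1 or p2.ndim != 1 or p1.shape != p2.shape:
            raise ValueError("p1 and p2 must be 1-D vectors of equal length")
        if not (np.isfinite(p1).all() and np.isfinite(p2).all()):
            raise ValueError("p-values must be finite")
        if p1.max(initial=0) > 1 or p2.max(initial=0) > 1:
            raise ValueError("p-values must not exceed 1")
        if p1.min(initial=1) <= 0 or p2.min(initial=1) <= 0:
            raise ValueError("p-values must be positive; clip before constructing")
        if self.snp_ids is not None and len(self.snp_ids) != p1.size:
            raise ValueError("snp_ids length must match p-value vectors")
        object.__setattr__(self, "p1", np.clip(p1, P_FLOOR, 1.0))
        object.__setattr__(self, "p2", np.clip(p2, P_FLOOR, 1.0))

    @property
    def n_snps(self) -> int:
        return self.p1.size


@dataclass(frozen=True)
class MarginalFit:
    """Two-group fit for a single trait."""

    pi1: float
    alpha: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class PairMixtureFit:
    """Fitted four-group mixture for one phenotype pair.

    ``pi`` orders the mixing proportions as (pi00, pi10, pi01, pi11);
    ``posteriors`` is the M x 4 matrix of Pr(state | p1, p2) in the same order.
    """

    pi: np.ndarray
    alpha1: float
    alpha2: float
    loglik: float
    posteriors: np.ndarray = field(repr=False, default=None)
    n_iter: int = 0
    converged: bool = True
    loglik_trace: np.ndarray = field(repr=False, default=None)


def beta_log_density(p, alpha):
    """Log density of Beta(alpha, 1) at ``p``: ``log(alpha) + (alpha - 1) log(p)``."""
    p = np.asarray(p, dtype=float)
    alpha = float(alpha)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must lie in (0, 1]")
    out = np.log(alpha) + (alpha - 1.0) * np.log(p)
    return out if out.ndim else float(out)


def _mle_alpha(weights: np.ndarray, logp: np.ndarray) -> float:
    """Weighted complete-data MLE of a Beta(alpha, 1) shape, boundary-clamped."""
    denom = float(np.dot(weights, logp))
    if denom >= 0.0:  # all weight on p == 1
        return 1.0 - ALPHA_MIN
    alpha = -float(weights.sum()) / denom
    return float(np.clip(alpha, ALPHA_MIN, 1.0 - ALPHA_MIN))


def fit_marginal_em(p, config: EMConfig | None = None) -> MarginalFit:
    """Fit ``pi1 * Beta(alpha, 1) + (1 - pi1) * U(0, 1)`` by EM."""
    config = config or EMConfig()
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("p must be a vector of length >= 2")
    if not np.isfinite(p).all():
        raise ValueError("p-values must be finite")
    p = np.clip(p, P_FLOOR, 1.0)
    logp = np.log(p)

    pi1 = 1.0 - config.init_pi[0]
    alpha = config.init_alpha
    trace = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        # E-step in linear space: with p clipped to >= P_FLOOR and alpha in
        # (0, 1), the Beta(alpha, 1) density is bounded by ~1e30 and the
        # uniform density is 1, so neither over- nor underflow can occur
        f_sig = alpha * np.exp((alpha - 1.0) * logp)
        lik = pi1 * f_sig + (1.0 - pi1)
        ll = float(np.log(lik).sum())
        trace.append(ll)
        w = pi1 * f_sig / lik
        # M-step
        pi1 = float(np.clip(w.mean(), 0.0, 1.0))
        wsum = w.sum()
        alpha = _mle_alpha(w, logp) if wsum > 0 else config.init_alpha
        if len(trace) > 1:
            prev = trace[-2]
            if abs(ll - prev) <= config.tol * (abs(prev) + 1e-12):
                converged = True
                break
    if not converged:
        logger.warning("marginal EM did not converge in %d iterations", config.max_iter)
    final_ll = trace[-1]
    if alpha >= 1.0 - 100 * ALPHA_MIN:
        # boundary guard: as alpha -> 1 the signal component duplicates the
        # Uniform null and pi1 is unidentified (flat likelihood); report the
        # all-null model it is indistinguishable from (exact loglik 0)
        logger.info("alpha at the uniform boundary (%.4f); reporting pi1 = 0", alpha)
        pi1 = 0.0
        alpha = 1.0 - ALPHA_MIN
        final_ll = 0.0
    return MarginalFit(
        pi1=pi1,
        alpha=alpha,
        loglik=final_ll,
        n_iter=it,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )


def _log_emissions(logp1: np.ndarray, logp2: np.ndarray,
                   alpha1: float, alpha2: float) -> np.ndarray:
    """M x 4 log emission densities for states (00, 10, 01, 11)."""
    b1 = np.log(alpha1) + (alpha1 - 1.0) * logp1
    b2 = np.log(alpha2) + (alpha2 - 1.0) * logp2
    zero = np.zeros_like(logp1)
    return np.stack([zero, b1, b2, b1 + b2], axis=1)


def fit_pair_em(
    data: PairData,
    config: EMConfig | None = None,
    init: tuple[np.ndarray, float, float] | None = None,
) -> PairMixtureFit:
    """Fit the four-group product-emission mixture by EM.

    E-step weights ``w_mc`` are proportional to ``pi_c`` times the product of
    the per-trait emission densities for state ``c``; the M-step sets each
    ``pi_c`` to the mean posterior weight and each shape to the weighted
    Beta(alpha, 1) MLE over the states in which that trait is associated
    (10 and 11 for trait 1; 01 and 11 for trait 2).

    ``init`` optionally overrides the starting point as
    ``(pi, alpha1, alpha2)``; by default the config's null-dominant start is
    used.
    """
    config = config or EMConfig()
    logp1 = np.log(data.p1)
    logp2 = np.log(data.p2)

    if init is not None:
        pi = np.asarray(init[0], dtype=float)
        alpha1 = float(np.clip(init[1], ALPHA_MIN, 1.0 - ALPHA_MIN))
        alpha2 = float(np.clip(init[2], ALPHA_MIN, 1.0 - ALPHA_MIN))
        if pi.shape != (4,) or pi.min() < 0 or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("init pi must be a probability 4-vector")
    else:
        pi = np.asarray(config.init_pi, dtype=float)
        alpha1 = alpha2 = config.init_alpha
    trace = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        # E-step in linear space (densities bounded; see fit_marginal_em)
        f1 = alpha1 * np.exp((alpha1 - 1.0) * logp1)
        f2 = alpha2 * np.exp((alpha2 - 1.0) * logp2)
        t0, t1 = pi[0], pi[1] * f1
        t2, t3 = pi[2] * f2, pi[3] * f1 * f2
        lik = t0 + t1 + t2 + t3
        ll = float(np.log(lik).sum())
        trace.append(ll)
        w10, w01, w11 = t1 / lik, t2 / lik, t3 / lik
        # M-step
        m10, m01, m11 = w10.mean(), w01.mean(), w11.mean()
        pi = np.array([1.0 - m10 - m01 - m11, m10, m01, m11])
        pi = np.clip(pi, 0.0, 1.0)
        pi = pi / pi.sum()
        w1 = w10 + w11
        w2 = w01 + w11
        alpha1 = _mle_alpha(w1, logp1) if w1.sum() > 0 else config.init_alpha
        alpha2 = _mle_alpha(w2, logp2) if w2.sum() > 0 else config.init_alpha
        if len(trace) > 1:
            prev = trace[-2]
            if abs(ll - prev) <= config.tol * (abs(prev) + 1e-12):
                converged = True
                break
    if not converged:
        logger.warning("pair EM did not converge in %d iterations", config.max_iter)

    fit = PairMixtureFit(
        pi=pi,
        alpha1=alpha1,
        alpha2=alpha2,
        loglik=trace[-1],
        posteriors=None,
        n_iter=it,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )
    # final posteriors at the converged parameters
    object.__setattr__(fit, "posteriors", posterior_z(fit, data))
    object.__setattr__(
        fit, "loglik", _pair_loglik(fit, logp1, logp2)
    )
    return fit


def _pair_loglik(fit: PairMixtureFit, logp1: np.ndarray, logp2: np.ndarray) -> float:
    logmix = np.log(np.maximum(fit.pi, 1e-300)) + _log_emissions(
        logp1, logp2, fit.alpha1, fit.alpha2
    )
    return float(logsumexp(logmix, axis=1).sum())


def posterior_z(fit: PairMixtureFit, data: PairData) -> np.ndarray:
    """Posterior state probabilities Pr(Z_mc = 1 | p_m1, p_m2) via Bayes' rule.

    Returns an M x 4 matrix over states (00, 10, 01, 11); rows sum to 1.
    """
    logmix = np.log(np.maximum(np.asarray(fit.pi, float), 1e-300)) + _log_emissions(
        np.log(data.p1), np.log(data.p2), fit.alpha1, fit.alpha2
    )
    return np.exp(logmix - logsumexp(logmix, axis=1)[:, None])


def local_fdr_11(fit: PairMixtureFit, data: PairData) -> np.ndarray:
    """Local FDR that a SNP is shared: ``1 - Pr(Z_m11 = 1 | p_m1, p_m2)``."""
    return 1.0 - posterior_z(fit, data)[:, 3]
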