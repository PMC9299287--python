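"""Hierarchical Beta-Binomial model: marginal likelihood, hyperparameter
fitting, shrinkage factors, and the empirical-Bayes connectivity estimate.

Given a partition, the block edge counts are Binomial(n_ab, theta_ab) and
the block probabilities follow Beta(alpha_0, beta_0) on the diagonal
(within-community) and Beta(alpha_1, beta_1) off the diagonal.  The two
hyperparameter pairs are fitted independently by maximizing the marginal
log-likelihood

    L(alpha, beta) = sum_blocks [ logB(alpha + x, beta + n - x) - logB(alpha, beta) ],

and the connectivity estimate is the posterior mean
(alpha + x) / (alpha + beta + n), a convex combination of the block MLE
x/n and the prior mean alpha/(alpha+beta) with weight
eta = (alpha+beta)/(alpha+beta+n) on the prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, digamma

from .blocks import BlockStats, ConnectivityEstimate


@dataclass
class HyperParams:
    """Beta hyperparameters for diagonal (d=0) and off-diagonal (d=1) blocks."""

    alpha0: float
    beta0: float
    alpha1: float
    beta1: float

    def __post_init__(self) -> None:
        if min(self.alpha0, self.beta0, self.alpha1, self.beta1) <= 0:
            raise ValueError("all hyperparameters must be strictly positive")

    def side(self, d: int) -> tuple[float, float]:
        return (self.alpha0, self.beta0) if d == 0 else (self.alpha1, self.beta1)


@dataclass
class OptimizerConfig:
    """Settings for the bounded quasi-Newton hyperparameter fit.

    The search runs over (log alpha, log beta) inside ``box_log_bounds``;
    the log parameterization enforces positivity and the box caps the
    degenerate spike that forms when all blocks share one empirical rate.
    """

    box_log_bounds: tuple[float, float] = (np.log(1e-6), np.log(1e6))
    restarts: int = 5
    tol: float = 1e-8
    seed: int = 0


@dataclass
class FitReport:
    hyperparams: HyperParams
    loglik_diag: float
    loglik_offdiag: float
    converged_diag: bool
    converged_offdiag: bool
    n_restarts_diag: int = 0
    n_restarts_offdiag: int = 0


def _side_counts(stats: BlockStats, side: str) -> tuple[np.ndarray, np.ndarray]:
    if side == "diagonal":
        return stats.diagonal()
    if side == "offdiagonal":
        return stats.offdiagonal()
    raise ValueError(f"unknown side {side!r}")


def marginal_loglik(stats: BlockStats, alpha: float, beta: float, side: str) -> float:
    """Marginal log-likelihood of one side's blocks under Beta(alpha, beta).

    Computed as sum_blocks [logB(alpha + x, beta + n - x) - logB(alpha, beta)],
    all in log space via log-Gamma.  Blocks with zero capacity contribute
    exactly 0; with no blocks on the side (off-diagonal at K=1) the value
    is 0.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be strictly positive")
    x, n = _side_counts(stats, side)
    if x.size == 0:
        return 0.0
    return float(np.sum(betaln(alpha + x, beta + n - x) - betaln(alpha, beta)))


def _neg_loglik_and_grad(logab: np.ndarray, x: np.ndarray, n: np.ndarray) -> tuple[float, np.ndarray]:
    a, b = np.exp(logab)
    val = np.sum(betaln(a + x, b + n - x) - betaln(a, b))
    # d/da logB(a+x, b+n-x) - logB(a,b) = psi(a+x) - psi(a+b+n) - psi(a) + psi(a+b)
    da = np.sum(digamma(a + x) - digamma(a + b + n) - digamma(a) + digamma(a + b))
    db = np.sum(digamma(b + n - x) - digamma(a + b + n) - digamma(b) + digamma(a + b))
    return -val, -np.array([da * a, db * b])


def _moment_init(x: np.ndarray, n: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Method-of-moments start from the blockwise rates, clipped to the box."""
    mask = n > 0
    if mask.sum() < 2:
        return np.zeros(2)
    rates = x[mask] / n[mask]
    m = rates.mean()
    v = rates.var()
    if v <= 0 or m <= 0 or m >= 1:
        return np.zeros(2)
    common = m * (1 - m) / v - 1
    if common <= 0:
        return np.zeros(2)
    return np.clip(np.log([m * common, (1 - m) * common]), lo, hi)


def _fit_side(
    x: np.ndarray, n: np.ndarray, cfg: OptimizerConfig, seed_offset: int
) -> tuple[float, float, float, bool, int]:
    """Fit (alpha, beta) for one side; returns (alpha, beta, loglik, converged, restarts)."""
    informative = n > 0
    if x.size == 0 or not informative.any():
        # empty likelihood term: a neutral prior keeps downstream criteria defined
        return 1.0, 1.0, 0.0, True, 0
    lo, hi = cfg.box_log_bounds
    bounds = [(lo, hi), (lo, hi)]
    starts = [_moment_init(x, n, lo, hi), np.zeros(2)]  # zeros => (alpha, beta) = (1, 1)

    best = None
    converged = False
    n_restarts = 0
    rng = np.random.default_rng(cfg.seed + seed_offset)
    attempt = 0
    while True:
        if attempt < len(starts):
            x0 = starts[attempt]
        elif attempt < len(starts) + cfg.restarts:
            n_restarts += 1
            x0 = rng.uniform(lo, hi, size=2)
        else:
            break
        res = minimize(
            _neg_loglik_and_grad,
            x0,
            args=(x, n),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"gtol": cfg.tol, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            converged = True
            if attempt >= len(starts) - 1:
                break
        attempt += 1
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"hyperparameter fit failed on all restarts: {best}")
    a, b = np.exp(best.x)
    return float(a), float(b), float(-best.fun), converged, n_restarts


def fit_hyperparams(stats: BlockStats, cfg: OptimizerConfig | None = None) -> FitReport:
    """Maximize the marginal likelihood independently on each side.

    Starts from a method-of-moments point and from (1, 1); on
    non-convergence up to ``cfg.restarts`` seeded uniform starts in the
    box are added, and the best optimum is kept.  Sides with no blocks
    (off-diagonal at K=1) are skipped with a neutral (1, 1) prior and a
    zero likelihood contribution.
    """
    cfg = cfg or OptimizerConfig()
    xd, nd = stats.diagonal()
    xo, no = stats.offdiagonal()
    a0, b0, ll0, conv0, r0 = _fit_side(xd, nd, cfg, seed_offset=0)
    a1, b1, ll1, conv1, r1 = _fit_side(xo, no, cfg, seed_offset=1)
    return FitReport(
        hyperparams=HyperParams(a0, b0, a1, b1),
        loglik_diag=ll0,
        loglik_offdiag=ll1,
        converged_diag=conv0,
        converged_offdiag=conv1,
        n_restarts_diag=r0,
        n_restarts_offdiag=r1,
    )


def _side_matrix(K: int, diag_val: tuple[float, float], off_val: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    a = np.full((K, K), off_val[0], dtype=np.float64)
    b = np.full((K, K), off_val[1], dtype=np.float64)
    np.fill_diagonal(a, diag_val[0])
    np.fill_diagonal(b, diag_val[1])
    return a, b


def shrinkage_factors(stats: BlockStats, hp: HyperParams) -> np.ndarray:
    """Shrinkage weights eta_ab = (alpha_d + beta_d) / (alpha_d + beta_d + n_ab).

    eta -> 1 pools all blocks (zero-capacity blocks fall back entirely on
    the prior); eta -> 0 recovers the block MLE as capacity grows.
    """
    a, b = _side_matrix(stats.K, (hp.alpha0, hp.beta0), (hp.alpha1, hp.beta1))
    s = a + b
    return s / (s + stats.capacities)


def eb_theta(stats: BlockStats, hp: HyperParams) -> ConnectivityEstimate:
    """Posterior-mean connectivity estimate (alpha_d + x) / (alpha_d + beta_d + n)."""
    a, b = _side_matrix(stats.K, (hp.alpha0, hp.beta0), (hp.alpha1, hp.beta1))
    theta = (a + stats.edge_counts) / (a + b + stats.capacities)
    return ConnectivityEstimate(theta=theta, shrinkage=shrinkage_factors(stats, hp), method="EB")
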