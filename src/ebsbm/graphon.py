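"""Piecewise-constant graphon estimation from a block approximation.

A partition with community proportions pi_k induces breakpoints
c_k = sum_{i<=k} pi_i on [0, 1]; the estimated graphon is
W-hat(x, y) = theta_{bin(x), bin(y)} with bin(x) = 1 + #{k : c_k <= x}.
Graphons are identifiable only up to measure-preserving maps, so the
communities are relabeled to make the degree function
g(l) = sum_k pi_k theta_lk nondecreasing before any comparison to a
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .blocks import block_counts, mle_theta
from .eb import fit_hyperparams, eb_theta, OptimizerConfig
from .graphs import Graph, Partition


@dataclass
class GraphonSpec:
    """A true graphon W: [0,1]^2 -> [0,1] with its generative parameters."""

    family: str
    rho: float
    lam: float
    W: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValueError("rho must lie in (0, 1]")


def power_law_graphon(rho: float, lam: float) -> GraphonSpec:
    """The product-form family W(x, y) = rho * lam^2 * (xy)^(lam - 1).

    rho scales the expected edge density (the integral of W is rho);
    lam >= 1 concentrates the edges on high-index nodes.  The constraint
    lam <= 1/sqrt(rho) keeps W within [0, 1].
    """
    if lam > 1.0 / np.sqrt(rho):
        raise ValueError("require lam <= 1/sqrt(rho) so that W <= 1")

    def W(x, y):
        return rho * lam**2 * (np.asarray(x) * np.asarray(y)) ** (lam - 1)

    return GraphonSpec(family="power_law", rho=rho, lam=lam, W=W)


@dataclass
class GraphonEstimate:
    """A blockwise-constant graphon estimate in identifiable orientation."""

    pi_hat: np.ndarray      # community proportions, length K
    breakpoints: np.ndarray  # c_1 < ... < c_K = 1
    theta: np.ndarray        # K x K connectivity after relabeling
    method: str = "EB"

    def __post_init__(self) -> None:
        self.pi_hat = np.asarray(self.pi_hat, dtype=np.float64)
        self.breakpoints = np.asarray(self.breakpoints, dtype=np.float64)
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if np.any(np.diff(self.breakpoints) <= 0) and self.breakpoints.size > 1:
            raise ValueError("breakpoints must be strictly increasing")
        if abs(self.breakpoints[-1] - 1.0) > 1e-12:
            raise ValueError("final breakpoint must be 1")
        g = self.theta @ self.pi_hat
        if np.any(np.diff(g) < -1e-12):
            raise ValueError("estimate is not in identifiable orientation (g must be nondecreasing)")

    @property
    def K(self) -> int:
        return self.pi_hat.size

    def evaluate(self, x, y) -> np.ndarray:
        """W-hat(x, y) for x, y in [0, 1) (scalars or arrays, broadcasting)."""
        bx = bin_point(x, self.breakpoints)
        by = bin_point(y, self.breakpoints)
        return self.theta[bx - 1, by - 1]

    def to_dict(self) -> dict:
        return {
            "pi_hat": self.pi_hat.tolist(),
            "breakpoints": self.breakpoints.tolist(),
            "theta": self.theta.tolist(),
            "method": self.method,
        }


def bin_point(x, breakpoints) -> np.ndarray | int:
    """bin(x) = 1 + #{k : c_k <= x}; a point on a breakpoint maps to the next bin."""
    x = np.asarray(x)
    if np.any(x < 0) or np.any(x >= 1):
        raise ValueError("x must lie in [0, 1)")
    idx = np.searchsorted(np.asarray(breakpoints), x, side="right") + 1
    return idx if idx.ndim else int(idx)


def relabel_identifiable(pi: np.ndarray, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permute communities so g(l) = sum_k pi_k theta_lk is nondecreasing.

    Returns (permutation, permuted pi, permuted theta).  The stable sort
    keeps the original order on ties.
    """
    pi = np.asarray(pi, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    g = theta @ pi
    perm = np.argsort(g, kind="stable")
    return perm, pi[perm], theta[np.ix_(perm, perm)]


def estimate_graphon(
    g: Graph,
    z: Partition,
    method: str = "EB",
    optimizer: OptimizerConfig | None = None,
) -> GraphonEstimate:
    """Blockwise-constant graphon estimate from a partition of ``g``.

    Proportions come from the cluster sizes, connectivity from the chosen
    estimator (empirical-Bayes posterior means or the blockwise MLE), and
    the result is put in identifiable orientation.
    """
    z = z.compact()
    stats = block_counts(g, z)
    if method == "EB":
        fit = fit_hyperparams(stats, optimizer)
        est = eb_theta(stats, fit.hyperparams)
    elif method == "MLE":
        est = mle_theta(stats)
    else:
        raise ValueError("method must be 'EB' or 'MLE'")
    pi = z.sizes / z.n
    _, pi_r, theta_r = relabel_identifiable(pi, est.theta)
    return GraphonEstimate(
        pi_hat=pi_r, breakpoints=np.cumsum(pi_r), theta=theta_r, method=method
    )


def graphon_mse(truth: GraphonSpec, est: GraphonEstimate, resolution: int = 500) -> float:
    """Midpoint-rule approximation of the integrated squared error
    between the true graphon and the blockwise-constant estimate.

    The grid midpoints are shifted by a deterministic epsilon if any
    coincides with a block breakpoint (a measure-zero set that would
    otherwise be resolved arbitrarily).
    """
    if resolution < 100:
        raise ValueError("resolution must be at least 100")
    xs = (np.arange(resolution) + 0.5) / resolution
    internal = est.breakpoints[:-1]
    if internal.size and np.min(np.abs(xs[:, None] - internal[None, :])) < 1e-12:
        xs = xs + 0.25 / resolution
    w_true = truth.W(xs[:, None], xs[None, :])
    bins = bin_point(xs, est.breakpoints) - 1
    w_hat = est.theta[np.ix_(bins, bins)]
    return float(np.mean((w_true - w_hat) ** 2))
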