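"""Simulators for the benchmark designs.

Four SBM designs and one graphon family are generated:

* model 1 / 2 (homogeneous): within-community probability rho*lam, between
  rho*eps, with lam = 0.9, eps = 0.1 and rho = 1 (dense) or rho = 0.2
  (sparse; edge density around 0.035 at K* = 10);
* model 1s / 2s (heterogeneous): per-community diagonal entries drawn from
  U(0.5, 0.9) and off-diagonal entries from U(0.3, 0.5), scaled by rho;
* graphon: W(x, y) = rho * lam^2 * (xy)^(lam - 1) with uniform latents.

Labels are multinomial with equal probabilities, so realized community
sizes vary; dyads are independent Bernoulli given the labels or latents.
Each replicate draws from an independent stream derived from
(master seed, replicate index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graphs import Graph, Partition
from .graphon import GraphonSpec, power_law_graphon

logger = logging.getLogger(__name__)


@dataclass
class SBMParams:
    pi: np.ndarray          # community probabilities, sums to 1
    theta_star: np.ndarray  # symmetric K* x K* connectivity in [0, 1]

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=np.float64)
        self.theta_star = np.asarray(self.theta_star, dtype=np.float64)
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.theta_star, self.theta_star.T):
            raise ValueError("theta_star must be symmetric")
        if np.any(self.theta_star < 0) or np.any(self.theta_star > 1):
            raise ValueError("theta_star entries must lie in [0, 1]")

    @property
    def K_star(self) -> int:
        return self.pi.size


@dataclass
class SimConfig:
    """One simulation scenario: model tag, size, and generative parameters."""

    model: str              # "m1", "m2", "m1s", "m2s", or "graphon"
    n: int
    K_star: int = 10
    rho: float = 1.0
    lam: float = 0.9
    eps: float = 0.1
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("m1", "m2", "m1s", "m2s", "graphon"):
            raise ValueError(f"unknown model tag {self.model!r}")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must lie in (0, 1]")
        if self.model == "graphon" and self.lam > 1.0 / np.sqrt(self.rho):
            raise ValueError("graphon family requires lam <= 1/sqrt(rho)")


def make_homogeneous_params(K_star: int, rho: float, lam: float, eps: float) -> SBMParams:
    """Affiliation-model connectivity: rho*lam within, rho*eps between."""
    if not (0 <= rho * eps <= rho * lam <= 1):
        raise ValueError("require 0 <= rho*eps <= rho*lam <= 1")
    if eps == lam:
        logger.warning("eps == lam gives a rank-degenerate SBM (no community signal)")
    theta = np.full((K_star, K_star), rho * eps)
    np.fill_diagonal(theta, rho * lam)
    return SBMParams(pi=np.full(K_star, 1.0 / K_star), theta_star=theta)


def sample_heterogeneous_params(K_star: int, rho: float, seed: int | np.random.Generator) -> SBMParams:
    """Connectivity with diagonal ~ U(0.5, 0.9)*rho and off-diagonal ~ U(0.3, 0.5)*rho.

    Off-diagonal entries are drawn on the upper triangle and mirrored,
    since the graph is undirected.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = np.zeros((K_star, K_star))
    iu = np.triu_indices(K_star, k=1)
    theta[iu] = rng.uniform(0.3, 0.5, size=iu[0].size) * rho
    theta += theta.T
    np.fill_diagonal(theta, rng.uniform(0.5, 0.9, size=K_star) * rho)
    return SBMParams(pi=np.full(K_star, 1.0 / K_star), theta_star=theta)


def _bernoulli_graph(prob_upper: np.ndarray, n: int, rng: np.random.Generator) -> Graph:
    """Symmetric 0/1 adjacency from upper-triangle Bernoulli probabilities."""
    a = np.zeros((n, n), dtype=np.int8)
    iu = np.triu_indices(n, k=1)
    a[iu] = (rng.random(iu[0].size) < prob_upper).astype(np.int8)
    a += a.T
    return Graph(a)


def simulate_sbm(params: SBMParams, n: int, seed: int | np.random.Generator) -> tuple[Graph, Partition]:
    """Draw labels from pi, then connect each dyad independently.

    The returned truth partition keeps the declared K* even if some
    community drew no nodes (use ``.compact()`` for the realized version).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = rng.choice(params.K_star, size=n, p=params.pi) + 1
    iu = np.triu_indices(n, k=1)
    probs = params.theta_star[labels[iu[0]] - 1, labels[iu[1]] - 1]
    g = _bernoulli_graph(probs, n, rng)
    return g, Partition(labels, K=params.K_star)


def simulate_graphon(spec: GraphonSpec, n: int, seed: int | np.random.Generator) -> tuple[Graph, np.ndarray]:
    """Uniform latents u_i, then dyads Bernoulli(W(u_i, u_j)); latents returned."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    iu = np.triu_indices(n, k=1)
    probs = spec.W(u[iu[0]], u[iu[1]])
    g = _bernoulli_graph(probs, n, rng)
    return g, u


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Independent stream for one replicate, reproducible in isolation."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, replicate)))


def simulate_from_config(cfg: SimConfig, replicate: int = 0):
    """Generate one replicate of the configured scenario.

    Returns (graph, truth) where truth is a Partition for the SBM models
    and the latent-position vector for the graphon model.
    """
    rng = replicate_rng(cfg.seed, replicate)
    if cfg.model in ("m1", "m2"):
        params = make_homogeneous_params(cfg.K_star, cfg.rho, cfg.lam, cfg.eps)
        return simulate_sbm(params, cfg.n, rng)
    if cfg.model in ("m1s", "m2s"):
        params = sample_heterogeneous_params(cfg.K_star, cfg.rho, rng)
        return simulate_sbm(params, cfg.n, rng)
    spec = power_law_graphon(cfg.rho, cfg.lam)
    return simulate_graphon(spec, cfg.n, rng)
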