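"""Evaluation metrics and the simulation experiment harness.

For SBM truths, estimation error is the node-level mean squared error:
both the estimate and the truth are expanded to n x n matrices through
their own partitions (so community label switching is irrelevant) and the
squared differences are averaged over ordered off-diagonal pairs.  For
graphon truths, the integrated squared error of the blockwise-constant
estimate is used after identifiability relabeling.

The harness regenerates the benchmark tables: per replicate it simulates
a network, builds candidate partitions over a K range, computes MLE and
EB estimates and their errors per K, and records three selected community
counts -- the penalized-likelihood (EB) choice, the CVRP baseline, and the
oracle K-tilde minimizing the MLE's error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import block_counts, mle_theta, ConnectivityEstimate
from .clustering import ClusterConfig, candidate_partitions
from .eb import fit_hyperparams, eb_theta
from .graphon import GraphonSpec, GraphonEstimate, power_law_graphon, graphon_mse, relabel_identifiable, estimate_graphon
from .graphs import Graph, Partition
from .selection import SelectConfig, partition_logmass, complexity_penalty, cvrp_risk
from .simulate import (
    SimConfig,
    make_homogeneous_params,
    sample_heterogeneous_params,
    simulate_sbm,
    simulate_graphon,
    replicate_rng,
)

logger = logging.getLogger(__name__)


def sbm_mse(
    est: ConnectivityEstimate | np.ndarray,
    z: Partition,
    truth_theta: np.ndarray,
    z_true: Partition,
) -> float:
    """Node-level mean squared error between two block-structured matrices.

    Each K x K matrix is expanded to node level through its own partition
    (Theta'_ij = theta_{Z(i) Z(j)}); the average runs over the n(n-1)
    ordered off-diagonal pairs.
    """
    if z.n != z_true.n:
        raise ValueError("partitions cover different node sets")
    theta_hat = est.theta if isinstance(est, ConnectivityEstimate) else np.asarray(est)
    n = z.n
    expanded_hat = theta_hat[np.ix_(z.labels - 1, z.labels - 1)]
    expanded_true = np.asarray(truth_theta)[np.ix_(z_true.labels - 1, z_true.labels - 1)]
    diff2 = (expanded_hat - expanded_true) ** 2
    np.fill_diagonal(diff2, 0.0)
    return float(diff2.sum() / (n * (n - 1)))


def k_tilde(mse_by_k: dict[int, float]) -> int:
    """The community count minimizing the MLE's error; ties toward smaller K."""
    if not mse_by_k:
        raise ValueError("empty MSE map")
    return min(mse_by_k, key=lambda k: (mse_by_k[k], k))


def deviation_metric(k_hat: list[int] | np.ndarray, reference) -> float:
    """Mean absolute deviation of selected counts from a reference (scalar or per-replicate)."""
    k_hat = np.asarray(k_hat, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if ref.ndim > 0 and ref.size != k_hat.size:
        raise ValueError("reference length does not match number of selections")
    return float(np.mean(np.abs(k_hat - ref)))


def test_likelihood(
    g: Graph,
    est_theta: np.ndarray,
    z_true: Partition,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> float:
    """Held-out log-likelihood over train-test and test-test dyads.

    Nodes are split into observed (V_o) and test (V_t) sets by seeded
    sampling; ``est_theta`` (indexed by the true labels) is assumed to be
    fitted by the caller on V_o's induced subgraph.  A degenerate
    probability contradicted by an observation yields -inf.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = g.n
    n_train = int(round(train_fraction * n))
    perm = rng.permutation(n)
    train, test = perm[:n_train], perm[n_train:]
    theta_nodes = np.asarray(est_theta)[np.ix_(z_true.labels - 1, z_true.labels - 1)]

    mask = np.zeros((n, n), dtype=bool)
    mask[np.ix_(train, test)] = True          # train-test dyads, each once
    tt = np.zeros((n, n), dtype=bool)
    tt[np.ix_(test, test)] = True
    mask |= np.triu(tt, k=1)                  # test-test dyads, unordered

    x = g.adjacency[mask].astype(np.float64)
    p = theta_nodes[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x == 1, np.log(p), np.log1p(-p))
    if np.any(np.isnan(terms)):
        return float("-inf")
    return float(terms.sum())


@dataclass
class ReplicateResult:
    k_hat_eb: int
    k_hat_cvrp: int
    k_tilde: int
    mse_mle: dict[int, float]
    mse_eb: dict[int, float]
    density: float
    failed: bool = False
    error: str | None = None


@dataclass
class EvalReport:
    """Aggregated outcomes of a simulation experiment."""

    sim: SimConfig
    replicates: list[ReplicateResult]

    def _ok(self) -> list[ReplicateResult]:
        return [r for r in self.replicates if not r.failed]

    @property
    def k_hat_eb(self) -> np.ndarray:
        return np.array([r.k_hat_eb for r in self._ok()])

    @property
    def k_hat_cvrp(self) -> np.ndarray:
        return np.array([r.k_hat_cvrp for r in self._ok()])

    @property
    def k_tilde(self) -> np.ndarray:
        return np.array([r.k_tilde for r in self._ok()])

    @property
    def mean_density(self) -> float:
        return float(np.mean([r.density for r in self._ok()]))

    def e_kstar(self, criterion: str = "EB") -> float:
        k_hat = self.k_hat_eb if criterion == "EB" else self.k_hat_cvrp
        return deviation_metric(k_hat, self.sim.K_star)

    def e_ktilde(self, criterion: str = "EB") -> float:
        k_hat = self.k_hat_eb if criterion == "EB" else self.k_hat_cvrp
        return deviation_metric(k_hat, self.k_tilde)

    def frequency_table(self, criterion: str = "EB") -> dict[int, int]:
        k_hat = self.k_hat_eb if criterion == "EB" else self.k_hat_cvrp
        values, counts = np.unique(k_hat, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def mean_mse_ratio(self, k: int) -> float:
        """Mean per-replicate ratio MSE_EB(k) / MSE_MLE(k)."""
        ratios = [r.mse_eb[k] / r.mse_mle[k] for r in self._ok() if r.mse_mle.get(k)]
        return float(np.mean(ratios))

    def mse_ratio_curve(self) -> dict[int, float]:
        ks = sorted(self._ok()[0].mse_mle) if self._ok() else []
        return {k: self.mean_mse_ratio(k) for k in ks}

    def frequency_frame(self) -> pd.DataFrame:
        """K-hat frequency table (one row per criterion) with the E summaries,
        mirroring the benchmark table layout."""
        ks = sorted(set(self.k_hat_eb) | set(self.k_hat_cvrp))
        rows = []
        for crit in ("EB", "CVRP"):
            freq = self.frequency_table(crit)
            row = {"criterion": crit}
            row.update({k: freq.get(k, 0) for k in ks})
            row["E_Kstar"] = self.e_kstar(crit)
            row["E_Ktilde"] = self.e_ktilde(crit)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "model": self.sim.model,
            "n": self.sim.n,
            "K_star": self.sim.K_star,
            "replicates": len(self.replicates),
            "failed": sum(r.failed for r in self.replicates),
            "mean_density": self.mean_density,
            "E_Kstar_EB": self.e_kstar("EB"),
            "E_Ktilde_EB": self.e_ktilde("EB"),
            "E_Kstar_CVRP": self.e_kstar("CVRP"),
            "E_Ktilde_CVRP": self.e_ktilde("CVRP"),
            "frequency_EB": self.frequency_table("EB"),
            "frequency_CVRP": self.frequency_table("CVRP"),
            "mse_ratio_EB_over_MLE": self.mse_ratio_curve(),
        }


def _graphon_estimate_from_partition(
    g: Graph, z: Partition, method: str, select_cfg: SelectConfig
) -> GraphonEstimate:
    return estimate_graphon(g, z, method=method, optimizer=select_cfg.optimizer)


def run_experiment(
    sim: SimConfig,
    cluster: ClusterConfig | None = None,
    select: SelectConfig | None = None,
) -> EvalReport:
    """Run one simulation scenario end to end.

    Per replicate: simulate, build candidate partitions for every K in the
    cluster config, compute per-K MLE/EB estimates and their errors
    (node-level MSE for SBM truths, integrated squared error for graphon
    truths), then record the EB-criterion and CVRP selections and the
    MLE-error-minimizing K-tilde.  Fully determined by the master seed.
    Failed replicates are recorded with a marker and excluded from the
    summaries.
    """
    cluster = cluster or ClusterConfig()
    select = select or SelectConfig()
    is_graphon = sim.model == "graphon"
    spec: GraphonSpec | None = power_law_graphon(sim.rho, sim.lam) if is_graphon else None

    results: list[ReplicateResult] = []
    for rep in range(sim.replicates):
        rng = replicate_rng(sim.seed, rep)
        try:
            if sim.model in ("m1", "m2"):
                params = make_homogeneous_params(sim.K_star, sim.rho, sim.lam, sim.eps)
                g, z_true = simulate_sbm(params, sim.n, rng)
            elif sim.model in ("m1s", "m2s"):
                params = sample_heterogeneous_params(sim.K_star, sim.rho, rng)
                g, z_true = simulate_sbm(params, sim.n, rng)
            else:
                g, _ = simulate_graphon(spec, sim.n, rng)
                params, z_true = None, None

            partitions = candidate_partitions(g, cluster)
            mse_mle: dict[int, float] = {}
            mse_eb: dict[int, float] = {}
            scores = []
            for i, z in enumerate(partitions):
                stats = block_counts(g, z)
                fit = fit_hyperparams(stats, select.optimizer)
                est_mle = mle_theta(stats)
                est_eb = eb_theta(stats, fit.hyperparams)
                key = cluster.k_range[i]
                if is_graphon:
                    pi = z.sizes / z.n
                    for est, store in ((est_mle, mse_mle), (est_eb, mse_eb)):
                        _, pi_r, theta_r = relabel_identifiable(pi, est.theta)
                        ge = GraphonEstimate(
                            pi_hat=pi_r, breakpoints=np.cumsum(pi_r), theta=theta_r, method=est.method
                        )
                        store[key] = graphon_mse(spec, ge)
                else:
                    mse_mle[key] = sbm_mse(est_mle, z, params.theta_star, z_true)
                    mse_eb[key] = sbm_mse(est_eb, z, params.theta_star, z_true)
                ll = fit.loglik_diag + fit.loglik_offdiag
                j_z = ll + partition_logmass(z, select.tau)
                penalty = complexity_penalty(z.K, g.n)
                scores.append((z.K, j_z - penalty, z))

            best_eb = min(scores, key=lambda s: (-s[1], s[0]))
            best_cvrp = min(scores, key=lambda s: (cvrp_risk(s[2]), s[0]))
            results.append(
                ReplicateResult(
                    k_hat_eb=best_eb[0],
                    k_hat_cvrp=best_cvrp[0],
                    k_tilde=k_tilde(mse_mle),
                    mse_mle=mse_mle,
                    mse_eb=mse_eb,
                    density=g.density,
                )
            )
        except Exception as exc:  # pragma: no cover - defensive flush of partial results
            logger.exception("replicate %d failed", rep)
            results.append(
                ReplicateResult(
                    k_hat_eb=-1, k_hat_cvrp=-1, k_tilde=-1,
                    mse_mle={}, mse_eb={}, density=float("nan"),
                    failed=True, error=str(exc),
                )
            )
    return EvalReport(sim=sim, replicates=results)
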