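# ebsbm

Empirical-Bayes shrinkage estimation and model selection for stochastic
block models (SBMs) and graphons.

## The problem

Given an undirected simple graph on *n* nodes and a partition of the nodes
into *K* communities, the standard estimate of the block connection
probability θ<sub>ab</sub> is the empirical edge frequency
θ̂<sub>ab</sub><sup>MLE</sup> = X<sup>B</sup><sub>ab</sub> / n<sub>ab</sub>,
where X<sup>B</sup><sub>ab</sub> counts the edges between communities *a*
and *b* and n<sub>ab</sub> is the number of dyads in that block.  When *K*
is large or the graph is sparse, many blocks contain few dyads and the MLE
is noisy.  This package implements a hierarchical Beta-Binomial model that
borrows strength across blocks:

- X<sup>B</sup><sub>ab</sub> | θ<sub>ab</sub> ~ Binomial(n<sub>ab</sub>, θ<sub>ab</sub>)
- θ<sub>aa</sub> ~ Beta(α₀, β₀) for within-community blocks,
  θ<sub>ab</sub> ~ Beta(α₁, β₁) for between-community blocks.

The hyperparameters are fitted by maximizing the marginal log-likelihood
(sums of log-Beta functions) with bounded L-BFGS-B, and the connectivity
estimate is the posterior mean

θ̂<sub>ab</sub><sup>EB</sup> = η<sub>ab</sub>·α<sub>d</sub>/(α<sub>d</sub>+β<sub>d</sub>) + (1−η<sub>ab</sub>)·X<sup>B</sup><sub>ab</sub>/n<sub>ab</sub>,
  η<sub>ab</sub> = (α<sub>d</sub>+β<sub>d</sub>)/(α<sub>d</sub>+β<sub>d</sub>+n<sub>ab</sub>),

a convex combination of the block MLE and the side's prior mean with a
data-determined shrinkage weight η.  The number of communities is chosen
across candidate partitions by a penalized joint marginal likelihood
(fitted block likelihoods plus a Jeffreys Dirichlet-multinomial mass for
the partition, minus an ICL-style penalty
½[(K−1) log n + K(K+1)/2 · log(n(n−1)/2)]).  A piecewise-constant graphon
estimate Ŵ(x, y) = θ̂<sub>bin(x),bin(y)</sub> follows from the block
approximation, relabeled so the degree function g(l) = Σ<sub>k</sub>
π<sub>k</sub> θ<sub>lk</sub> is nondecreasing (the identifiable
orientation).

Intended users: anyone fitting SBMs or blockwise graphon approximations to
network data — protein-interaction, social, or communication networks —
who wants stable connectivity estimates and a principled choice of K that
works with any community-detection front-end.  A regularized spectral
clusterer is included as the default front-end.

## Worked example

```python
from ebsbm import (ClusterConfig, candidate_partitions, select_partition,
                   make_homogeneous_params, simulate_sbm, block_counts,
                   fit_hyperparams, eb_theta, mle_theta, sbm_mse)

params = make_homogeneous_params(K_star=10, rho=1.0, lam=0.9, eps=0.1)
graph, truth = simulate_sbm(params, n=200, seed=42)
print(f"simulated graph: n={graph.n}, edges={graph.n_edges}, density={graph.density:.3f}")

parts = candidate_partitions(graph, ClusterConfig(k_range=list(range(1, 21)), seed=0))
best, scores = select_partition(graph, parts)
print(f"selected K = {best.K}")

stats = block_counts(graph, best)
fit = fit_hyperparams(stats)
hp = fit.hyperparams
mse_eb = sbm_mse(eb_theta(stats, hp), best, params.theta_star, truth)
mse_mle = sbm_mse(mle_theta(stats), best, params.theta_star, truth)
print(f"MSE: EB {mse_eb:.2e}, MLE {mse_mle:.2e}  (ratio {100*mse_eb/mse_mle:.1f}%)")
```

Output:

```
simulated graph: n=200, edges=3507, density=0.176
selected K = 10
MSE: EB 4.58e-06, MLE 2.52e-04  (ratio 1.8%)
```

The affiliation network has within-community probability 0.9 and
between-community probability 0.1 across 10 planted communities.  The
penalized criterion recovers K = 10 from candidates K = 1…20, and because
the within- (and between-) block probabilities are identical across
blocks, the fitted Beta priors are tight, shrinkage is strong, and the EB
estimate cuts the MLE's mean squared error (measured against the true
node-level connectivity matrix) by ~98%.

A command-line interface mirrors the library:

```sh
ebsbm simulate --model m2 --n 200 --k-star 10 --rho 0.2 --replicates 5 --seed 1 --out-dir scratch/m2
ebsbm experiment --config experiment.yaml --out report.json
```

where `experiment.yaml` holds `simulation:`, `clustering:` and
`selection:` sections matching `SimConfig`, `ClusterConfig` and
`SelectConfig`.

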