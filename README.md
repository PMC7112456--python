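# ssfir

Epidemic spreading on complex networks with a contact-triggered
self-protective susceptible class, and the tools to analyze it three ways.

The model extends SIR with a protected state `S^F`: along every S–I edge the
disease transmits at rate `beta` while the susceptible end adopts protection
at rate `beta_f`; protected individuals are infected through their own S^F–I
edges at the discounted rate `gamma * beta` (`0 <= gamma <= 1`); infected
nodes recover at rate `mu`. The package ships three mutually cross-checking
engines:

- **`ssfir.simulate`** — an exact event-driven (Gillespie) simulator on a
  concrete graph (numba-compiled inner loop), with ensemble management, the
  relative-variability measure `Delta` of the final size, and
  threshold estimation from the `Delta` peak.
- **`ssfir.theory`** — the bond-percolation / cavity analysis: per-edge
  competition probabilities `(T1, T2, T3)`, conditional infection
  probabilities, the self-consistent fixed point `theta`, the final size
  `R(inf)`, the outbreak condition `(T1 + T2*T3) * g1'(1) >= 1`, and a
  bisection threshold solver. Thresholds rise with `beta_f` and fall with
  `gamma`.
- **`ssfir.meanfield`** — the degree-based mean-field ODEs, implemented
  precisely so their well-known defect can be exhibited: the mean-field
  threshold `mu * <k> / <k^2>` does **not** depend on `beta_f` or `gamma`,
  unlike the percolation threshold (and simulations, which side with
  percolation).

`ssfir.networks` provides the graph substrate: Erdős–Rényi and uncorrelated
configuration-model (power-law, degree cutoff `sqrt(n)`) generators, a plain
edge-list text format, and degree distributions with their generating
functions `g0`/`g1`.

## Quick start

```python
import numpy as np
from ssfir import (EpidemicParams, generate_er, empirical_degree_distribution,
                   run_ensemble, prevalence, solve_threshold_beta)

net = generate_er(10_000, 10.0, seed=1)
dist = empirical_degree_distribution(net)
params = EpidemicParams(beta=0.3, beta_f=1.0, gamma=0.1, mu=1.0)

ens = run_ensemble(net, params, 1000, rng=2)
print(ens.outbreak_mean(), prevalence(dist, params).prevalence)
print(solve_threshold_beta(dist, beta_f=1.0, gamma=0.1, mu=1.0))
```

## Command line

A `ssfir` entry point wraps config-driven experiment pipelines
(`--config` YAML, `--seed`, `--out`, `--quiet`; defaults mirror the standard
setup: n = 10^4, `<k>` = 10, `mu` = 1, 1000 realizations):

```sh
ssfir net      --seed 1 --out results/net        # generate + save a graph
ssfir theory   --seed 1 --out results/theory     # theta/R(inf) sweep + thresholds
ssfir simulate --seed 1 --out results/sim        # Monte-Carlo sweep (rho, Delta)
ssfir meanfield --seed 1 --out results/mf        # mean-field R(inf) + liftoff
ssfir compare  --seed 1 --out results/cmp        # three-way comparison table
```

All outputs are CSV/JSON with floats fixed to 10 significant digits, so
reruns under the same config and seed are byte-identical.

Example config:

```yaml
network: {type: er, n: 2000, mean_degree: 10.0}
params:
  beta_grid: [0.05, 0.45, 0.02]   # start, stop, step (or an explicit list)
  beta_f: [0.0, 1.0]
  gamma: [0.1, 0.3]
  mu: 1.0
ensemble: {n_realizations: 500}
```

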