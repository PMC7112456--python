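"""Exact continuous-time stochastic simulation of the four reactions.

The dynamics is a continuous-time Markov process with four reaction
channels: per S-I edge, transmission at rate ``beta`` and alerting at rate
``beta_f``; per S^F-I edge, transmission at rate ``gamma * beta``; per
infected node, recovery at rate ``mu``.  The Gillespie engine keeps, for
every susceptible/protected node, its count of infected neighbors, together
with the aggregate S-I and S^F-I edge counts, so each event costs O(degree)
bookkeeping plus a rejection-sampled node draw.

The inner loop is compiled with numba; seeding it with a fixed integer makes
a run bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import ParameterError
from .networks import Network
from .theory import EpidemicParams

__all__ = [
    "SimulationOutcome",
    "EnsembleResult",
    "DeltaPeakResult",
    "run_epidemic",
    "run_ensemble",
    "variability_delta",
    "threshold_by_delta_peak",
]

# node states in the kernel
_S, _SF, _I, _R = 0, 1, 2, 3


@dataclass(frozen=True)
class SimulationOutcome:
    """Final state of one realization."""

    final_recovered_fraction: float
    final_sf_fraction: float
    peak_infected_fraction: float
    extinction_time: float
    #: transition totals (s_to_i, s_to_sf, sf_to_i, i_to_r) for invariant checks
    event_counts: tuple[int, int, int, int] = (0, 0, 0, 0)
    seed_nodes: tuple[int, ...] = ()


@dataclass
class EnsembleResult:
    """Per-realization final sizes of an independent ensemble."""

    rho_values: np.ndarray
    sf_values: np.ndarray
    extinction_times: np.ndarray
    seed_nodes: np.ndarray
    master_seed: int | None = None
    params: EpidemicParams | None = None
    mean_rho: float = field(init=False)
    delta: float = field(init=False)

    def __post_init__(self):
        self.rho_values = np.asarray(self.rho_values, dtype=float)
        self.mean_rho = float(self.rho_values.mean())
        self.delta = variability_delta(self.rho_values)

    @property
    def realization_count(self) -> int:
        return self.rho_values.size

    def outbreak_mean(self, cutoff: float = 0.05) -> float:
        """Mean final size over realizations with ``rho > cutoff``.

        Single-seed runs die out with finite probability even far above
        threshold, so the unconditioned mean underestimates the giant
        outbreak size; this is the quantity to compare against the
        percolation final-size formula.  NaN when no run exceeds the cutoff.
        """
        mask = self.rho_values > cutoff
        if not mask.any():
            return float("nan")
        return float(self.rho_values[mask].mean())

    def outbreak_probability(self, cutoff: float = 0.05) -> float:
        return float((self.rho_values > cutoff).mean())


@dataclass
class DeltaPeakResult:
    """Grid scan of the variability measure with its argmax."""

    beta_c: float
    betas: np.ndarray
    deltas: np.ndarray
    mean_rhos: np.ndarray
    warning: str | None = None


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gillespie_kernel(indptr, indices, n, beta, beta_f, gamma_beta, mu, seeds, rng_seed):
    np.random.seed(rng_seed)
    state = np.zeros(n, dtype=np.int8)
    ninf = np.zeros(n, dtype=np.int64)

    active_s = np.empty(n, dtype=np.int64)
    pos_s = np.full(n, -1, dtype=np.int64)
    n_as = 0
    active_f = np.empty(n, dtype=np.int64)
    pos_f = np.full(n, -1, dtype=np.int64)
    n_af = 0
    inf_list = np.empty(n, dtype=np.int64)
    pos_i = np.full(n, -1, dtype=np.int64)
    n_i = 0

    max_deg = 0
    for u in range(n):
        d = indptr[u + 1] - indptr[u]
        if d > max_deg:
            max_deg = d

    for s in seeds:
        state[s] = _I
        pos_i[s] = n_i
        inf_list[n_i] = s
        n_i += 1
    for s in seeds:
        for j in range(indptr[s], indptr[s + 1]):
            ninf[indices[j]] += 1
    w_s = 0
    for u in range(n):
        if state[u] == _S and ninf[u] > 0:
            pos_s[u] = n_as
            active_s[n_as] = u
            n_as += 1
            w_s += ninf[u]
    w_f = 0

    t = 0.0
    peak_i = n_i
    n_s_to_i = 0
    n_s_to_sf = 0
    n_sf_to_i = 0
    n_i_to_r = 0

    while n_i > 0:
        r_inf = beta * w_s
        r_alert = beta_f * w_s
        r_finf = gamma_beta * w_f
        r_rec = mu * n_i
        total = r_inf + r_alert + r_finf + r_rec
        t += -math.log(np.random.random()) / total
        draw = np.random.random() * total

        if draw < r_inf + r_alert:
            # pick an S node proportional to its infected-neighbor count
            while True:
                u = active_s[int(np.random.random() * n_as)]
                if np.random.random() * max_deg < ninf[u]:
                    break
            # swap-remove u from active_s
            i = pos_s[u]
            last = active_s[n_as - 1]
            active_s[i] = last
            pos_s[last] = i
            pos_s[u] = -1
            n_as -= 1
            w_s -= ninf[u]
            if draw < r_inf:
                # S -> I
                n_s_to_i += 1
                state[u] = _I
                pos_i[u] = n_i
                inf_list[n_i] = u
                n_i += 1
                if n_i > peak_i:
                    peak_i = n_i
                for j in range(indptr[u], indptr[u + 1]):
                    w = indices[j]
                    ninf[w] += 1
                    if state[w] == _S:
                        w_s += 1
                        if ninf[w] == 1:
                            pos_s[w] = n_as
                            active_s[n_as] = w
                            n_as += 1
                    elif state[w] == _SF:
                        w_f += 1
                        if ninf[w] == 1:
                            pos_f[w] = n_af
                            active_f[n_af] = w
                            n_af += 1
            else:
                # S -> S^F
                n_s_to_sf += 1
                state[u] = _SF
                pos_f[u] = n_af
                active_f[n_af] = u
                n_af += 1
                w_f += ninf[u]
        elif draw < r_inf + r_alert + r_finf:
            # S^F -> I
            while True:
                u = active_f[int(np.random.random() * n_af)]
                if np.random.random() * max_deg < ninf[u]:
                    break
            i = pos_f[u]
            last = active_f[n_af - 1]
            active_f[i] = last
            pos_f[last] = i
            pos_f[u] = -1
            n_af -= 1
            w_f -= ninf[u]
            n_sf_to_i += 1
            state[u] = _I
            pos_i[u] = n_i
            inf_list[n_i] = u
            n_i += 1
            if n_i > peak_i:
                peak_i = n_i
            for j in range(indptr[u], indptr[u + 1]):
                w = indices[j]
                ninf[w] += 1
                if state[w] == _S:
                    w_s += 1
                    if ninf[w] == 1:
                        pos_s[w] = n_as
                        active_s[n_as] = w
                        n_as += 1
                elif state[w] == _SF:
                    w_f += 1
                    if ninf[w] == 1:
                        pos_f[w] = n_af
                        active_f[n_af] = w
                        n_af += 1
        else:
            # I -> R
            v = inf_list[int(np.random.random() * n_i)]
            i = pos_i[v]
            last = inf_list[n_i - 1]
            inf_list[i] = last
            pos_i[last] = i
            pos_i[v] = -1
            n_i -= 1
            n_i_to_r += 1
            state[v] = _R
            for j in range(indptr[v], indptr[v + 1]):
                w = indices[j]
                ninf[w] -= 1
                if state[w] == _S:
                    w_s -= 1
                    if ninf[w] == 0:
                        i2 = pos_s[w]
                        last2 = active_s[n_as - 1]
                        active_s[i2] = last2
                        pos_s[last2] = i2
                        pos_s[w] = -1
                        n_as -= 1
                elif state[w] == _SF:
                    w_f -= 1
                    if ninf[w] == 0:
                        i2 = pos_f[w]
                        last2 = active_f[n_af - 1]
                        active_f[i2] = last2
                        pos_f[last2] = i2
                        pos_f[w] = -1
                        n_af -= 1

    n_r = 0
    n_sf = 0
    for u in range(n):
        if state[u] == _R:
            n_r += 1
        elif state[u] == _SF:
            n_sf += 1
    return n_r, n_sf, peak_i, t, n_s_to_i, n_s_to_sf, n_sf_to_i, n_i_to_r


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _resolve_seeds(net: Network, initial_infected, rng: np.random.Generator) -> np.ndarray:
    if isinstance(initial_infected, (int, np.integer)):
        count = int(initial_infected)
        if count < 1:
            raise ParameterError("need at least one initially infected node")
        if count > net.n:
            raise ParameterError("more seeds than nodes")
        return np.sort(rng.choice(net.n, size=count, replace=False)).astype(np.int64)
    seeds = np.unique(np.asarray(list(initial_infected), dtype=np.int64))
    if seeds.size == 0:
        raise ParameterError("empty initial infected set")
    if seeds.min() < 0 or seeds.max() >= net.n:
        raise ParameterError("seed node id out of range")
    return seeds


def run_epidemic(
    net: Network,
    params: EpidemicParams,
    initial_infected=1,
    rng=None,
) -> SimulationOutcome:
    """Run one realization to extinction (no infected nodes left).

    ``initial_infected`` is either a node count (chosen uniformly without
    replacement) or an explicit iterable of node ids.
    """
    rng = _as_rng(rng)
    seeds = _resolve_seeds(net, initial_infected, rng)
    indptr, indices = net.to_csr()
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    n_r, n_sf, peak_i, t_end, e1, e2, e3, e4 = _gillespie_kernel(
        indptr,
        indices,
        net.n,
        float(params.beta),
        float(params.beta_f),
        float(params.gamma * params.beta),
        float(params.mu),
        seeds,
        kernel_seed,
    )
    # conservation: every infection (incl. seeds) recovers exactly once
    assert n_r == e4 == e1 + e3 + seeds.size
    assert n_sf == e2 - e3
    return SimulationOutcome(
        final_recovered_fraction=n_r / net.n,
        final_sf_fraction=n_sf / net.n,
        peak_infected_fraction=peak_i / net.n,
        extinction_time=t_end,
        event_counts=(e1, e2, e3, e4),
        seed_nodes=tuple(int(s) for s in seeds),
    )


def run_ensemble(
    net: Network,
    params: EpidemicParams,
    n_realizations: int,
    initial_infected=1,
    rng=None,
) -> EnsembleResult:
    """Independent realizations with a fresh random seed node per run.

    Reruns with the same integer ``rng`` seed are bit-identical.
    """
    if n_realizations < 1:
        raise ParameterError("need n_realizations >= 1")
    master_seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = _as_rng(rng)
    rho = np.empty(n_realizations)
    sf = np.empty(n_realizations)
    times = np.empty(n_realizations)
    seed_nodes = np.empty(n_realizations, dtype=np.int64)
    for i in range(n_realizations):
        out = run_epidemic(net, params, initial_infected=initial_infected, rng=rng)
        rho[i] = out.final_recovered_fraction
        sf[i] = out.final_sf_fraction
        times[i] = out.extinction_time
        seed_nodes[i] = out.seed_nodes[0]
    return EnsembleResult(rho, sf, times, seed_nodes, master_seed=master_seed, params=params)


def variability_delta(rho_values) -> float:
    """Relative standard deviation ``sqrt(<rho^2> - <rho>^2) / <rho>``.

    Population moments over all realizations, early die-outs included.
    Returns NaN (with a warning) when the mean is zero.
    """
    rho = np.asarray(rho_values, dtype=float)
    if rho.size == 0:
        raise ParameterError("empty ensemble")
    mean = rho.mean()
    if mean == 0.0:
        warnings.warn("mean final size is zero; variability undefined", RuntimeWarning)
        return float("nan")
    # np.var is the two-pass population variance: exact 0 on constant input
    var = float(np.var(rho))
    return float(math.sqrt(max(var, 0.0)) / mean)


def threshold_by_delta_peak(
    net: Network,
    params_without_beta: EpidemicParams,
    beta_grid,
    n_realizations: int,
    rng=None,
    initial_infected=1,
) -> DeltaPeakResult:
    """Estimate the epidemic threshold as the argmax of the variability
    measure over a transmission-rate grid (ties go to the smaller rate)."""
    betas = np.asarray(beta_grid, dtype=float)
    if betas.size == 0:
        raise ParameterError("empty beta grid")
    if np.any(np.diff(betas) <= 0):
        raise ParameterError("beta grid must be strictly increasing")
    rng = _as_rng(rng)
    deltas = np.empty(betas.size)
    means = np.empty(betas.size)
    for i, b in enumerate(betas):
        ens = run_ensemble(
            net,
            params_without_beta.with_beta(float(b)),
            n_realizations,
            initial_infected=initial_infected,
            rng=rng,
        )
        deltas[i] = ens.delta
        means[i] = ens.mean_rho
    warning = None
    if betas.size == 1:
        warning = "single-point grid; returning its only value"
    peak = int(np.nanargmax(deltas))
    if betas.size > 1 and (peak == 0 or peak == betas.size - 1):
        warning = "variability peak at grid boundary; widen the grid"
    return DeltaPeakResult(float(betas[peak]), betas, deltas, means, warning)
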