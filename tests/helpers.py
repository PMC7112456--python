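"""Independent reference implementations used as test oracles.

Everything here is deliberately written from scratch (plain sums, bisection,
synchronous small-step dynamics) and shares no code path with the package:
these are the second routes of every dual-route check.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# classical SIR bond percolation (reduced model: no protected class)
# ---------------------------------------------------------------------------


def sir_g0(pk: dict[int, float], x: float) -> float:
    return sum(p * x**k for k, p in pk.items())


def sir_g1(pk: dict[int, float], x: float) -> float:
    kmean = sum(k * p for k, p in pk.items())
    return sum(k * p * x ** (k - 1) for k, p in pk.items() if k >= 1) / kmean


def sir_theta(pk: dict[int, float], transmissibility: float, tol: float = 1e-14) -> float:
    """Largest root of theta = 1 - G1(1 - theta*T) by bisection."""
    t = transmissibility

    def h(x: float) -> float:
        return x - (1.0 - sir_g1(pk, 1.0 - x * t))

    lo = 1e-12
    if h(lo) >= 0.0:  # subcritical: only the trivial root
        return 0.0
    hi = 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h(mid) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def sir_final_size(pk: dict[int, float], transmissibility: float) -> float:
    th = sir_theta(pk, transmissibility)
    return 1.0 - sir_g0(pk, 1.0 - th * transmissibility)


def sir_threshold_beta(pk: dict[int, float], mu: float) -> float:
    """beta solving beta/(beta+mu) * G1'(1) = 1."""
    kmean = sum(k * p for k, p in pk.items())
    k2 = sum(k * k * p for k, p in pk.items())
    g1p = (k2 - kmean) / kmean
    if g1p <= 1.0:
        return float("inf")
    # T_c = 1/g1p;  beta/(beta+mu) = T_c  =>  beta = mu*T_c/(1-T_c)
    t_c = 1.0 / g1p
    return mu * t_c / (1.0 - t_c)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle for the sequential-neighbor infection probability
# ---------------------------------------------------------------------------


def mc_p_infected_given_m(
    m: int, t1: float, t2: float, t3: float, n_rep: int, rng: np.random.Generator
) -> float:
    """Simulate the non-overlapping neighbor process directly.

    Neighbors act one at a time; each either transmits (t1), alerts (t2) or
    recovers untriggered (1-t1-t2).  After the first alert, the alerter and
    every later neighbor independently transmits with probability t3.
    """
    if m == 0:
        return 0.0
    u = rng.random((n_rep, m))
    transmit = u < t1
    alert = (u >= t1) & (u < t1 + t2)
    first_transmit = np.where(transmit.any(axis=1), transmit.argmax(axis=1), m)
    first_alert = np.where(alert.any(axis=1), alert.argmax(axis=1), m)
    direct = first_transmit < first_alert
    v = rng.random((n_rep, m))
    positions = np.arange(m)
    post_alert_hit = ((positions[None, :] >= first_alert[:, None]) & (v < t3)).any(axis=1)
    via_protected = (~direct) & (first_alert < m) & post_alert_hit
    return float((direct | via_protected).mean())


def binom_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 1e-12) / n)


# ---------------------------------------------------------------------------
# synchronous small-step engine (reference for the Gillespie simulator)
# ---------------------------------------------------------------------------

S, SF, I, R = 0, 1, 2, 3


def run_discrete(
    adj: list[list[int]],
    beta: float,
    beta_f: float,
    gamma: float,
    mu: float,
    seeds: list[int],
    rng: np.random.Generator,
    dt: float = 1e-3,
    check_conservation: bool = True,
) -> dict:
    """Synchronous dynamics with per-step probabilities rate*dt.

    O(dt) discretization error; used only for statistical cross-validation
    on small graphs.  Verifies state conservation after every step.
    """
    n = len(adj)
    state = np.full(n, S, dtype=np.int8)
    state[list(seeds)] = I
    p_inf = beta * dt
    p_alert = beta_f * dt
    p_finf = gamma * beta * dt
    p_rec = mu * dt
    assert p_inf + p_alert < 1.0 and p_finf < 1.0 and p_rec < 1.0
    peak = len(seeds)
    t = 0.0
    while True:
        infected = np.nonzero(state == I)[0]
        if infected.size == 0:
            break
        t += dt
        to_infect: set[int] = set()
        to_alert: set[int] = set()
        for v in infected:
            for w in adj[v]:
                if state[w] == S:
                    u = rng.random()
                    if u < p_inf:
                        to_infect.add(w)
                    elif u < p_inf + p_alert:
                        to_alert.add(w)
                elif state[w] == SF:
                    if rng.random() < p_finf:
                        to_infect.add(w)
        recover = infected[rng.random(infected.size) < p_rec]
        for w in to_infect:
            state[w] = I
        for w in to_alert - to_infect:
            if state[w] == S:
                state[w] = SF
        state[recover] = R
        peak = max(peak, int((state == I).sum()))
        if check_conservation:
            assert (state >= 0).all() and (state <= 3).all()
            assert len(state) == n
    counts = np.bincount(state, minlength=4)
    return {
        "rho": counts[R] / n,
        "sf": counts[SF] / n,
        "peak": peak / n,
        "time": t,
    }


# ---------------------------------------------------------------------------
# scalar degree-based SIR mean-field (reference for the beta_f = 0 limit)
# ---------------------------------------------------------------------------


def sir_meanfield_final_size(
    pk: dict[int, float],
    beta: float,
    mu: float,
    eps: float = 1e-4,
    dt: float = 0.01,
    t_max: float = 5000.0,
) -> float:
    """Forward-Euler degree-class SIR; intentionally naive and independent."""
    ks = np.array(sorted(pk), dtype=float)
    probs = np.array([pk[int(k)] for k in ks])
    kmean = float(np.dot(ks, probs))
    s = np.full(ks.size, 1.0 - eps)
    i = np.full(ks.size, eps)
    r = np.zeros(ks.size)
    t = 0.0
    while t < t_max:
        theta = float(np.dot(ks * probs, i)) / kmean
        new_inf = beta * ks * s * theta * dt
        rec = mu * i * dt
        s = s - new_inf
        i = i + new_inf - rec
        r = r + rec
        t += dt
        if float(np.dot(probs, i)) < 1e-10:
            break
    return float(np.dot(probs, r + i))
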