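"""Percolation (cavity) analysis of the four-reaction epidemic model.

The model extends SIR with a protected susceptible class ``S^F``: along each
S-I edge the disease transmits at rate ``beta`` while the susceptible end
becomes protected at rate ``beta_f``; protected nodes are infected through
S^F-I edges at the discounted rate ``gamma * beta``; infected nodes recover
at rate ``mu``.

Racing the three exponential clocks on an edge gives the competition
probabilities

    T1 = beta / (beta + beta_f + mu)        (S-I edge transmits first)
    T2 = beta_f / (beta + beta_f + mu)      (S-I edge alerts first)
    T3 = gamma*beta / (gamma*beta + mu)     (S^F-I edge transmits)

Conditioning a focal node on the number ``m`` of externally infected
neighbors (neighbors that get infected even with the focal node removed —
the cavity construction, valid on locally tree-like graphs) and assuming
those neighbors act in a non-overlapping order yields a closed form for the
infection probability ``p(R|m)``, a self-consistent fixed-point equation for
the external-infection probability ``theta``, the final epidemic size
``R(inf)``, and the outbreak condition

    (T1 + T2*T3) * g1'(1) >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import BracketingError, ParameterError
from .networks import DegreeDistribution

__all__ = [
    "EpidemicParams",
    "EdgeProbabilities",
    "TheoryResult",
    "edge_probabilities",
    "transmissibility",
    "p_infected_given_m",
    "p_infected_given_k",
    "theta_map",
    "solve_theta",
    "prevalence",
    "outbreak_condition",
    "solve_threshold_beta",
]

#: below this |T1+T2-T3| the shared denominator is treated as removable
_DEGENERATE_EPS = 1e-9


@dataclass(frozen=True)
class EpidemicParams:
    """Rate quadruple ``(beta, beta_f, gamma, mu)`` of the four reactions.

    ``beta`` and ``beta_f`` are *rates* and may exceed 1.  ``gamma = 1`` is
    admitted as the no-discount validation limit in which the protected
    class is epidemiologically inert.
    """

    beta: float
    beta_f: float = 0.0
    gamma: float = 0.0
    mu: float = 1.0

    def __post_init__(self):
        if self.beta < 0:
            raise ParameterError(f"beta must be >= 0, got {self.beta}")
        if self.beta_f < 0:
            raise ParameterError(f"beta_f must be >= 0, got {self.beta_f}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ParameterError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.mu <= 0:
            raise ParameterError(f"mu must be > 0, got {self.mu}")

    def with_beta(self, beta: float) -> "EpidemicParams":
        return EpidemicParams(beta, self.beta_f, self.gamma, self.mu)


@dataclass(frozen=True)
class EdgeProbabilities:
    """Per-edge competition probabilities ``(T1, T2, T3)``."""

    t1: float
    t2: float
    t3: float

    def __post_init__(self):
        for name in ("t1", "t2", "t3"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} = {v} outside [0, 1]")
        if self.t1 + self.t2 > 1.0 + 1e-12:
            raise ParameterError(f"t1 + t2 = {self.t1 + self.t2} exceeds 1")


@dataclass(frozen=True)
class TheoryResult:
    """Solved fixed point and, when requested, the final epidemic size."""

    theta: float
    prevalence: float | None
    converged: bool
    iterations: int
    residual: float


def edge_probabilities(params: EpidemicParams) -> EdgeProbabilities:
    """Edge-level competition probabilities from the rate quadruple."""
    denom = params.beta + params.beta_f + params.mu
    t1 = params.beta / denom
    t2 = params.beta_f / denom
    gb = params.gamma * params.beta
    t3 = gb / (gb + params.mu)
    return EdgeProbabilities(t1, t2, t3)


def transmissibility(params: EpidemicParams) -> float:
    """Effective edge transmissibility ``T1 + T2*T3`` driving the threshold."""
    ep = edge_probabilities(params)
    return ep.t1 + ep.t2 * ep.t3


# ---------------------------------------------------------------------------
# conditional infection probabilities
# ---------------------------------------------------------------------------

def _coefficients(ep: EdgeProbabilities) -> tuple[float, float, float]:
    """Return ``(A, B, D)`` with ``p = 1 - A*a^m - B*b^m``; ``A + B = 1``."""
    d = ep.t1 + ep.t2 - ep.t3
    a_num = ep.t1 - ep.t3 + ep.t2 * ep.t3
    b_num = (1.0 - ep.t3) * ep.t2
    return a_num / d, b_num / d, d


def p_infected_given_m(m: int, ep: EdgeProbabilities):
    """Probability the focal node ends infected given ``m`` external
    infected neighbors acting sequentially.

    Closed form ``1 - A (1-T1-T2)^m - B (1-T3)^m`` with
    ``A = (T1-T3+T2*T3)/(T1+T2-T3)`` and ``B = (1-T3)T2/(T1+T2-T3)``.
    When ``T1+T2 ≈ T3`` the removable singularity is replaced by its limit
    ``1 - a^m - (1-T3) T2 m a^(m-1)`` with ``a = 1-T1-T2``.
    """
    m_arr = np.asarray(m)
    if np.any(m_arr < 0):
        raise ParameterError(f"m must be >= 0, got {m!r}")
    a = 1.0 - ep.t1 - ep.t2
    b = 1.0 - ep.t3
    if abs(ep.t1 + ep.t2 - ep.t3) < _DEGENERATE_EPS:
        with np.errstate(divide="ignore", invalid="ignore"):
            lead = np.where(m_arr > 0, m_arr * a ** np.maximum(m_arr - 1, 0), 0.0)
        out = (1.0 - a**m_arr) - b * ep.t2 * lead
    else:
        # written as A(1-a^m) + B(1-b^m) with A + B = 1: exact 0 at m = 0
        coef_a, coef_b, _ = _coefficients(ep)
        out = coef_a * (1.0 - a**m_arr) + coef_b * (1.0 - b**m_arr)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(m) else out


def p_infected_given_k(k: int, theta: float, ep: EdgeProbabilities):
    """Infection probability of a degree-``k`` node when each neighbor is
    externally infected independently with probability ``theta``.

    Equals the binomial mixture ``sum_m C(k,m) theta^m (1-theta)^(k-m)
    p(R|m)``, which collapses to the same two-power closed form with bases
    ``1 - theta*(T1+T2)`` and ``1 - theta*T3``.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 0):
        raise ParameterError(f"k must be >= 0, got {k!r}")
    if not (0.0 <= theta <= 1.0):
        raise ParameterError(f"theta must lie in [0, 1], got {theta}")
    x = 1.0 - theta * (ep.t1 + ep.t2)
    y = 1.0 - theta * ep.t3
    if abs(ep.t1 + ep.t2 - ep.t3) < _DEGENERATE_EPS:
        with np.errstate(divide="ignore", invalid="ignore"):
            lead = np.where(k_arr > 0, k_arr * x ** np.maximum(k_arr - 1, 0), 0.0)
        out = (1.0 - x**k_arr) - (1.0 - ep.t3) * ep.t2 * theta * lead
    else:
        coef_a, coef_b, _ = _coefficients(ep)
        out = coef_a * (1.0 - x**k_arr) + coef_b * (1.0 - y**k_arr)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(k) else out


# ---------------------------------------------------------------------------
# self-consistent theta and final size
# ---------------------------------------------------------------------------

def _g1_prime(dist: DegreeDistribution, x: float) -> float:
    q = dist.excess()
    ks = q.support.astype(float)
    mask = ks >= 1
    return float(np.sum(q.probs[mask] * ks[mask] * x ** (ks[mask] - 1.0)))


def _g0_prime(dist: DegreeDistribution, x: float) -> float:
    ks = dist.support.astype(float)
    mask = ks >= 1
    return float(np.sum(dist.probs[mask] * ks[mask] * x ** (ks[mask] - 1.0)))


def theta_map(theta: float, dist: DegreeDistribution, ep: EdgeProbabilities) -> float:
    """One application of the fixed-point map ``f`` defining ``theta``.

    ``f(theta) = 1 - A g1(1 - theta(T1+T2)) - B g1(1 - theta T3)`` with the
    same removable-singularity handling as the conditional probabilities.
    ``f(0) = 0`` exactly and ``f`` is nondecreasing on [0, 1].
    """
    if theta == 0.0:
        return 0.0
    x = 1.0 - theta * (ep.t1 + ep.t2)
    y = 1.0 - theta * ep.t3
    if abs(ep.t1 + ep.t2 - ep.t3) < _DEGENERATE_EPS:
        val = 1.0 - dist.g1(x) - (1.0 - ep.t3) * ep.t2 * theta * _g1_prime(dist, x)
    else:
        coef_a, coef_b, _ = _coefficients(ep)
        val = coef_a * (1.0 - dist.g1(x)) + coef_b * (1.0 - dist.g1(y))
    return min(max(val, 0.0), 1.0)


def solve_theta(
    dist: DegreeDistribution,
    params: EpidemicParams,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> TheoryResult:
    """Largest fixed point of the self-consistent map on [0, 1].

    Below the outbreak threshold the only fixed point is 0 and it is
    returned exactly.  Above threshold the iteration starts at 1 and
    descends monotonically onto the physical fixed point; Aitken
    extrapolation accelerates the tail.  Non-convergence is flagged on the
    result, never raised.
    """
    ep = edge_probabilities(params)
    outbreak, _ = outbreak_condition(dist, params)
    if not outbreak:
        return TheoryResult(0.0, None, True, 0, 0.0)

    theta = 1.0
    for it in range(1, max_iter + 1):
        f1 = theta_map(theta, dist, ep)
        if abs(f1 - theta) <= tol:
            return TheoryResult(f1, None, True, it, abs(f1 - theta))
        f2 = theta_map(f1, dist, ep)
        denom = f2 - 2.0 * f1 + theta
        nxt = f2
        if abs(denom) > 1e-300:
            accel = theta - (f1 - theta) ** 2 / denom
            if 0.0 <= accel <= 1.0:
                # accept the extrapolation only if it reduces the residual
                if abs(theta_map(accel, dist, ep) - accel) < abs(theta_map(f2, dist, ep) - f2):
                    nxt = accel
        theta = nxt
    residual = abs(theta_map(theta, dist, ep) - theta)
    return TheoryResult(theta, None, residual <= tol, max_iter, residual)


def prevalence(
    dist: DegreeDistribution,
    params: EpidemicParams,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> TheoryResult:
    """Final epidemic size ``R(inf)`` from the solved ``theta``.

    ``R(inf) = 1 - A g0(1 - theta(T1+T2)) - B g0(1 - theta T3)``
    which equals ``sum_k P(k) p(R|k)``.
    """
    res = solve_theta(dist, params, tol=tol, max_iter=max_iter)
    ep = edge_probabilities(params)
    theta = res.theta
    x = 1.0 - theta * (ep.t1 + ep.t2)
    y = 1.0 - theta * ep.t3
    if abs(ep.t1 + ep.t2 - ep.t3) < _DEGENERATE_EPS:
        r_inf = 1.0 - dist.g0(x) - (1.0 - ep.t3) * ep.t2 * theta * _g0_prime(dist, x)
    else:
        coef_a, coef_b, _ = _coefficients(ep)
        r_inf = coef_a * (1.0 - dist.g0(x)) + coef_b * (1.0 - dist.g0(y))
    r_inf = min(max(float(r_inf), 0.0), 1.0)
    return TheoryResult(theta, r_inf, res.converged, res.iterations, res.residual)


def outbreak_condition(
    dist: DegreeDistribution, params: EpidemicParams
) -> tuple[bool, float]:
    """Whether a giant outbreak is possible, plus the signed margin.

    The margin is ``(T1 + T2*T3) * g1'(1) - 1``; positive means
    supercritical.  A distribution with all degrees <= 1 cannot carry a
    giant component: returns ``(False, -inf)``.
    """
    g1p = dist.g1_prime_at_1()
    if g1p <= 0.0:
        return False, float("-inf")
    margin = transmissibility(params) * g1p - 1.0
    return margin > 0.0, margin


def solve_threshold_beta(
    dist: DegreeDistribution,
    beta_f: float,
    gamma: float,
    mu: float,
    bracket: tuple[float, float] | None = None,
) -> float:
    """Critical transmission rate ``beta_c`` by bisection on the margin.

    For a Poisson degree distribution this reduces to
    ``beta (mu + g b + g bf) / ((mu + g b)(mu + b + bf)) = 1/<k>``.
    """
    if bracket is None:
        bracket = (1e-6, 50.0 * mu)
    lo, hi = bracket

    def margin(beta: float) -> float:
        return outbreak_condition(dist, EpidemicParams(beta, beta_f, gamma, mu))[1]

    f_lo, f_hi = margin(lo), margin(hi)
    if not (f_lo < 0.0 < f_hi):
        raise BracketingError(
            f"margin does not change sign on [{lo}, {hi}]: f(lo)={f_lo}, f(hi)={f_hi}",
            f_lo=f_lo,
            f_hi=f_hi,
        )
    return float(brentq(margin, lo, hi, xtol=1e-14, rtol=1e-12))
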