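"""Degree-based (heterogeneous) mean-field ODEs for the four-state model.

Per degree class ``k`` the fractions ``(S_k, F_k, I_k, R_k)`` evolve as

    dS_k/dt = -beta k S_k Theta - beta_f k S_k Theta
    dF_k/dt =  beta_f k S_k Theta - gamma beta k F_k Theta
    dI_k/dt =  k Theta beta (S_k + gamma F_k) - mu I_k
    dR_k/dt =  mu I_k

with the uncorrelated-network coupling
``Theta = sum_k k P(k) I_k / <k>``.  The equations are usually written with
the recovery rate absorbed (``mu = 1``); here ``mu`` multiplies the
recovery terms explicitly so the parameterization matches the simulator.

Linearizing around the disease-free state gives the mean-field threshold
``beta_c = mu <k> / <k^2>`` — independent of ``beta_f`` and ``gamma``,
because the two-step route S -> S^F -> I is second order in the infected
fraction once dynamic correlations are discarded.  This is precisely where
the mean-field closure disagrees with the percolation analysis (whose
threshold does move with ``beta_f`` and ``gamma``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ParameterError
from .networks import DegreeDistribution
from .theory import EpidemicParams

__all__ = [
    "MeanFieldState",
    "MeanFieldTrajectory",
    "mf_rhs",
    "integrate_mf",
    "mf_threshold",
    "mf_liftoff_beta",
]


@dataclass(frozen=True)
class MeanFieldState:
    """Per-degree-class fractions; each of the four arrays is indexed like
    ``dist.support``."""

    s: np.ndarray
    f: np.ndarray
    i: np.ndarray
    r: np.ndarray

    def pack(self) -> np.ndarray:
        return np.concatenate([self.s, self.f, self.i, self.r])

    @staticmethod
    def unpack(y: np.ndarray, n_classes: int) -> "MeanFieldState":
        return MeanFieldState(
            y[:n_classes],
            y[n_classes : 2 * n_classes],
            y[2 * n_classes : 3 * n_classes],
            y[3 * n_classes :],
        )


@dataclass
class MeanFieldTrajectory:
    """Aggregated trajectory and final size of one integration."""

    t: np.ndarray
    s: np.ndarray  # aggregate fractions sum_k P(k) X_k
    f: np.ndarray
    i: np.ndarray
    r: np.ndarray
    r_infinity: float
    success: bool


def coupling_theta(dist: DegreeDistribution, i_k: np.ndarray) -> float:
    """Probability a random edge points at an infected node."""
    ks = dist.support.astype(float)
    return float(np.dot(ks * dist.probs, i_k) / dist.mean)


def mf_rhs(
    state: MeanFieldState, dist: DegreeDistribution, params: EpidemicParams
) -> MeanFieldState:
    """Time derivative of the mean-field state (sums to zero per class)."""
    ks = dist.support.astype(float)
    theta = coupling_theta(dist, state.i)
    ds = -(params.beta + params.beta_f) * ks * state.s * theta
    df = params.beta_f * ks * state.s * theta - params.gamma * params.beta * ks * state.f * theta
    di = ks * theta * params.beta * (state.s + params.gamma * state.f) - params.mu * state.i
    dr = params.mu * state.i
    return MeanFieldState(ds, df, di, dr)


def integrate_mf(
    dist: DegreeDistribution,
    params: EpidemicParams,
    initial_infected_fraction: float = 1e-4,
    t_max: float = 10_000.0,
    tol: float = 1e-10,
    i_extinct: float = 1e-9,
    n_eval: int = 200,
) -> MeanFieldTrajectory:
    """Integrate from a uniform small infected fraction until the aggregate
    infected fraction drops below ``i_extinct`` (or ``t_max``)."""
    if not (0.0 < initial_infected_fraction < 1.0):
        raise ParameterError("initial infected fraction must lie in (0, 1)")
    n_cls = dist.support.size
    eps = initial_infected_fraction
    y0 = np.concatenate(
        [np.full(n_cls, 1.0 - eps), np.zeros(n_cls), np.full(n_cls, eps), np.zeros(n_cls)]
    )

    def rhs(_t, y):
        st = MeanFieldState.unpack(y, n_cls)
        d = mf_rhs(st, dist, params)
        return d.pack()

    def extinct(_t, y):
        i_k = y[2 * n_cls : 3 * n_cls]
        return float(np.dot(dist.probs, i_k)) - i_extinct

    extinct.terminal = True
    extinct.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        y0,
        method="LSODA",
        rtol=tol,
        atol=tol * 1e-2,
        events=extinct,
        dense_output=False,
        t_eval=None,
        max_step=np.inf,
    )
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    st = MeanFieldState.unpack(sol.y[:, -1], n_cls)
    # leftover infections all recover; fold I into R for the final size
    r_inf = float(np.dot(dist.probs, st.r + st.i))
    return MeanFieldTrajectory(
        t=sol.t,
        s=dist.probs @ sol.y[0:n_cls],
        f=dist.probs @ sol.y[n_cls : 2 * n_cls],
        i=dist.probs @ sol.y[2 * n_cls : 3 * n_cls],
        r=dist.probs @ sol.y[3 * n_cls :],
        r_infinity=r_inf,
        success=True,
    )


def mf_threshold(dist: DegreeDistribution, mu: float = 1.0) -> float:
    """Mean-field critical transmission rate ``mu <k> / <k^2>``.

    Independent of the response rate and the discount factor — the closure
    artifact this module exists to exhibit.
    """
    if dist.second_moment <= 0:
        raise ParameterError("<k^2> must be positive")
    return mu * dist.mean / dist.second_moment


def mf_liftoff_beta(
    dist: DegreeDistribution,
    beta_grid,
    beta_f: float,
    gamma: float,
    mu: float = 1.0,
    initial_infected_fraction: float = 1e-4,
    liftoff_factor: float = 10.0,
) -> tuple[float, np.ndarray]:
    """Smallest grid rate whose final size exceeds ``liftoff_factor`` times
    the initial infected fraction; returns it with the full R(inf) curve."""
    betas = np.asarray(beta_grid, dtype=float)
    r_curve = np.empty(betas.size)
    for i, b in enumerate(betas):
        traj = integrate_mf(
            dist,
            EpidemicParams(float(b), beta_f, gamma, mu),
            initial_infected_fraction=initial_infected_fraction,
        )
        r_curve[i] = traj.r_infinity
    above = np.nonzero(r_curve > liftoff_factor * initial_infected_fraction)[0]
    if above.size == 0:
        return float("nan"), r_curve
    return float(betas[above[0]]), r_curve
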