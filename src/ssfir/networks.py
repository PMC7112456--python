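"""Random graphs and degree-distribution calculus.

Two generators are provided: Erdős–Rényi ``G(n, p)`` and the uncorrelated
configuration model (UCM) with a power-law degree sequence truncated at
``floor(sqrt(n))``.  Graphs are simple (no self-loops, no multi-edges),
undirected, with contiguous 0-based node ids, and can be round-tripped
through a plain two-column edge-list text format.

:class:`DegreeDistribution` carries ``P(k)`` together with its excess
distribution ``Q(k) = (k+1) P(k+1) / <k>`` and the generating functions

    g0(x) = sum_k P(k) x^k        g1(x) = sum_k Q(k) x^k

whose derivative at 1, ``g1'(1) = (<k^2> - <k>) / <k>``, is the mean excess
degree used by the percolation threshold condition.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import FormatError, GenerationError, ParameterError

__all__ = [
    "Network",
    "DegreeDistribution",
    "generate_er",
    "generate_ucm",
    "empirical_degree_distribution",
    "g0",
    "g1",
    "g1_prime_at_1",
    "read_edge_list",
    "write_edge_list",
]


class Network:
    """Undirected simple graph with contiguous node ids ``0..n-1``.

    Parameters
    ----------
    n:
        Number of nodes.
    edges:
        Iterable of ``(u, v)`` pairs.  Each undirected edge must appear
        once; self-loops and duplicates raise :class:`ParameterError`.
    """

    __slots__ = ("n", "_edges", "_adj")

    def __init__(self, n: int, edges: Iterable[tuple[int, int]]):
        if n < 1:
            raise ParameterError(f"node count must be >= 1, got {n}")
        self.n = int(n)
        canon: set[tuple[int, int]] = set()
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ParameterError(f"self-loop on node {u}")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ParameterError(f"edge ({u}, {v}) outside 0..{self.n - 1}")
            key = (u, v) if u < v else (v, u)
            if key in canon:
                raise ParameterError(f"duplicate edge ({u}, {v})")
            canon.add(key)
            adj[u].append(v)
            adj[v].append(u)
        self._edges = canon
        self._adj = [np.array(sorted(nbrs), dtype=np.int64) for nbrs in adj]

    # -- basic queries ----------------------------------------------------
    @property
    def node_count(self) -> int:
        return self.n

    @property
    def edge_count(self) -> int:
        return len(self._edges)

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Edges in canonical order (smaller id first, sorted)."""
        return sorted(self._edges)

    def neighbors(self, u: int) -> np.ndarray:
        return self._adj[u]

    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self._adj], dtype=np.int64)

    def mean_degree(self) -> float:
        return 2.0 * self.edge_count / self.n

    def has_edge(self, u: int, v: int) -> bool:
        key = (u, v) if u < v else (v, u)
        return key in self._edges

    def to_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Adjacency in CSR form ``(indptr, indices)`` for the simulator."""
        degs = self.degrees()
        indptr = np.zeros(self.n + 1, dtype=np.int64)
        np.cumsum(degs, out=indptr[1:])
        indices = np.concatenate(self._adj) if self.n else np.empty(0, np.int64)
        return indptr, indices.astype(np.int64)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network(n={self.n}, m={self.edge_count})"


@dataclass(frozen=True)
class DegreeDistribution:
    """A degree distribution ``P(k)`` on finite integer support."""

    support: np.ndarray
    probs: np.ndarray
    _mean: float = field(init=False, repr=False)
    _second: float = field(init=False, repr=False)

    def __post_init__(self):
        ks = np.asarray(self.support, dtype=np.int64)
        ps = np.asarray(self.probs, dtype=np.float64)
        if ks.ndim != 1 or ps.shape != ks.shape:
            raise ParameterError("support and probs must be 1-D and congruent")
        if ks.size == 0:
            raise ParameterError("empty degree distribution")
        if np.any(ks < 0):
            raise ParameterError("degrees must be non-negative")
        if len(np.unique(ks)) != ks.size:
            raise ParameterError("degree support has repeats")
        if np.any(ps < -1e-15):
            raise ParameterError("negative probability mass")
        total = float(ps.sum())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"P(k) sums to {total!r}, not 1")
        order = np.argsort(ks)
        ps = np.clip(ps[order], 0.0, None) / total
        ks = ks[order]
        object.__setattr__(self, "support", ks)
        object.__setattr__(self, "probs", ps)
        object.__setattr__(self, "_mean", float(np.dot(ks, ps)))
        object.__setattr__(self, "_second", float(np.dot(ks.astype(float) ** 2, ps)))

    # -- moments ----------------------------------------------------------
    @property
    def mean(self) -> float:
        """First moment ``<k>``."""
        return self._mean

    @property
    def second_moment(self) -> float:
        """Second moment ``<k^2>``."""
        return self._second

    # -- excess distribution ----------------------------------------------
    def excess(self) -> "DegreeDistribution":
        """Excess degree distribution ``Q(k) = (k+1) P(k+1) / <k>``."""
        if self._mean <= 0:
            raise ParameterError("excess distribution undefined for <k> = 0")
        mask = self.support >= 1
        ks = self.support[mask]
        qs = ks * self.probs[mask] / self._mean
        return DegreeDistribution(ks - 1, qs)

    # -- generating functions ---------------------------------------------
    def g0(self, x) -> float | np.ndarray:
        return g0(self, x)

    def g1(self, x) -> float | np.ndarray:
        return g1(self, x)

    def g1_prime_at_1(self) -> float:
        return g1_prime_at_1(self)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_counts(cls, counts: dict[int, int] | Sequence[int]) -> "DegreeDistribution":
        if isinstance(counts, dict):
            ks = np.array(sorted(counts), dtype=np.int64)
            ns = np.array([counts[k] for k in ks], dtype=np.float64)
        else:
            ns = np.asarray(counts, dtype=np.float64)
            ks = np.arange(ns.size, dtype=np.int64)
        total = ns.sum()
        if total <= 0:
            raise ParameterError("no mass in degree counts")
        mask = ns > 0
        return cls(ks[mask], ns[mask] / total)

    @classmethod
    def poisson(cls, mean: float, tail_sigmas: float = 10.0) -> "DegreeDistribution":
        """Truncated Poisson; tail mass beyond ``mean + tail_sigmas*sd`` dropped."""
        if mean <= 0:
            raise ParameterError("Poisson mean must be positive")
        from scipy.stats import poisson as _poisson

        k_max = int(math.ceil(mean + tail_sigmas * math.sqrt(mean))) + 1
        ks = np.arange(0, k_max + 1)
        ps = _poisson.pmf(ks, mean)
        return cls(ks, ps / ps.sum())

    @classmethod
    def power_law(cls, exponent: float, k_min: int, k_max: int) -> "DegreeDistribution":
        """``P(k) ∝ k^-exponent`` on ``[k_min, k_max]``."""
        if k_min < 1 or k_max < k_min:
            raise ParameterError("need 1 <= k_min <= k_max")
        ks = np.arange(k_min, k_max + 1)
        w = ks.astype(float) ** (-float(exponent))
        return cls(ks, w / w.sum())

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# k\tP(k)\n")
            for k, p in zip(self.support, self.probs):
                fh.write(f"{k}\t{p:.17g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DegreeDistribution":
        ks, ps = [], []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                k, p = line.split()
                ks.append(int(k))
                ps.append(float(p))
        return cls(np.array(ks), np.array(ps))


# ---------------------------------------------------------------------------
# generating-function calculus (module-level functional forms)
# ---------------------------------------------------------------------------

def _check_unit_interval(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ParameterError(f"argument must lie in [0, 1], got {x!r}")
    return arr


def g0(dist: DegreeDistribution, x) -> float | np.ndarray:
    """Degree generating function ``sum_k P(k) x^k``; ``g0(1) = 1``."""
    arr = _check_unit_interval(x)
    out = np.power.outer(arr, dist.support.astype(np.float64)) @ dist.probs
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def g1(dist: DegreeDistribution, x) -> float | np.ndarray:
    """Excess-degree generating function ``sum_k Q(k) x^k``; ``g1(1) = 1``."""
    if dist.mean <= 0:
        raise ParameterError("g1 undefined for <k> = 0")
    arr = _check_unit_interval(x)
    q = dist.excess()
    out = np.power.outer(arr, q.support.astype(np.float64)) @ q.probs
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def g1_prime_at_1(dist: DegreeDistribution) -> float:
    """Mean excess degree ``g1'(1) = (<k^2> - <k>) / <k>``."""
    if dist.mean <= 0:
        raise ParameterError("g1'(1) undefined for <k> = 0")
    return (dist.second_moment - dist.mean) / dist.mean


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _as_seed_int(seed) -> int:
    """Collapse any RNG-like seed into a plain int for networkx."""
    if seed is None:
        return int(np.random.SeedSequence().generate_state(1)[0])
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(0, 2**31 - 1))
    return int(seed)


def generate_er(n: int, mean_degree: float, seed=None) -> Network:
    """Erdős–Rényi ``G(n, p)`` with ``p = mean_degree / (n - 1)``."""
    if n < 2:
        raise ParameterError(f"need n >= 2, got {n}")
    if not (0 < mean_degree < n - 1 + 1e-12):
        raise ParameterError(f"need 0 < mean_degree < n-1, got {mean_degree}")
    p = min(mean_degree / (n - 1), 1.0)
    g = nx.fast_gnp_random_graph(n, p, seed=_as_seed_int(seed))
    return Network(n, g.edges())


def _sample_degree_sequence(
    n: int, exponent: float, k_min: int, k_max: int, rng: np.random.Generator
) -> np.ndarray:
    dist = DegreeDistribution.power_law(exponent, k_min, k_max)
    degs = rng.choice(dist.support, size=n, p=dist.probs)
    # parity fix: resample a single node until the stub count is even
    while degs.sum() % 2 != 0:
        degs[rng.integers(n)] = rng.choice(dist.support, p=dist.probs)
    return degs.astype(np.int64)


def generate_ucm(
    n: int,
    exponent: float,
    k_min: int,
    seed=None,
    max_restarts: int = 100,
) -> Network:
    """Uncorrelated configuration model with ``P(k) ∝ k^-exponent``.

    Degrees are drawn on ``[k_min, floor(sqrt(n))]``; the cutoff suppresses
    degree-degree correlations.  Stubs are matched by repeated random
    pairing; pairs that would create a self-loop or multi-edge are rejected,
    and a stalled matching is restarted from scratch (``max_restarts``
    attempts before :class:`GenerationError`).
    """
    if exponent <= 2:
        raise ParameterError(f"need exponent > 2, got {exponent}")
    if not (2 <= k_min < math.sqrt(n)):
        raise ParameterError(f"need 2 <= k_min < sqrt(n), got k_min={k_min}, n={n}")
    k_max = int(math.isqrt(n))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    for attempt in range(1, max_restarts + 1):
        degs = _sample_degree_sequence(n, exponent, k_min, k_max, rng)
        edges = _match_stubs(degs, rng)
        if edges is not None:
            return Network(n, edges)
    raise GenerationError(
        f"no simple stub matching after {max_restarts} restarts", attempts=max_restarts
    )


def _match_stubs(degs: np.ndarray, rng: np.random.Generator):
    """Random stub pairing with rejection; None when the matching deadlocks."""
    stubs = np.repeat(np.arange(degs.size), degs)
    rng.shuffle(stubs)
    stubs = list(stubs)
    edges: set[tuple[int, int]] = set()
    failures = 0
    max_failures = max(2000, 50 * len(stubs))
    while stubs:
        n_left = len(stubs)
        i = int(rng.integers(n_left))
        j = int(rng.integers(n_left - 1))
        if j >= i:
            j += 1
        u, v = int(stubs[i]), int(stubs[j])
        key = (u, v) if u < v else (v, u)
        if u == v or key in edges:
            failures += 1
            if failures > max_failures:
                return None
            continue
        edges.add(key)
        for idx in sorted((i, j), reverse=True):
            stubs[idx] = stubs[-1]
            stubs.pop()
    return edges


def empirical_degree_distribution(net: Network) -> DegreeDistribution:
    """``P(k)`` = fraction of nodes with degree ``k`` in the realized graph."""
    if net.n < 1:
        raise ParameterError("empty network")
    degs = net.degrees()
    counts = np.bincount(degs)
    return DegreeDistribution.from_counts(list(counts))


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> Network:
    """Read a whitespace-separated two-column edge list ('#' comments).

    Node count is ``max id + 1``; ids must be non-negative integers.  A
    self-loop or repeated edge raises :class:`FormatError` naming the line.
    """
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    max_id = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"line {lineno}: expected two columns, got {raw.rstrip()!r}",
                    line=lineno,
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer node id", line=lineno) from exc
            if u < 0 or v < 0:
                raise FormatError(f"line {lineno}: negative node id", line=lineno)
            if u == v:
                raise FormatError(f"line {lineno}: self-loop on node {u}", line=lineno)
            key = (u, v) if u < v else (v, u)
            if key in seen:
                raise FormatError(f"line {lineno}: duplicate edge ({u}, {v})", line=lineno)
            seen.add(key)
            edges.append(key)
            max_id = max(max_id, u, v)
    if max_id < 0:
        raise FormatError("edge list contains no edges")
    return Network(max_id + 1, edges)


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write canonical form: one edge per line, smaller id first, sorted."""
    buf = io.StringIO()
    for u, v in net.edges:
        buf.write(f"{u} {v}\n")
    Path(path).write_text(buf.getvalue())
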