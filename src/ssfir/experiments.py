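"""Config-driven experiment pipelines behind the command-line interface.

Each pipeline is fully determined by ``(config, master seed)``: graph
generation, ensemble seeds and output files are all derived from the one
seed, and floats are written with 10 significant digits so reruns are
byte-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from .errors import BracketingError, ConfigError
from .meanfield import mf_liftoff_beta, mf_threshold
from .networks import (
    DegreeDistribution,
    Network,
    empirical_degree_distribution,
    generate_er,
    generate_ucm,
    read_edge_list,
    write_edge_list,
)
from .simulate import run_ensemble, threshold_by_delta_peak
from .theory import EpidemicParams, prevalence, outbreak_condition, solve_threshold_beta

log = logging.getLogger("ssfir")

_NETWORK_KEYS = {"type", "n", "mean_degree", "exponent", "k_min", "path"}
_PARAM_KEYS = {"beta_grid", "beta_f", "gamma", "mu"}
_ENSEMBLE_KEYS = {"n_realizations", "initial_infected", "outbreak_cutoff"}
_MF_KEYS = {"initial_infected_fraction", "liftoff_factor"}
_TOP_KEYS = {"network", "params", "ensemble", "meanfield"}

DEFAULT_CONFIG = {
    "network": {"type": "er", "n": 10_000, "mean_degree": 10.0},
    "params": {"beta_grid": [0.05, 0.45, 0.05], "beta_f": [0.0], "gamma": [0.1], "mu": 1.0},
    "ensemble": {"n_realizations": 1000, "initial_infected": 1, "outbreak_cutoff": 0.05},
    "meanfield": {"initial_infected_fraction": 1e-4, "liftoff_factor": 10.0},
}


def _fmt(x: float) -> str:
    return f"{float(x):.10g}"


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    bad = sorted(set(section) - allowed)
    if bad:
        raise ConfigError(f"unknown keys in {where}: {bad}", keys=bad)


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config, validate its schema and fill in defaults."""
    cfg = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "config")
    merged = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for sec, allowed in [
        ("network", _NETWORK_KEYS),
        ("params", _PARAM_KEYS),
        ("ensemble", _ENSEMBLE_KEYS),
        ("meanfield", _MF_KEYS),
    ]:
        if sec in cfg:
            if not isinstance(cfg[sec], dict):
                raise ConfigError(f"section {sec!r} must be a mapping", keys=[sec])
            _check_keys(cfg[sec], allowed, sec)
            merged[sec].update(cfg[sec])
    return merged


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def beta_values(cfg: dict) -> np.ndarray:
    spec = cfg["params"]["beta_grid"]
    if isinstance(spec, (list, tuple)) and len(spec) == 3 and all(
        isinstance(v, (int, float)) for v in spec
    ):
        start, stop, step = map(float, spec)
        n = int(round((stop - start) / step)) + 1
        return np.round(start + step * np.arange(n), 12)
    return np.asarray([float(v) for v in spec])


def build_network(cfg: dict, rng: np.random.Generator) -> Network:
    net_cfg = cfg["network"]
    kind = net_cfg.get("type", "er")
    if kind == "er":
        return generate_er(int(net_cfg["n"]), float(net_cfg["mean_degree"]), seed=rng)
    if kind == "ucm":
        return generate_ucm(
            int(net_cfg["n"]), float(net_cfg["exponent"]), int(net_cfg["k_min"]), seed=rng
        )
    if kind == "edgelist":
        return read_edge_list(net_cfg["path"])
    raise ConfigError(f"unknown network type {kind!r}", keys=["type"])


def ideal_distribution(cfg: dict) -> DegreeDistribution:
    """The nominal degree distribution of the configured network family."""
    net_cfg = cfg["network"]
    if net_cfg["type"] == "er":
        return DegreeDistribution.poisson(float(net_cfg["mean_degree"]))
    if net_cfg["type"] == "ucm":
        n = int(net_cfg["n"])
        return DegreeDistribution.power_law(
            float(net_cfg["exponent"]), int(net_cfg["k_min"]), int(np.sqrt(n))
        )
    raise ConfigError("ideal distribution undefined for edge-list networks")


def _param_combos(cfg: dict):
    p = cfg["params"]
    for bf in p["beta_f"]:
        for g in p["gamma"]:
            yield float(bf), float(g)


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        log.info("stage %s finished in %.2f s", self.name, time.perf_counter() - self.t0)


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def cmd_net(cfg: dict, seed: int, out_dir: Path) -> dict:
    """Generate the configured network; write edge list and degree TSV."""
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    with _Stage("net"):
        net = build_network(cfg, rng)
        write_edge_list(net, out_dir / "network.edges")
        empirical_degree_distribution(net).to_tsv(out_dir / "degree_distribution.tsv")
    info = {
        "n": net.n,
        "edges": net.edge_count,
        "mean_degree": net.mean_degree(),
        "seed": seed,
        "config_hash": config_hash(cfg),
    }
    (out_dir / "network.json").write_text(json.dumps(info, indent=2) + "\n")
    return info


def cmd_theory(cfg: dict, seed: int, out_dir: Path, dist: DegreeDistribution | None = None) -> dict:
    """Percolation sweep: theta/prevalence per grid point plus thresholds."""
    out_dir.mkdir(parents=True, exist_ok=True)
    if dist is None:
        dist = ideal_distribution(cfg)
    mu = float(cfg["params"]["mu"])
    betas = beta_values(cfg)
    rows = []
    thresholds = []
    with _Stage("theory"):
        for bf, g in _param_combos(cfg):
            for b in betas:
                params = EpidemicParams(float(b), bf, g, mu)
                res = prevalence(dist, params)
                _, margin = outbreak_condition(dist, params)
                rows.append((b, bf, g, mu, res.theta, res.prevalence, margin))
            try:
                beta_c = solve_threshold_beta(dist, bf, g, mu)
            except BracketingError as exc:
                log.warning("no threshold in bracket for beta_f=%s gamma=%s: %s", bf, g, exc)
                beta_c = float("nan")
            thresholds.append({"beta_f": bf, "gamma": g, "mu": mu, "beta_c": beta_c})
    sweep = out_dir / "theory_sweep.csv"
    with open(sweep, "w") as fh:
        fh.write("beta,beta_f,gamma,mu,theta,prevalence,margin\n")
        for row in rows:
            fh.write(",".join(_fmt(v) for v in row) + "\n")
    (out_dir / "thresholds.json").write_text(json.dumps(thresholds, indent=2) + "\n")
    return {"sweep": str(sweep), "thresholds": thresholds}


def cmd_simulate(cfg: dict, seed: int, out_dir: Path) -> dict:
    """Monte-Carlo sweep: mean final size and variability per grid point."""
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    mu = float(cfg["params"]["mu"])
    n_real = int(cfg["ensemble"]["n_realizations"])
    n_seed = cfg["ensemble"]["initial_infected"]
    cutoff = float(cfg["ensemble"]["outbreak_cutoff"])
    betas = beta_values(cfg)
    with _Stage("network"):
        net = build_network(cfg, rng)
    rows = []
    real_rows = []
    with _Stage("ensembles"):
        for bf, g in _param_combos(cfg):
            for b in betas:
                params = EpidemicParams(float(b), bf, g, mu)
                ens = run_ensemble(net, params, n_real, initial_infected=n_seed, rng=rng)
                rows.append(
                    (b, bf, g, ens.mean_rho, ens.outbreak_mean(cutoff), ens.delta, n_real)
                )
                for j in range(ens.realization_count):
                    real_rows.append(
                        (b, bf, g, ens.seed_nodes[j], ens.rho_values[j],
                         ens.sf_values[j], ens.extinction_times[j])
                    )
    sweep = out_dir / "simulation_sweep.csv"
    with open(sweep, "w") as fh:
        fh.write("beta,beta_f,gamma,mean_rho,outbreak_mean_rho,delta,n_realizations\n")
        for row in rows:
            fh.write(",".join(_fmt(v) for v in row) + "\n")
    with open(out_dir / "realizations.csv", "w") as fh:
        fh.write("beta,beta_f,gamma,seed_node,rho,sf_fraction,extinction_time\n")
        for row in real_rows:
            fh.write(",".join(_fmt(v) for v in row) + "\n")
    summary = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "n": net.n,
        "mean_degree": net.mean_degree(),
        "n_realizations": n_real,
        "outbreak_cutoff": cutoff,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {"sweep": str(sweep), "summary": summary}


def cmd_meanfield(cfg: dict, seed: int, out_dir: Path) -> dict:
    """Mean-field final-size sweep with the liftoff point per parameter set."""
    out_dir.mkdir(parents=True, exist_ok=True)
    dist = ideal_distribution(cfg)
    mu = float(cfg["params"]["mu"])
    betas = beta_values(cfg)
    eps = float(cfg["meanfield"]["initial_infected_fraction"])
    factor = float(cfg["meanfield"]["liftoff_factor"])
    rows = []
    liftoffs = []
    with _Stage("meanfield"):
        for bf, g in _param_combos(cfg):
            lift, curve = mf_liftoff_beta(
                dist, betas, bf, g, mu, initial_infected_fraction=eps, liftoff_factor=factor
            )
            liftoffs.append(
                {"beta_f": bf, "gamma": g, "liftoff_beta": lift, "mf_threshold": mf_threshold(dist, mu)}
            )
            for b, r in zip(betas, curve):
                rows.append((b, bf, g, r))
    sweep = out_dir / "meanfield_sweep.csv"
    with open(sweep, "w") as fh:
        fh.write("beta,beta_f,gamma,r_infinity\n")
        for row in rows:
            fh.write(",".join(_fmt(v) for v in row) + "\n")
    (out_dir / "meanfield_liftoff.json").write_text(json.dumps(liftoffs, indent=2) + "\n")
    return {"sweep": str(sweep), "liftoffs": liftoffs}


def cmd_compare(cfg: dict, seed: int, out_dir: Path) -> dict:
    """Three-way comparison: simulation vs percolation theory vs mean-field
    on the shared transmission-rate grid, plus all threshold estimates."""
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    mu = float(cfg["params"]["mu"])
    n_real = int(cfg["ensemble"]["n_realizations"])
    cutoff = float(cfg["ensemble"]["outbreak_cutoff"])
    betas = beta_values(cfg)
    with _Stage("network"):
        net = build_network(cfg, rng)
        dist = empirical_degree_distribution(net)
    ideal = ideal_distribution(cfg)
    eps = float(cfg["meanfield"]["initial_infected_fraction"])

    rows = []
    thresholds = []
    with _Stage("compare"):
        for bf, g in _param_combos(cfg):
            _, mf_curve = mf_liftoff_beta(ideal, betas, bf, g, mu, initial_infected_fraction=eps)
            mf_lift, _ = mf_liftoff_beta(ideal, betas, bf, g, mu, initial_infected_fraction=eps)
            sim_deltas = []
            for i, b in enumerate(betas):
                params = EpidemicParams(float(b), bf, g, mu)
                ens = run_ensemble(
                    net, params, n_real, initial_infected=cfg["ensemble"]["initial_infected"], rng=rng
                )
                theo = prevalence(dist, params)
                sim_deltas.append(ens.delta)
                rows.append(
                    (b, bf, g, ens.mean_rho, ens.outbreak_mean(cutoff), ens.delta,
                     theo.prevalence, mf_curve[i])
                )
            try:
                beta_c = solve_threshold_beta(dist, bf, g, mu)
            except BracketingError:
                beta_c = float("nan")
            peak = int(np.nanargmax(sim_deltas))
            thresholds.append(
                {
                    "beta_f": bf,
                    "gamma": g,
                    "percolation_beta_c": beta_c,
                    "delta_peak_beta": float(betas[peak]),
                    "meanfield_threshold": mf_threshold(ideal, mu),
                    "meanfield_liftoff": mf_lift,
                }
            )
    table = out_dir / "compare.csv"
    with open(table, "w") as fh:
        fh.write(
            "beta,beta_f,gamma,sim_mean_rho,sim_outbreak_mean_rho,sim_delta,"
            "theory_r_infinity,meanfield_r_infinity\n"
        )
        for row in rows:
            fh.write(",".join(_fmt(v) for v in row) + "\n")
    (out_dir / "compare_thresholds.json").write_text(json.dumps(thresholds, indent=2) + "\n")
    return {"table": str(table), "thresholds": thresholds}
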