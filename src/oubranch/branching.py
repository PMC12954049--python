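"""Birth-death branching simulation and phenotype-coupled lineage networks.

Two demographic layers share one rate model:

* a constant-rate linear birth-death process with per-capita division rate
  ``b`` and death rate ``d`` (exact Gillespie simulation), and
* a phenotype-coupled clone-level process in which every extant clone carries
  an OU-evolving trait ``Y`` and divides/dies with rates

      lambda(Y) = lambda0 * exp(alpha * (Y - mu_ref))
      delta(Y)  = delta0  * exp(-beta * (Y - mu_ref)),

  clipped to ``[0, rate_cap]`` for numerical stability.  The clone-level
  simulation is time-stepped: per step each extant clone performs one exact
  OU transition, then divides with probability ``1 - exp(-lambda dt)`` and
  dies with probability ``1 - exp(-delta dt)`` (death resolved after
  division, so a clone can leave a child in its final step).  Children
  inherit the parent's current trait (optionally plus Normal jitter).

The resulting rooted forest — clones with birth/death times, trait paths and
per-edge division rates — is the lineage network; clones are classified
extant/extinct at a snapshot time (default t = 20).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .ou import OUParams

log = logging.getLogger(__name__)

__all__ = [
    "BranchingConfig",
    "LineageNetwork",
    "phenotype_rates",
    "simulate_constant_bd",
    "constant_bd_ensemble",
    "simulate_lineage_network",
    "snapshot_classification",
    "downsample_extant",
    "export_network",
]


@dataclass(frozen=True)
class BranchingConfig:
    """Rates and run controls for the clone-level birth-death simulation.

    ``lambda0``/``delta0`` double as the constant-rate aliases ``b``/``d``
    (the defaults 0.05/0.04 with 40 founders); ``alpha``/``beta`` couple the
    trait deviation ``Y - mu_ref`` to division and death.
    """

    lambda0: float = 0.05
    delta0: float = 0.04
    alpha: float = 0.0
    beta: float = 0.0
    mu_ref: float = 0.0
    rate_cap: float = 10.0
    n0: int = 40
    t_max: float = 40.0
    dt: float = 0.05
    n_cap: int = 100_000
    inheritance_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda0 < 0 or self.delta0 < 0:
            raise ValueError("baseline rates must be >= 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("couplings alpha, beta must be >= 0")
        if self.rate_cap <= 0:
            raise ValueError("rate_cap must be > 0")
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if not (0 < self.dt <= self.t_max):
            raise ValueError("need 0 < dt <= t_max")


@dataclass
class LineageNetwork:
    """Rooted forest of clones from one branching run.

    Arrays are indexed by node id 0..n-1: ``parent`` is -1 for founders,
    ``death`` is NaN for clones still alive at ``t_end``; ``lam_at_birth`` is
    the parent's instantaneous division rate when the edge was created (NaN
    for founders).  ``paths`` optionally maps node id to its sampled
    ``(times, Y)`` trait path.
    """

    parent: np.ndarray
    birth: np.ndarray
    death: np.ndarray
    y_birth: np.ndarray
    y_final: np.ndarray
    lam_at_birth: np.ndarray
    snapshot_time: float
    seed: int
    t_end: float
    t_max: float
    truncated: bool = False
    node_ids: np.ndarray | None = None
    paths: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.node_ids is None:
            self.node_ids = np.arange(self.parent.size)

    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    def population_size(self, t: float) -> int:
        """Number of clones alive at time t (born, not yet dead)."""
        alive = (self.birth <= t) & (np.isnan(self.death) | (self.death > t))
        return int(alive.sum())

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        extant, extinct = snapshot_classification(self, self.snapshot_time)
        extant, extinct = set(extant), set(extinct)
        for i in range(self.n_nodes):
            status = (
                "extant" if i in extant else "extinct" if i in extinct else "unborn"
            )
            g.add_node(
                int(self.node_ids[i]),
                birth=float(self.birth[i]),
                death=float(self.death[i]) if not np.isnan(self.death[i]) else -1.0,
                phenotype=float(self.y_final[i]),
                phenotype_at_birth=float(self.y_birth[i]),
                status=status,
            )
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                g.add_edge(
                    int(self.node_ids[p]),
                    int(self.node_ids[i]),
                    division_rate=float(self.lam_at_birth[i]),
                )
        return g


def phenotype_rates(
    Y: float | np.ndarray, config: BranchingConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Clipped division/death rates at trait value(s) ``Y``."""
    dev = np.asarray(Y, dtype=float) - config.mu_ref
    with np.errstate(over="ignore"):
        lam = config.lambda0 * np.exp(config.alpha * dev)
        dlt = config.delta0 * np.exp(-config.beta * dev)
    lam = np.clip(lam, 0.0, config.rate_cap)
    dlt = np.clip(dlt, 0.0, config.rate_cap)
    return lam, dlt


def simulate_constant_bd(
    b: float,
    d: float,
    n0: int,
    t_max: float,
    seed: int | np.random.Generator = 0,
    size_cap: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact (Gillespie) linear birth-death realization.

    Returns event times and population sizes, starting with ``(0, n0)``.
    Stops at extinction, ``t_max``, or ``size_cap`` (if given).
    """
    if b < 0 or d < 0:
        raise ValueError("rates must be >= 0")
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    rng = np.random.default_rng(seed)
    t, n = 0.0, int(n0)
    times, sizes = [t], [n]
    p_birth = b / (b + d) if (b + d) > 0 else 0.0
    while n > 0 and (size_cap is None or n < size_cap):
        total = (b + d) * n
        if total == 0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        n += 1 if rng.random() < p_birth else -1
        times.append(t)
        sizes.append(n)
    return np.asarray(times), np.asarray(sizes)


def constant_bd_ensemble(
    b: float,
    d: float,
    n0: int,
    n_runs: int,
    seed: int | np.random.Generator = 0,
    t_max: float = np.inf,
    size_cap: int | None = None,
) -> dict:
    """Vectorized ensemble of Gillespie birth-death runs.

    Each run advances event-by-event (all active runs in lockstep) until
    extinction, ``t_max`` or ``size_cap``.  Returns final sizes (the size at
    ``t_max`` for runs stopped by the horizon), extinction flags and stop
    times.  Used for ensemble statistics where storing every trajectory is
    wasteful.
    """
    rng = np.random.default_rng(seed)
    n = np.full(n_runs, int(n0), dtype=np.int64)
    t = np.zeros(n_runs)
    active = np.ones(n_runs, dtype=bool)
    p_birth = b / (b + d) if (b + d) > 0 else 0.0
    while active.any():
        idx = np.nonzero(active)[0]
        rate = (b + d) * n[idx]
        waits = rng.exponential(1.0, size=idx.size) / rate
        t_new = t[idx] + waits
        over = t_new > t_max
        # horizon reached before the next event: freeze the pre-event size
        stop = idx[over]
        t[stop] = t_max
        active[stop] = False
        go = idx[~over]
        if go.size == 0:
            continue
        t[go] = t_new[~over]
        births = rng.random(go.size) < p_birth
        n[go] += np.where(births, 1, -1)
        dead = go[n[go] == 0]
        active[dead] = False
        if size_cap is not None:
            capped = go[n[go] >= size_cap]
            active[capped] = False
    return {"final_size": n, "extinct": n == 0, "stop_time": t}


def simulate_lineage_network(
    ou: OUParams,
    config: BranchingConfig,
    seed: int | np.random.Generator = 0,
    snapshot_time: float = 20.0,
    y0: float | None = None,
    record_paths: bool = True,
    path_stride: int = 1,
) -> LineageNetwork:
    """Time-stepped phenotype-coupled birth-death lineage simulation.

    Founders start at ``y0`` (default ``ou.mu``).  Per step of length
    ``config.dt`` every extant clone updates its trait by one exact OU
    transition, divides with probability ``1 - exp(-lambda(Y) dt)`` and dies
    with probability ``1 - exp(-delta(Y) dt)``; events within a step resolve
    death after division.  The run stops at ``t_max``, extinction, or the
    population cap (``truncated`` flag, not an error).
    """
    if config.lambda0 * config.dt > 0.2:
        log.warning(
            "lambda0*dt = %.3g > 0.2: at most one division per clone per step, "
            "consider a smaller dt", config.lambda0 * config.dt,
        )
    rng = np.random.default_rng(seed)
    seed_val = int(seed) if np.isscalar(seed) else -1
    dt = config.dt
    e_dt = math.exp(-ou.theta * dt)
    sd_dt = math.sqrt(ou.stationary_variance * (1.0 - e_dt * e_dt))
    y_start = ou.mu if y0 is None else float(y0)

    parent = [-1] * config.n0
    birth = [0.0] * config.n0
    death: list[float] = [math.nan] * config.n0
    yb = [y_start] * config.n0
    lam_birth = [math.nan] * config.n0
    alive = list(range(config.n0))
    y_alive = np.full(config.n0, y_start, dtype=float)
    path_t: dict[int, list] = {}
    path_y: dict[int, list] = {}
    if record_paths:
        for i in alive:
            path_t[i] = [0.0]
            path_y[i] = [y_start]

    n_steps = int(round(config.t_max / dt))
    truncated = False
    t = 0.0
    step = 0
    while step < n_steps and alive:
        step += 1
        t = step * dt
        n_alive = len(alive)
        y_alive = ou.mu + (y_alive - ou.mu) * e_dt + sd_dt * rng.standard_normal(
            n_alive
        )
        lam, dlt = phenotype_rates(y_alive, config)
        u = rng.random((n_alive, 2))
        divide = u[:, 0] < -np.expm1(-lam * dt)
        die = u[:, 1] < -np.expm1(-dlt * dt)
        # divisions first: a dying clone can still leave a child this step
        new_ids = []
        for j in np.nonzero(divide)[0]:
            cid = len(parent)
            parent.append(alive[j])
            birth.append(t)
            death.append(math.nan)
            child_y = y_alive[j]
            if config.inheritance_jitter_sd > 0:
                child_y += config.inheritance_jitter_sd * rng.standard_normal()
            yb.append(float(child_y))
            lam_birth.append(float(lam[j]))
            new_ids.append((cid, child_y))
        for j in np.nonzero(die)[0]:
            death[alive[j]] = t
        keep = ~die
        alive = [alive[j] for j in np.nonzero(keep)[0]]
        y_alive = y_alive[keep]
        if new_ids:
            alive.extend(cid for cid, _ in new_ids)
            y_alive = np.concatenate(
                [y_alive, np.array([cy for _, cy in new_ids])]
            )
        if record_paths and step % path_stride == 0:
            for idx, cid in enumerate(alive):
                path_t.setdefault(cid, []).append(t)
                path_y.setdefault(cid, []).append(float(y_alive[idx]))
        if len(alive) >= config.n_cap:
            truncated = True
            log.warning("population cap %d reached at t=%.2f", config.n_cap, t)
            break

    y_final = np.array(yb, dtype=float)
    for idx, cid in enumerate(alive):
        y_final[cid] = y_alive[idx]
    if record_paths:
        for cid in path_t:
            y_final[cid] = path_y[cid][-1]
    paths = (
        {
            cid: (np.asarray(path_t[cid]), np.asarray(path_y[cid]))
            for cid in path_t
        }
        if record_paths
        else {}
    )
    return LineageNetwork(
        parent=np.asarray(parent, dtype=np.int64),
        birth=np.asarray(birth, dtype=float),
        death=np.asarray(death, dtype=float),
        y_birth=np.asarray(yb, dtype=float),
        y_final=y_final,
        lam_at_birth=np.asarray(lam_birth, dtype=float),
        snapshot_time=snapshot_time,
        seed=seed_val,
        t_end=t,
        t_max=config.t_max,
        truncated=truncated,
        paths=paths,
    )


def snapshot_classification(
    net: LineageNetwork, t_snap: float
) -> tuple[np.ndarray, np.ndarray]:
    """Clone ids extant / extinct at the snapshot time (unborn excluded)."""
    if t_snap > net.t_max:
        raise ValueError(f"snapshot time {t_snap} exceeds t_max {net.t_max}")
    born = net.birth <= t_snap
    dead_by = ~np.isnan(net.death) & (net.death <= t_snap)
    extant = np.nonzero(born & ~dead_by)[0]
    extinct = np.nonzero(dead_by)[0]
    return extant, extinct


def downsample_extant(
    net: LineageNetwork,
    max_nodes: int = 2000,
    seed: int | np.random.Generator = 0,
) -> LineageNetwork:
    """Visualization view keeping at most ``max_nodes`` extant clones.

    If the extant count exceeds the cap, a uniform seeded subset of extant
    nodes is kept, together with each kept node's ancestor path so the view
    stays a connected forest.  The underlying network is untouched; node ids
    in the view refer to the original network.
    """
    if max_nodes < 1:
        raise ValueError("max_nodes must be >= 1")
    extant, _ = snapshot_classification(net, net.snapshot_time)
    if extant.size <= max_nodes:
        return net
    rng = np.random.default_rng(seed)
    chosen = rng.choice(extant, size=max_nodes, replace=False)
    keep = set()
    for cid in chosen:
        node = int(cid)
        while node >= 0 and node not in keep:
            keep.add(node)
            node = int(net.parent[node])
    order = np.array(sorted(keep), dtype=np.int64)
    remap = {old: new for new, old in enumerate(order)}
    new_parent = np.array(
        [remap.get(int(net.parent[i]), -1) for i in order], dtype=np.int64
    )
    return LineageNetwork(
        parent=new_parent,
        birth=net.birth[order],
        death=net.death[order],
        y_birth=net.y_birth[order],
        y_final=net.y_final[order],
        lam_at_birth=net.lam_at_birth[order],
        snapshot_time=net.snapshot_time,
        seed=net.seed,
        t_end=net.t_end,
        t_max=net.t_max,
        truncated=net.truncated,
        node_ids=net.node_ids[order],
        paths={int(i): net.paths[int(i)] for i in order if int(i) in net.paths},
    )


def export_network(
    net: LineageNetwork, path: str | Path, format: str = "graphml"
) -> Path:
    """Write a lineage network as GraphML, an edge-list table, or JSON."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif format == "edgelist":
        rows = [
            {
                "parent": int(net.node_ids[net.parent[i]]),
                "child": int(net.node_ids[i]),
                "division_rate": float(net.lam_at_birth[i]),
            }
            for i in range(net.n_nodes)
            if net.parent[i] >= 0
        ]
        pd.DataFrame(rows, columns=["parent", "child", "division_rate"]).to_csv(
            path, index=False
        )
    elif format == "json":
        extant, extinct = snapshot_classification(net, net.snapshot_time)
        extant, extinct = set(extant.tolist()), set(extinct.tolist())
        nodes = [
            {
                "id": int(net.node_ids[i]),
                "parent": int(net.node_ids[net.parent[i]]) if net.parent[i] >= 0 else None,
                "birth": float(net.birth[i]),
                "death": None if np.isnan(net.death[i]) else float(net.death[i]),
                "phenotype": float(net.y_final[i]),
                "status": "extant" if i in extant else "extinct" if i in extinct else "unborn",
            }
            for i in range(net.n_nodes)
        ]
        payload = {
            "snapshot_time": net.snapshot_time,
            "seed": net.seed,
            "truncated": net.truncated,
            "nodes": nodes,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
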