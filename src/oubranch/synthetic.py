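"""Seeded generator of LTEE-like replicate mutation-frequency panels.

Real long-term evolution experiment (LTEE) panels are replicate
mutation-frequency time series per lineage; this module emulates their
structure with known ground truth so that inference, separation and
simulation code can be exercised end to end: per lineage and replicate an OU
path is simulated exactly on the log10 scale, mapped back to frequencies
``x = 10^y``, and observations below a detection floor are recorded as exact
zeros (the field's "not detected" convention).

Default lineage parameters are the three reference profiles used throughout
the package — WT (-6.799, 0.775, 0.727), priA (-5.000, 0.117, 0.436) and
recG (-7.652, 8.516, 2.789) — with 5 replicates on the sparse grid
t = 0, 3, ..., 21 and a 1e-8 detection floor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ou import OUParams, simulate_exact

__all__ = ["DEFAULT_LINEAGES", "SyntheticPanelSpec", "generate_panel", "fixture_bundle"]

DEFAULT_LINEAGES: tuple[tuple[str, OUParams], ...] = (
    ("WT", OUParams(mu=-6.799, theta=0.775, sigma=0.727)),
    ("priA", OUParams(mu=-5.000, theta=0.117, sigma=0.436)),
    ("recG", OUParams(mu=-7.652, theta=8.516, sigma=2.789)),
)


def _default_grid() -> np.ndarray:
    return np.arange(0.0, 22.0, 3.0)


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Design of one synthetic replicate panel.

    ``y0_mode='stationary'`` draws each replicate's first value from the
    stationary law Normal(mu, sigma^2/(2 theta)) so early points are typical;
    ``'fixed'`` starts every replicate at ``y0_fixed`` (default mu).
    ``detection_floor_true`` is the frequency below which the instrument
    reports 0 (set 0 to disable).
    """

    lineages: tuple[tuple[str, OUParams], ...] = DEFAULT_LINEAGES
    n_replicates: int = 5
    t_grid: np.ndarray = field(default_factory=_default_grid)
    y0_mode: str = "stationary"
    y0_fixed: float | None = None
    detection_floor_true: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        object.__setattr__(self, "t_grid", t)
        if self.detection_floor_true < 0:
            raise ValueError("detection floor must be >= 0")
        if self.y0_mode not in ("stationary", "fixed"):
            raise ValueError("y0_mode must be 'stationary' or 'fixed'")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def generate_panel(spec: SyntheticPanelSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a raw long-format panel plus its ground-truth record.

    Returns
    -------
    table : DataFrame with columns ``lineage, replicate, time, value`` —
        frequencies on the original scale, zeros where the simulated
        frequency fell below the detection floor.
    truth : dict with the generating parameters, seeds and design, for
        parameter-recovery tests.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(spec.lineages))
    rows = []
    truth_lineages = {}
    for (label, params), child in zip(spec.lineages, children):
        rng = np.random.default_rng(child)
        for r in range(spec.n_replicates):
            if spec.y0_mode == "stationary":
                y0 = params.mu + math.sqrt(
                    params.stationary_variance
                ) * rng.standard_normal()
            else:
                y0 = params.mu if spec.y0_fixed is None else spec.y0_fixed
            y = simulate_exact(params, y0, spec.t_grid, n_reps=1, seed=rng)[0]
            x = 10.0**y
            if spec.detection_floor_true > 0:
                x = np.where(x < spec.detection_floor_true, 0.0, x)
            for t, v in zip(spec.t_grid, x):
                rows.append((label, f"r{r + 1}", float(t), float(v)))
        truth_lineages[label] = {
            "mu": params.mu,
            "theta": params.theta,
            "sigma": params.sigma,
        }
    table = pd.DataFrame(rows, columns=["lineage", "replicate", "time", "value"])
    truth = {
        "lineages": truth_lineages,
        "n_replicates": spec.n_replicates,
        "t_grid": spec.t_grid.tolist(),
        "y0_mode": spec.y0_mode,
        "detection_floor_true": spec.detection_floor_true,
        "seed": spec.seed,
    }
    return table, truth


def fixture_bundle(outdir: str | Path, seed: int = 0) -> dict:
    """Write the canonical small fixture set used by tests and the demo.

    Contents: the default 3-lineage x 5-replicate x 8-time panel
    (``panel.csv``), its truth record (``truth.json``), and a hand-built
    3-node network fixture (``network_fixture.json``: founder at t=0 with one
    child dying at t=5 and one child alive past the t=20 snapshot).  Output
    is byte-stable for a given seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = SyntheticPanelSpec(seed=seed)
    table, truth = generate_panel(spec)
    panel_path = outdir / "panel.csv"
    table.to_csv(panel_path, index=False, float_format="%.17g")
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    network = {
        "snapshot_time": 20.0,
        "nodes": [
            {"id": 0, "parent": None, "birth": 0.0, "death": None, "phenotype": -6.8},
            {"id": 1, "parent": 0, "birth": 2.0, "death": 5.0, "phenotype": -6.5},
            {"id": 2, "parent": 0, "birth": 3.0, "death": None, "phenotype": -7.1},
        ],
    }
    net_path = outdir / "network_fixture.json"
    net_path.write_text(json.dumps(network, indent=2, sort_keys=True) + "\n")
    return {"panel": panel_path, "truth": truth_path, "network": net_path}
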