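"""Trajectory tables, detection-floor preprocessing and result artifact IO.

Raw input is a long-format delimited table with one row per observation:
``lineage, replicate, time, value`` where ``value`` is a non-negative
frequency.  Before likelihood analysis each lineage is floored at its
detection limit ``epsilon = 0.5 * min positive value`` (zeros become
``epsilon``) and transformed to log10.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_COLUMNS: Mapping[str, str] = {
    "lineage": "lineage",
    "replicate": "replicate",
    "time": "time",
    "value": "value",
}

__all__ = [
    "Replicate",
    "LineageDataset",
    "read_trajectories",
    "detection_floor",
    "floor_and_log",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class Replicate:
    """One replicate time series (strictly increasing times)."""

    times: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and y must be 1-D arrays of equal length")
        if not np.all(np.isfinite(t)):
            raise ValueError("times must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing within a replicate")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class LineageDataset:
    """Replicate-grouped trajectories of one lineage.

    ``scale`` records whether ``y`` holds raw frequencies or log10 floored
    frequencies; the likelihood machinery requires ``scale == "log10"``.
    ``epsilon`` is the lineage-specific detection floor used in the transform
    (``None`` while still on the raw scale).
    """

    lineage: str
    replicates: tuple[Replicate, ...]
    epsilon: float | None = None
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log10"):
            raise ValueError("scale must be 'raw' or 'log10'")
        if not self.replicates:
            raise ValueError("dataset needs at least one replicate")
        object.__setattr__(self, "replicates", tuple(self.replicates))

    @property
    def n_transitions(self) -> int:
        return sum(max(len(r) - 1, 0) for r in self.replicates)

    def all_values(self) -> np.ndarray:
        return np.concatenate([r.y for r in self.replicates])


def _validate_raw_table(df: pd.DataFrame) -> pd.DataFrame:
    neg = df.index[df["value"] < 0]
    if len(neg):
        raise ValueError(
            f"negative frequency value(s) at row(s) {list(neg[:5])}: "
            "frequencies must be >= 0"
        )
    if not np.all(np.isfinite(df["time"].to_numpy(dtype=float))):
        raise ValueError("non-finite time values")
    dup = df.duplicated(subset=["lineage", "replicate", "time"])
    if dup.any():
        rows = list(df.index[dup][:5])
        raise ValueError(
            f"duplicate (lineage, replicate, time) rows at {rows}; "
            "resolve duplicates upstream rather than silently averaging"
        )
    return df


def read_trajectories(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a long-format trajectory table into a validated DataFrame.

    Parameters
    ----------
    path : path to a delimited text file with a header row.
    column_map : mapping from canonical names (``lineage, replicate, time,
        value``) to the file's column names; defaults to identity.
    sep : field separator; inferred from the extension (``.tsv``/``.tab`` ->
        tab, otherwise comma) when omitted.

    Rows with a missing value are dropped with a logged count.  Negative
    values and duplicate keys raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep)
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise KeyError(f"missing required column(s) {missing} in {path.name}")
    df = df.rename(columns={v: k for k, v in cmap.items()})
    df = df[["lineage", "replicate", "time", "value"]].copy()
    if df.empty:
        log.warning("empty trajectory table read from %s", path)
        return df
    n_missing = int(df["value"].isna().sum())
    if n_missing:
        log.info("dropping %d row(s) with missing value", n_missing)
        df = df.dropna(subset=["value"]).reset_index(drop=True)
    df["time"] = df["time"].astype(float)
    df["value"] = df["value"].astype(float)
    return _validate_raw_table(df)


def detection_floor(values: Iterable[float]) -> float:
    """Detection-floor constant: half the smallest strictly positive value."""
    x = np.asarray(list(values), dtype=float)
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("no positive observations; floor undefined")
    return 0.5 * float(pos.min())


def floor_and_log(table: pd.DataFrame, lineage: str) -> LineageDataset:
    """Build a log10-scale :class:`LineageDataset` for one lineage.

    The detection floor epsilon is computed over this lineage's values only;
    every value is floored at epsilon (``x* = max(x, epsilon)``) and then
    log10-transformed, so the output is finite whenever the lineage has at
    least one positive observation.
    """
    sub = table[table["lineage"] == lineage]
    if sub.empty:
        raise KeyError(f"lineage {lineage!r} not present in table")
    eps = detection_floor(sub["value"])
    reps = []
    for _, grp in sub.groupby("replicate", sort=True):
        grp = grp.sort_values("time")
        y = np.log10(np.maximum(grp["value"].to_numpy(dtype=float), eps))
        reps.append(Replicate(times=grp["time"].to_numpy(dtype=float), y=y))
    return LineageDataset(
        lineage=str(lineage), replicates=tuple(reps), epsilon=eps, scale="log10"
    )


# ---------------------------------------------------------------------------
# result artifact IO


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(artifact, path: str | Path, format: str = "json") -> Path:
    """Serialize a result artifact to disk.

    ``format='json'`` works for any dataclass-like result (fits, separation
    summaries, comparisons); ``format='table'`` writes a flat dataclass as a
    one-row CSV.  Lineage networks have their own exporters in
    :mod:`oubranch.branching` and are rejected here.
    """
    from .branching import LineageNetwork  # local import to avoid cycle

    if isinstance(artifact, LineageNetwork):
        raise TypeError("networks are exported via oubranch.branching.export_network")
    path = Path(path)
    payload = _jsonable(artifact)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "table":
        if not isinstance(payload, dict):
            raise TypeError("table format requires a flat dataclass/dict artifact")
        flat = {
            k: v
            for k, v in payload.items()
            if np.isscalar(v) or v is None or isinstance(v, (bool, str))
        }
        pd.DataFrame([flat]).to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_results(path: str | Path, format: str = "json"):
    """Read back an artifact written by :func:`write_results` (as dict/DataFrame)."""
    path = Path(path)
    if format == "json":
        return json.loads(path.read_text())
    if format == "table":
        return pd.read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def dataset_from_arrays(
    lineage: str,
    times: Sequence[np.ndarray] | np.ndarray,
    ys: Sequence[np.ndarray],
    scale: str = "log10",
    epsilon: float | None = None,
) -> LineageDataset:
    """Convenience constructor from per-replicate arrays (shared grid allowed)."""
    times = np.asarray(times, dtype=float)
    reps = []
    for y in ys:
        t = times if times.ndim == 1 else times[len(reps)]
        reps.append(Replicate(times=np.asarray(t, dtype=float), y=np.asarray(y, dtype=float)))
    return LineageDataset(lineage=lineage, replicates=tuple(reps), epsilon=epsilon, scale=scale)
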