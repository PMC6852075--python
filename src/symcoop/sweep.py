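"""Parameter sweeps over the analytic models and the simulator.

A :class:`SweepSpec` names a mode (which computation runs per grid cell)
and the parameter axes to cross. Results come back as one tidy DataFrame
row per cell (times replicate, in simulate mode) with a fixed column
schema, suitable for plotting equilibrium surfaces, dominance maps, route
decompositions, or simulation/branching maps.
"""

from __future__ import annotations

import itertools
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analytic import (
    dominant_factor_open,
    ess_closed,
    ess_open,
    marginal_effect_relatedness,
    marginal_effect_transmission,
    route_decomposition_closed,
    whole_group_relatedness_closed,
)
from .params import ClosedParams, OpenParams
from .simulate import SimConfig, run_simulation
from .stats import classify_branching, compare_relatedness

__all__ = ["SweepSpec", "run_sweep", "write_results", "read_results", "COLUMNS"]

MODES = ("ess_open", "ess_closed", "dominance", "routes", "simulate")

#: Fixed output schema; absent quantities are NaN/None.
COLUMNS = [
    "mode",
    "R",
    "lam",
    "s",
    "f",
    "k_h",
    "k_v",
    "k",
    "seed",
    "x_star",
    "stable",
    "dominant_factor",
    "route_ratio",
    "mean_x",
    "var_x",
    "realized_R_obs",
    "realized_R_pred",
    "branched",
    "first_branch_generation",
    "error",
]


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: a mode, parameter axes, and (for simulations) replication.

    ``axes`` maps parameter names (``R``, ``lam``, ``s``, ``f``, ``k``,
    ``k_h``, ``k_v``) to value lists; the sweep crosses all axes. Simulate
    mode additionally honours ``sim_overrides`` (forwarded to
    :class:`~symcoop.simulate.SimConfig`) and runs ``replicates`` seeds per
    cell, each seed derived reproducibly from ``base_seed`` and the cell
    and replicate indices.
    """

    mode: str
    axes: dict[str, list[float]]
    replicates: int = 1
    base_seed: int = 0
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not self.axes or any(len(v) == 0 for v in self.axes.values()):
            raise ValueError("every axis needs at least one value")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _cell_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-cell seed: CRC32 of the indices XOR the base."""
    digest = zlib.crc32(f"cell={cell_index},rep={replicate}".encode())
    return (base_seed ^ digest) & 0x7FFFFFFF


def _blank_row(mode: str) -> dict:
    row = {c: math.nan for c in COLUMNS}
    row.update(mode=mode, dominant_factor=None, stable=None, branched=None, error=None)
    return row


def _analytic_row(mode: str, cell: dict) -> dict:
    row = _blank_row(mode)
    row.update(cell)
    if mode == "ess_open":
        p = OpenParams(R=cell["R"], lam=cell["lam"], s=cell["s"], f=cell["f"])
        sol = ess_open(p)
        row.update(x_star=sol.x_star, stable=sol.stable)
    elif mode == "dominance":
        p = OpenParams(R=cell["R"], lam=cell["lam"], s=cell["s"], f=cell["f"])
        sol = ess_open(p)
        row.update(
            x_star=sol.x_star,
            stable=sol.stable,
            dominant_factor=dominant_factor_open(p),
        )
        row["dx_dR"] = marginal_effect_relatedness(p)
        row["dx_dlam"] = marginal_effect_transmission(p)
    elif mode == "ess_closed":
        k = int(cell["k"])
        p = ClosedParams(lam=cell["lam"], k_h=k, k_v=k, s=cell["s"], f=cell["f"])
        sol = ess_closed(p)
        row.update(
            k=k,
            k_h=k,
            k_v=k,
            x_star=sol.x_star,
            stable=sol.stable,
            R=whole_group_relatedness_closed(p),
        )
    elif mode == "routes":
        k = int(cell["k"])
        p = ClosedParams(lam=cell["lam"], k_h=k, k_v=k, s=cell["s"], f=cell["f"])
        dec = route_decomposition_closed(p)
        row.update(
            k=k,
            k_h=k,
            k_v=k,
            R=whole_group_relatedness_closed(p),
            x_star=ess_closed(p).x_star,
            route_ratio=dec.ratio,
        )
    return row


def _simulate_row(cell: dict, seed: int, overrides: dict) -> dict:
    row = _blank_row("simulate")
    row.update(cell, seed=seed)
    k = int(cell["k"])
    cfg_kwargs = dict(
        n_hosts=500,
        k=k,
        lam=cell["lam"],
        s=cell.get("s", 1.0),
        f=cell.get("f", 1.0),
        n_generations=2000,
        seed=seed,
    )
    cfg_kwargs.update(overrides)
    cfg = SimConfig(**cfg_kwargs)
    result = run_simulation(cfg, keep_snapshots=True)
    closed = ClosedParams(lam=cfg.lam, k_h=k, k_v=k, s=cfg.s, f=cfg.f)
    predicted = whole_group_relatedness_closed(closed)
    summ = result.summaries
    gens = summ["generation"].to_numpy()
    window = summ[gens >= 0.25 * gens.max()]
    call = classify_branching(result)
    try:
        _, observed, _ = compare_relatedness(summ, predicted)
    except ValueError:
        observed = math.nan
    row.update(
        k=k,
        k_h=k,
        k_v=k,
        x_star=ess_closed(closed).x_star,
        mean_x=float(window["mean_x"].mean()),
        var_x=float(window["var_x"].mean()),
        realized_R_obs=observed,
        realized_R_pred=predicted,
        branched=call.branched,
        first_branch_generation=call.first_branch_generation,
    )
    return row


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the sweep; one row per grid cell (x replicate).

    A failing cell is recorded in its row's ``error`` column and the sweep
    continues. Deterministic given the spec, including simulate-mode
    seeding.
    """
    names = list(spec.axes)
    rows = []
    for cell_index, values in enumerate(itertools.product(*spec.axes.values())):
        cell = dict(zip(names, values))
        if spec.mode == "simulate":
            for rep in range(spec.replicates):
                seed = _cell_seed(spec.base_seed, cell_index, rep)
                try:
                    rows.append(_simulate_row(cell, seed, spec.sim_overrides))
                except Exception as exc:  # noqa: BLE001 — error rows by contract
                    row = _blank_row(spec.mode)
                    row.update(cell, seed=seed, error=str(exc))
                    rows.append(row)
        else:
            try:
                rows.append(_analytic_row(spec.mode, cell))
            except Exception as exc:  # noqa: BLE001
                row = _blank_row(spec.mode)
                row.update(cell, error=str(exc))
                rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = [c for c in COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in COLUMNS]
    return frame[ordered + extra]


def write_results(table: pd.DataFrame, path: str | Path, format: str = "csv") -> Path:
    """Write a sweep table to CSV or JSON (12 significant digits)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    try:
        if format == "csv":
            table.to_csv(path, index=False, float_format="%.12g")
        elif format == "json":
            records = json.loads(table.to_json(orient="records", double_precision=12))
            path.write_text(json.dumps(records, indent=1))
        else:
            raise ValueError(f"unsupported format {format!r}; use 'csv' or 'json'")
    except OSError as exc:
        raise OSError(f"failed writing results to {path}: {exc}") from exc
    return path


def read_results(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Read a table previously written by :func:`write_results`."""
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        return pd.DataFrame(json.loads(path.read_text()))
    raise ValueError(f"unsupported format {format!r}; use 'csv' or 'json'")
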