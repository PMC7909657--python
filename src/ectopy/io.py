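"""Serialization helpers: flat YAML configs, CSV tables, HDF5 snapshots."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .cell import CellParams
from .medium import FieldState, MediumConfig

__all__ = [
    "save_params",
    "load_params",
    "save_trajectory_csv",
    "save_grid_csv",
    "load_grid_csv",
    "save_snapshot",
    "load_snapshot",
    "branch_to_csv",
    "save_trial_summary",
]


def save_params(path, params) -> None:
    """Write a parameter dataclass as a flat key-value YAML file."""
    d = {k: v for k, v in dataclasses.asdict(params).items() if np.isscalar(v)}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_params(path, cls=CellParams):
    return cls(**yaml.safe_load(Path(path).read_text()))


def save_trajectory_csv(path, t, V, W=None) -> None:
    cols = [np.asarray(t), np.asarray(V)]
    header = "t,V"
    if W is not None:
        cols.append(np.asarray(W))
        header += ",W"
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header, comments="")


def save_grid_csv(path, grid) -> None:
    np.savetxt(path, np.asarray(grid), delimiter=",")


def load_grid_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


def save_snapshot(path, state: FieldState, cfg: MediumConfig) -> None:
    """Write a field snapshot plus the defining configuration to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("V", data=state.V)
        f.create_dataset("W", data=state.W)
        f.create_dataset("b_field", data=cfg.b_field)
        f.create_dataset("flux_mask", data=cfg.flux_mask)
        f.attrs["t"] = state.t
        f.attrs["c"] = cfg.c
        f.attrs["bc"] = cfg.bc
        f.attrs["dx"] = cfg.dx
        f.attrs["dy"] = cfg.dy
        for k, v in dataclasses.asdict(cfg.cell).items():
            f.attrs[f"cell_{k}"] = v


def load_snapshot(path) -> tuple[FieldState, MediumConfig]:
    with h5py.File(path, "r") as f:
        cell = CellParams(**{k[5:]: float(v) for k, v in f.attrs.items() if k.startswith("cell_")})
        cfg = MediumConfig(
            b_field=f["b_field"][()],
            c=float(f.attrs["c"]),
            bc=str(f.attrs["bc"]),
            dx=float(f.attrs["dx"]),
            dy=float(f.attrs["dy"]),
            cell=cell,
            flux_mask=f["flux_mask"][()],
        )
        state = FieldState(f["V"][()], f["W"][()], float(f.attrs["t"]))
    return state, cfg


def branch_to_csv(points, path) -> None:
    """Bifurcation diagram as (b, V, stability, label) CSV."""
    rows = [
        f"{pt.b:.8g},{pt.state.V:.8g},{'stable' if pt.stable else 'unstable'},{pt.label}"
        for pt in points
    ]
    Path(path).write_text("b,V,stability,label\n" + "\n".join(rows) + "\n")


def save_trial_summary(base, summary) -> None:
    """Write per-cell failure percentages (CSV) and scalar statistics (JSON)."""
    base = Path(base)
    np.savetxt(base.with_suffix(".csv"), summary.failure_pct, delimiter=",")
    scalars = {
        "n_trials": summary.n_trials,
        "n_diverged": summary.n_diverged,
        "boundary_rate_pct": summary.boundary_rate,
        "boundary_se_pct": summary.boundary_se,
        "midfield_rate_pct": summary.midfield_rate,
        "midfield_se_pct": summary.midfield_se,
        "boundary_se_binomial_pct": summary.boundary_se_binomial,
        "midfield_se_binomial_pct": summary.midfield_se_binomial,
    }
    base.with_suffix(".json").write_text(json.dumps(scalars, indent=2))
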