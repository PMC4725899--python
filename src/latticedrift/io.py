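"""Plain-text serialization: trajectory CSV + JSON sidecar, grid snapshots,
fixation-time sample input.

Outputs are deliberately plain CSV/JSON so a run is reconstructible from its
files alone and readable by anything.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import ENGINE_VERSION, PopulationGrid, SimulationParams, Trajectory


def params_to_dict(params: SimulationParams) -> dict:
    return {
        "rows": params.cfg.rows,
        "cols": params.cfg.cols,
        "topology": params.topology,
        "p0": params.p0,
        "seed": params.seed,
        "max_generations": params.generation_cap,
    }


def write_trajectory(traj: Trajectory, csv_path: str | Path) -> Path:
    """Write per-generation series as CSV and metadata as a JSON sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "generation": traj.generations,
            "n_AA": traj.counts[:, 0],
            "n_Aa": traj.counts[:, 1],
            "n_aa": traj.counts[:, 2],
            "f_A": traj.f_A,
        }
    )
    df.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    meta = {
        "params": params_to_dict(traj.params),
        "t_h": traj.t_h,
        "fixed_allele": traj.fixed_allele,
        "capped": traj.capped,
        "engine_version": ENGINE_VERSION,
    }
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    return csv_path


def write_grid_snapshot(grid: PopulationGrid, path: str | Path) -> Path:
    """CSV matrix of A-copy counts per site (2=AA, 1=Aa, 0=aa)."""
    path = Path(path)
    np.savetxt(path, grid.copies, fmt="%d", delimiter=",")
    return path


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """CSV matrix of cluster labels (0 = heterozygote)."""
    path = Path(path)
    np.savetxt(path, labels, fmt="%d", delimiter=",")
    return path


def read_fixation_samples(path: str | Path) -> np.ndarray:
    """Fixation-time samples: one value per line, or a CSV t_h column."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: no samples found")
    first = text.splitlines()[0]
    if "t_h" in first:
        values = pd.read_csv(path)["t_h"].to_numpy(dtype=float)
    else:
        values = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split(",")[0].strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: not a number: {line!r}") from exc
        values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError(f"{path}: no samples found")
    bad = np.flatnonzero(values <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: non-positive sample at line {int(bad[0]) + 1}"
        )
    return values
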