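"""Reading and writing trajectory / outcome artifacts.

Trajectory CSVs have columns ``t, env, N_i, N_j`` with the environment coded
as single characters G/B and floats printed with 17 significant digits so the
written abundances round-trip to full double precision.  A JSON sidecar
(``<name>.json`` next to the CSV) records the full generating configuration
(parameters, seed, threshold) so every artifact can be regenerated.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .environment import EnvSequence

__all__ = ["write_trajectory", "read_trajectory", "trajectory_config", "FLOAT_FORMAT"]

FLOAT_FORMAT = "%.17g"


def trajectory_config(traj: Trajectory) -> dict:
    """A JSON-serializable record of everything needed to regenerate ``traj``."""
    cfg = {
        "T": len(traj),
        "intro_time": traj.intro_time,
        "intro_abundance": traj.intro_abundance,
        "extinction_threshold": traj.extinction_threshold,
    }
    cfg.update(traj.meta)
    return cfg


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write the trajectory CSV plus its JSON config sidecar; returns the CSV path."""
    path = Path(path)
    traj.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FORMAT)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(trajectory_config(traj), fh, indent=2, default=str)
    return path


def read_trajectory(path) -> pd.DataFrame:
    """Read a trajectory CSV back as a DataFrame (t, env, N_i, N_j)."""
    df = pd.read_csv(path, dtype={"env": str}, float_precision="round_trip")
    required = {"t", "env", "N_i", "N_j"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return df


def trajectory_from_frame(df: pd.DataFrame, intro_time: int = 2,
                          intro_abundance: float = 2.0,
                          extinction_threshold: float = 1.0) -> Trajectory:
    """Rebuild a Trajectory object from a (t, env, N_i, N_j) frame."""
    env = EnvSequence.from_labels(df["env"].to_numpy())
    return Trajectory(
        env=env,
        n_i=df["N_i"].to_numpy(float),
        n_j=df["N_j"].to_numpy(float),
        intro_time=intro_time,
        intro_abundance=intro_abundance,
        extinction_threshold=extinction_threshold,
    )
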