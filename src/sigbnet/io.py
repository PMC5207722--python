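"""Tab-separated text I/O for trajectories and analysis tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .inputs import PhosphataseInput
from .model import SPECIES, Trajectory

__all__ = ["write_trajectory", "read_trajectory", "write_table"]


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    """One header row (time_hr + species names + P_T_uM), full float
    precision, one row per time point."""
    df = pd.DataFrame(traj.y, columns=list(SPECIES))
    df.insert(0, "time_hr", traj.t)
    df["P_T_uM"] = traj.P_T
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    t = df["time_hr"].to_numpy()
    y = df[list(SPECIES)].to_numpy()
    inp = PhosphataseInput("trajectory", {}, t_grid=t,
                           values=df["P_T_uM"].to_numpy())
    return Trajectory(t=t, y=y, input=inp)


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
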