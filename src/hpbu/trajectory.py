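"""Pen trajectories and their on-disk formats.

A trajectory is a sequence of time-stamped planar pen samples.  Two
equivalent dialects are supported: CSV with header ``t,x,y`` and a JSON
list of ``{"t": ..., "x": ..., "y": ...}`` records.  Values are written
with ``repr`` round-trip precision so read(write(traj)) is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "read_trajectory", "write_trajectory"]


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 2-d pen path; ``t`` in seconds, strictly increasing."""

    t: np.ndarray
    xy: np.ndarray  # shape (n, 2), canvas units

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if t.ndim != 1 or xy.shape != (t.size, 2):
            raise ValueError("trajectory needs t of shape (n,) and xy of shape (n, 2)")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(xy)):
            raise ValueError("trajectory values must be finite")
        t.setflags(write=False)
        xy.setflags(write=False)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)

    def __len__(self) -> int:
        return self.t.size

    @classmethod
    def from_samples(cls, samples) -> "Trajectory":
        """Build from an (n, 3) array-like of ``t, x, y`` rows."""
        arr = np.asarray(samples, dtype=float)
        return cls(arr[:, 0], arr[:, 1:3])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.xy[:, 0], "y": self.xy[:, 1]})


def write_trajectory(traj: Trajectory, path) -> None:
    """Write CSV (``.csv``) or JSON (``.json``), chosen by suffix."""
    path = Path(path)
    if path.suffix == ".json":
        records = [
            {"t": ti, "x": xi, "y": yi}
            for ti, (xi, yi) in zip(traj.t.tolist(), traj.xy.tolist())
        ]
        path.write_text(json.dumps(records, indent=None, separators=(",", ":")))
    else:
        lines = ["t,x,y"]
        lines += [
            f"{ti!r},{xi!r},{yi!r}"
            for ti, (xi, yi) in zip(traj.t.tolist(), traj.xy.tolist())
        ]
        path.write_text("\n".join(lines) + "\n")


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
        t = np.array([r["t"] for r in records], dtype=float)
        xy = np.array([[r["x"], r["y"]] for r in records], dtype=float)
        return Trajectory(t, xy)
    df = pd.read_csv(path, float_precision="round_trip")
    return Trajectory(df["t"].to_numpy(), df[["x", "y"]].to_numpy())
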