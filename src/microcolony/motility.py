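"""Swimming-trajectory construction and motile/sessile classification.

High-frame-rate assays (default 7.5 frames/s) yield per-frame coordinates in
micrometres with time in seconds.  A trajectory's path length is the sum of
step Euclidean distances, its net displacement the straight-line distance
between first and last position, and its mean speed path length over elapsed
time.  Cells are classified motile when their net displacement exceeds a
threshold (default 2 um, about one cell length); only motile cells enter
speed statistics, mirroring how sessile cells are ignored in swimming assays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    cell_id: str
    timestamps_s: np.ndarray
    positions_um: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def path_length_um(self) -> float:
        steps = np.diff(self.positions_um, axis=0)
        return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))

    @property
    def net_displacement_um(self) -> float:
        d = self.positions_um[-1] - self.positions_um[0]
        return float(np.hypot(d[0], d[1]))

    @property
    def mean_speed_um_s(self) -> float:
        dt = self.timestamps_s[-1] - self.timestamps_s[0]
        return self.path_length_um / dt

    @property
    def net_speed_um_s(self) -> float:
        dt = self.timestamps_s[-1] - self.timestamps_s[0]
        return self.net_displacement_um / dt


def build_trajectories(
    observations: pd.DataFrame, frame_rate_hz: float | None = None
) -> tuple[list[Trajectory], list[str]]:
    """Per-cell trajectories from a high-frame-rate observation table.

    Accepts either a ``time_s`` column or ``frame`` plus ``frame_rate_hz``.
    Cells observed in fewer than two frames are skipped; their ids are
    returned as notices.
    """
    df = observations.copy()
    if "time_s" not in df.columns:
        if frame_rate_hz is None or frame_rate_hz <= 0:
            raise ValueError("need a time_s column or a positive frame rate")
        df["time_s"] = df["frame"].astype(float) / frame_rate_hz
    trajectories: list[Trajectory] = []
    skipped: list[str] = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_s")
        if len(grp) < 2:
            skipped.append(str(cid))
            continue
        trajectories.append(
            Trajectory(
                str(cid),
                grp["time_s"].to_numpy(dtype=float),
                grp[["x_um", "y_um"]].to_numpy(dtype=float),
            )
        )
    return trajectories, skipped


def classify_motile(trajectory: Trajectory, threshold_um: float = 2.0) -> str:
    """'motile' when the net displacement exceeds the threshold, else 'sessile'."""
    return "motile" if trajectory.net_displacement_um > threshold_um else "sessile"


def speed_table(
    trajectories: list[Trajectory], threshold_um: float = 2.0
) -> pd.DataFrame:
    """Per-cell speed summary with the motile/sessile class."""
    rows = [
        (
            tr.cell_id,
            tr.path_length_um,
            tr.net_displacement_um,
            tr.mean_speed_um_s,
            tr.net_speed_um_s,
            classify_motile(tr, threshold_um),
        )
        for tr in trajectories
    ]
    return pd.DataFrame(
        rows,
        columns=["cell_id", "path_um", "net_um", "speed_um_s", "net_speed_um_s", "class"],
    )


def swimming_speed_stats(speeds: pd.DataFrame) -> dict[str, float]:
    """Mean/SD swimming speed over motile cells and the motile fraction."""
    motile = speeds[speeds["class"] == "motile"]
    n = len(speeds)
    return {
        "n_cells": float(n),
        "motile_fraction": len(motile) / n if n else float("nan"),
        "mean_speed_um_s": float(motile["speed_um_s"].mean()) if len(motile) else float("nan"),
        "sd_speed_um_s": float(motile["speed_um_s"].std(ddof=1)) if len(motile) > 1 else float("nan"),
    }
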