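"""Per-cell movement vectors, instantaneous velocities, and the summed
mean-displacement curve.

A movement vector is a cell's 3D displacement between two consecutive
recorded time points.  Speeds are reported in µm/min (displacement
magnitude over elapsed time); the summed mean-displacement curve is the
running sum over frames of the per-frame mean step magnitude, a simple
population-level measure of how far cells travel over a time-lapse.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import TrackSet

VECTOR_COLUMNS = [
    "track_id", "frame", "frame_next", "dx_um", "dy_um", "dz_um",
    "magnitude_um", "dt_min",
]


def movement_vectors(ts: TrackSet, gap_policy: str = "consecutive_recorded") -> pd.DataFrame:
    """Displacement vectors between consecutive recorded points of each track.

    gap_policy
        ``consecutive_recorded`` (default): one vector per adjacent pair of
        recorded frames, whatever the gap — automated trackers drop frames,
        and dt carries the true elapsed time.
        ``strict_frames``: only pairs with frame_next == frame + 1.

    Returns a table with columns ``track_id, frame, frame_next, dx_um,
    dy_um, dz_um, magnitude_um, dt_min``.  Length-1 tracks yield no rows.
    """
    if gap_policy not in ("consecutive_recorded", "strict_frames"):
        raise ValueError(f"unknown gap_policy: {gap_policy!r}")
    df = ts.data
    if len(df) == 0:
        return pd.DataFrame(columns=VECTOR_COLUMNS)
    g = df.groupby("track_id", sort=False)
    nxt = g[["frame", "time_min", "x_um", "y_um", "z_um"]].shift(-1)
    valid = nxt["frame"].notna()
    out = pd.DataFrame({
        "track_id": df.loc[valid, "track_id"].to_numpy(),
        "frame": df.loc[valid, "frame"].to_numpy(),
        "frame_next": nxt.loc[valid, "frame"].to_numpy().astype(int),
        "dx_um": (nxt.loc[valid, "x_um"] - df.loc[valid, "x_um"]).to_numpy(),
        "dy_um": (nxt.loc[valid, "y_um"] - df.loc[valid, "y_um"]).to_numpy(),
        "dz_um": (nxt.loc[valid, "z_um"] - df.loc[valid, "z_um"]).to_numpy(),
        "dt_min": (nxt.loc[valid, "time_min"] - df.loc[valid, "time_min"]).to_numpy(),
    })
    # irregular clocks: fall back to the frame step if times are degenerate
    zero_dt = out["dt_min"] <= 0
    if zero_dt.any():
        out.loc[zero_dt, "dt_min"] = (
            (out.loc[zero_dt, "frame_next"] - out.loc[zero_dt, "frame"]) * ts.frame_interval
        )
    out["magnitude_um"] = np.sqrt(
        out["dx_um"] ** 2 + out["dy_um"] ** 2 + out["dz_um"] ** 2
    )
    if gap_policy == "strict_frames":
        out = out[out["frame_next"] == out["frame"] + 1]
    return out[VECTOR_COLUMNS].reset_index(drop=True)


def velocities(vectors: pd.DataFrame, unit: str = "um_per_min") -> pd.DataFrame:
    """Per-vector instantaneous speeds: magnitude / dt.

    unit: ``um_per_min`` (native) or ``um_per_h`` (display scale).
    """
    if unit not in ("um_per_min", "um_per_h"):
        raise ValueError(f"unknown unit: {unit!r}")
    out = vectors.copy()
    speed = out["magnitude_um"] / out["dt_min"]
    out["speed"] = speed * (60.0 if unit == "um_per_h" else 1.0)
    out["speed_unit"] = unit
    return out


def frame_speed_summary(vectors: pd.DataFrame, unit: str = "um_per_min") -> pd.DataFrame:
    """Per-frame velocity aggregates over the cells contributing at that frame.

    A vector contributes at the frame its pair *starts* at.  Returns
    ``frame, n_cells, mean_speed, sd_speed``.
    """
    v = velocities(vectors, unit=unit)
    if len(v) == 0:
        return pd.DataFrame(columns=["frame", "n_cells", "mean_speed", "sd_speed"])
    agg = (
        v.groupby("frame")["speed"]
        .agg(n_cells="size", mean_speed="mean", sd_speed="std")
        .reset_index()
    )
    agg["sd_speed"] = agg["sd_speed"].fillna(0.0)
    return agg


def summed_mean_displacement(
    vectors: pd.DataFrame, frames: np.ndarray | None = None
) -> pd.DataFrame:
    """Cumulative sum over frames of the per-frame mean step magnitude.

    At frame f the curve holds the running sum, over frames g <= f, of the
    mean movement-vector magnitude among cells stepping at g; it is
    non-decreasing by construction.  Frames with no vectors contribute 0
    and are flagged in the ``has_data`` column.

    frames
        Optional explicit frame axis; defaults to the frames present in
        ``vectors``.
    """
    if len(vectors) == 0:
        return pd.DataFrame(columns=["frame", "mean_step_um", "cumulative_um", "n_cells", "has_data"])
    per_frame = vectors.groupby("frame")["magnitude_um"].agg(["mean", "size"])
    if frames is None:
        frames = np.sort(vectors["frame"].unique())
    frames = np.asarray(frames, dtype=int)
    mean_step = np.array([per_frame["mean"].get(f, 0.0) for f in frames])
    n = np.array([int(per_frame["size"].get(f, 0)) for f in frames])
    return pd.DataFrame({
        "frame": frames,
        "mean_step_um": mean_step,
        "cumulative_um": np.cumsum(mean_step),
        "n_cells": n,
        "has_data": n > 0,
    })
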