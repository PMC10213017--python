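"""Reading, validating, writing and cropping single-cell track tables.

The canonical on-disk format is UTF-8 comma-delimited text with header
``track_id,frame,time_min,x_um,y_um,z_um`` — one row per cell per time
point, coordinates in micrometres, time in minutes.  An Imaris-style
position-export dialect is also read (columns ``Position X/Y/Z``, ``Time``,
``TrackID``), with ``Time`` ordinals 1..N mapped to 0-based frames and
wall-clock time reconstructed from the frame interval.

The in-memory unit of analysis is :class:`TrackSet`, a thin wrapper around
a tidy :class:`pandas.DataFrame` plus the frame interval of the time-lapse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = ["track_id", "frame", "time_min", "x_um", "y_um", "z_um"]

IMARIS_COLUMNS = {
    "Position X": "x_um",
    "Position Y": "y_um",
    "Position Z": "z_um",
    "Time": "time_ordinal",
    "TrackID": "track_id",
}

DEFAULT_FRAME_INTERVAL_MIN = 15.0


class TrackFormatError(ValueError):
    """A required column is missing or a field cannot be parsed."""


class TrackValidationError(ValueError):
    """The table parses but violates a track-table invariant."""


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned spatial window in µm; z bounds optional (None = unbounded)."""

    x: tuple[float, float]
    y: tuple[float, float]
    z: tuple[float, float] | None = None

    def __post_init__(self):
        for name, bounds in (("x", self.x), ("y", self.y), ("z", self.z)):
            if bounds is None:
                continue
            lo, hi = bounds
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"RegionOfInterest: {name} bounds must satisfy min < max, got {bounds}")

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Boolean mask over an (n, 3) position array."""
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        mask = (
            (xyz[:, 0] >= self.x[0]) & (xyz[:, 0] <= self.x[1])
            & (xyz[:, 1] >= self.y[0]) & (xyz[:, 1] <= self.y[1])
        )
        if self.z is not None:
            mask &= (xyz[:, 2] >= self.z[0]) & (xyz[:, 2] <= self.z[1])
        return mask


@dataclass
class TrackSet:
    """A collection of cell tracks sharing one frame clock.

    Parameters
    ----------
    data
        Tidy table with the canonical columns; one row per (track, frame).
    frame_interval
        Minutes between consecutive frames of the time-lapse (default 15).
    meta
        Free-form provenance notes (e.g. ``z_filled`` when a 2D input had
        its z column zero-filled).
    """

    data: pd.DataFrame
    frame_interval: float = DEFAULT_FRAME_INTERVAL_MIN
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise TrackValidationError(f"frame_interval must be > 0, got {self.frame_interval}")
        self.data = _validate_table(self.data)

    # -- accessors -------------------------------------------------------
    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    @property
    def track_ids(self) -> list:
        return list(self.data["track_id"].unique())

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.data["frame"].unique())

    @property
    def is_empty(self) -> bool:
        return len(self.data) == 0

    def track(self, track_id) -> pd.DataFrame:
        """Rows of one track, frame-sorted."""
        return self.data[self.data["track_id"] == track_id]

    def positions_at(self, frame: int) -> pd.DataFrame:
        """Cells present at one frame, indexed by track_id."""
        sub = self.data[self.data["frame"] == frame]
        return sub.set_index("track_id")[["x_um", "y_um", "z_um"]]

    def equals(self, other: "TrackSet") -> bool:
        return (
            self.frame_interval == other.frame_interval
            and self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))
        )


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, CANONICAL_COLUMNS].copy()
    for col in ["frame", "time_min", "x_um", "y_um", "z_um"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise TrackFormatError(f"non-numeric value in column '{col}' at row {row}")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0])
            raise TrackFormatError(f"missing value in column '{col}' at row {row}")
        df[col] = coerced
    if not np.isfinite(df[["x_um", "y_um", "z_um", "time_min"]].to_numpy()).all():
        raise TrackValidationError("non-finite coordinate or time value")
    if (df["frame"] < 0).any() or (df["frame"] % 1 != 0).any():
        raise TrackValidationError("frame indices must be non-negative integers")
    df["frame"] = df["frame"].astype(int)
    if (df["time_min"] < 0).any():
        raise TrackValidationError("time_min must be >= 0")
    dup = df.duplicated(subset=["track_id", "frame"], keep=False)
    if dup.any():
        offenders = (
            df.loc[dup, ["track_id", "frame"]].drop_duplicates().itertuples(index=False)
        )
        listing = ", ".join(f"({t.track_id}, frame {t.frame})" for t in offenders)
        raise TrackValidationError(f"duplicate (track_id, frame) rows: {listing}")
    # frame monotonicity is enforced by sorting; duplicates already rejected
    df = df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)
    return df


def read_tracks(
    path,
    dialect: str = "canonical",
    frame_interval: float = DEFAULT_FRAME_INTERVAL_MIN,
) -> TrackSet:
    """Read a track table from delimited text.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"canonical"`` for the native format, ``"imaris"`` for
        position-export tables (``Position X/Y/Z``, ``Time``, ``TrackID``;
        extra columns ignored).  Imaris ``Time`` values are 1-based frame
        ordinals; they are mapped to 0-based frames and
        ``time_min = frame * frame_interval``.
    frame_interval
        Minutes per frame, used both as TrackSet metadata and to
        reconstruct imaris times.
    """
    if dialect not in ("canonical", "imaris"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    # round_trip float parsing so write/read cycles are bit-exact
    df = pd.read_csv(path, float_precision="round_trip")
    meta: dict = {"source": str(path), "dialect": dialect}
    if dialect == "imaris":
        required = [c for c in IMARIS_COLUMNS if c != "Position Z"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TrackFormatError(f"missing required column(s): {', '.join(missing)}")
        df = df.rename(columns=IMARIS_COLUMNS)
        if "z_um" not in df.columns:
            df["z_um"] = 0.0
            meta["z_filled"] = True
        ordinal = pd.to_numeric(df["time_ordinal"], errors="coerce")
        if ordinal.isna().any():
            row = int(df.index[ordinal.isna()][0])
            raise TrackFormatError(f"non-numeric value in column 'Time' at row {row}")
        df["frame"] = ordinal.astype(int) - int(ordinal.min())
        df["time_min"] = df["frame"] * frame_interval
        df = df[CANONICAL_COLUMNS]
    else:
        if "z_um" not in df.columns and {"track_id", "frame", "time_min", "x_um", "y_um"} <= set(df.columns):
            df["z_um"] = 0.0
            meta["z_filled"] = True
    return TrackSet(df, frame_interval=frame_interval, meta=meta)


def write_tracks(ts: TrackSet, path) -> None:
    """Write a TrackSet as canonical delimited text (full float precision).

    ``read_tracks(write_tracks(ts))`` reproduces ``ts`` exactly.
    """
    ts.data.to_csv(path, index=False, float_format=None)


def crop_region(
    ts: TrackSet,
    roi: RegionOfInterest,
    policy: str = "whole_track_inside_at_start",
) -> TrackSet:
    """Select tracks by position relative to a spatial window.

    Selection is per-track — tracks are kept or dropped whole, never
    truncated, so downstream displacement computations stay well-defined.

    policy
        ``whole_track_inside_at_start``: keep tracks whose first recorded
        position lies inside the window (the crop-then-track reading of a
        cropped field of view).
        ``any_point_inside``: keep tracks with at least one position inside.
    """
    if policy not in ("whole_track_inside_at_start", "any_point_inside"):
        raise ValueError(f"unknown crop policy: {policy!r}")
    if ts.is_empty:
        return TrackSet(ts.data.copy(), ts.frame_interval, dict(ts.meta))
    keep = []
    for tid, grp in ts.data.groupby("track_id", sort=False):
        xyz = grp[["x_um", "y_um", "z_um"]].to_numpy()
        inside = roi.contains(xyz)
        if policy == "whole_track_inside_at_start":
            if inside[0]:
                keep.append(tid)
        elif inside.any():
            keep.append(tid)
    out = ts.data[ts.data["track_id"].isin(keep)].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("crop_region: no tracks matched the region of interest", stacklevel=2)
    meta = dict(ts.meta)
    meta["cropped"] = {"policy": policy, "n_kept": len(keep), "n_dropped": ts.n_tracks - len(keep)}
    return TrackSet(out, ts.frame_interval, meta)
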