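"""Toward/away-from-scar classification of track net movement.

In a wound explant, cells either migrate toward the central scar region,
move away from it (toward the epidermis at the periphery), or barely move.
Each track is classed by its net displacement (endpoint minus start):
below a minimal-movement threshold (5 µm by default) it is ``minimal``;
otherwise ``toward_scar`` when the distance to the scar centre strictly
decreases from first to last point, else ``away_from_scar``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import RegionOfInterest, TrackSet

MOVEMENT_CLASSES = ("toward_scar", "away_from_scar", "minimal")
DEFAULT_MIN_MOVEMENT_UM = 5.0


class UnclassifiableTrackError(ValueError):
    """Track has fewer than 2 points, or no track is classifiable."""


@dataclass(frozen=True)
class ScarGeometry:
    """Scar-centre coordinates (µm) and optional ROI window around it."""

    scar_center: tuple[float, float, float]
    roi: RegionOfInterest | None = None

    def __post_init__(self):
        c = np.asarray(self.scar_center, dtype=float)
        if c.shape != (3,) or not np.isfinite(c).all():
            raise ValueError(f"scar_center must be a finite 3-vector, got {self.scar_center}")
        if self.roi is not None and not self.roi.contains(c.reshape(1, 3))[0]:
            raise ValueError("scar_center must lie inside the given ROI")

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.scar_center, dtype=float)


class ScarDirectionClassifier(BaseEstimator):
    """Rule-based three-class movement classifier relative to a scar centre.

    Parameters
    ----------
    scar_center : 3-sequence of float, µm
    min_movement_um : float
        Displacement-magnitude gate for the ``minimal`` class (default 5).
    mode : {"net", "stepwise"}
        ``net`` compares the first and last distances to the scar centre;
        ``stepwise`` takes a majority vote over per-step radial changes
        (the gate still applies to the net displacement).
    threshold_on : {"net", "path"}
        Apply the 5 µm gate to the net displacement magnitude (default) or
        to the summed path length.
    use_z : bool
        Use 3D distances; set False to project onto the xy plane for thin
        explants.

    Attributes (after :meth:`fit`)
    ------------------------------
    classes_ : tuple of the three class labels.
    """

    def __init__(
        self,
        scar_center=(0.0, 0.0, 0.0),
        min_movement_um: float = DEFAULT_MIN_MOVEMENT_UM,
        mode: str = "net",
        threshold_on: str = "net",
        use_z: bool = True,
    ):
        self.scar_center = scar_center
        self.min_movement_um = min_movement_um
        self.mode = mode
        self.threshold_on = threshold_on
        self.use_z = use_z

    def fit(self, ts: TrackSet | None = None, y=None) -> "ScarDirectionClassifier":
        """Validate parameters; the rule needs no estimation from data."""
        if self.mode not in ("net", "stepwise"):
            raise ValueError(f"mode must be 'net' or 'stepwise', got {self.mode!r}")
        if self.threshold_on not in ("net", "path"):
            raise ValueError(f"threshold_on must be 'net' or 'path', got {self.threshold_on!r}")
        if self.min_movement_um < 0:
            raise ValueError("min_movement_um must be >= 0")
        c = np.asarray(self.scar_center, dtype=float)
        if c.shape != (3,) or not np.isfinite(c).all():
            raise ValueError(f"scar_center must be a finite 3-vector, got {self.scar_center!r}")
        self.classes_ = MOVEMENT_CLASSES
        return self

    def _dist(self, xyz: np.ndarray) -> np.ndarray:
        c = np.asarray(self.scar_center, dtype=float)
        d = xyz - c
        if not self.use_z:
            d = d[..., :2]
        return np.linalg.norm(d, axis=-1)

    def _classify_one(self, xyz: np.ndarray) -> str:
        if len(xyz) < 2:
            raise UnclassifiableTrackError("track of length 1 is unclassifiable")
        steps = np.diff(xyz if self.use_z else xyz[:, :2], axis=0)
        net = xyz[-1] - xyz[0]
        if not self.use_z:
            net = net[:2]
        gate = (
            float(np.linalg.norm(net))
            if self.threshold_on == "net"
            else float(np.linalg.norm(steps, axis=1).sum())
        )
        if gate < self.min_movement_um:
            return "minimal"
        r = self._dist(xyz)
        if self.mode == "net":
            return "toward_scar" if r[-1] < r[0] else "away_from_scar"
        dr = np.diff(r)
        return "toward_scar" if (dr < 0).sum() > (dr > 0).sum() else "away_from_scar"

    def predict(self, ts: TrackSet) -> pd.Series:
        """One class per classifiable track; length-1 tracks are omitted.

        Raises :class:`UnclassifiableTrackError` if no track has >= 2 points.
        """
        if not hasattr(self, "classes_"):
            self.fit()
        labels = {}
        for tid, grp in ts.data.groupby("track_id", sort=False):
            xyz = grp[["x_um", "y_um", "z_um"]].to_numpy()
            if len(xyz) < 2:
                continue
            labels[tid] = self._classify_one(xyz)
        if not labels:
            raise UnclassifiableTrackError("no classifiable tracks (all have a single point)")
        return pd.Series(labels, name="movement_class")

    def fraction_summary(self, ts: TrackSet) -> pd.DataFrame:
        """Counts and fractions per movement class (fractions sum to 1)."""
        pred = self.predict(ts)
        counts = pred.value_counts().reindex(MOVEMENT_CLASSES, fill_value=0)
        return pd.DataFrame({
            "movement_class": MOVEMENT_CLASSES,
            "count": counts.to_numpy(),
            "fraction": counts.to_numpy() / len(pred),
        })


def classify_track(track: pd.DataFrame, geometry: ScarGeometry,
                   min_movement_um: float = DEFAULT_MIN_MOVEMENT_UM, **kwargs) -> str:
    """Classify one track table (canonical columns) against a scar geometry."""
    clf = ScarDirectionClassifier(
        scar_center=tuple(geometry.center), min_movement_um=min_movement_um, **kwargs
    ).fit()
    xyz = track.sort_values("frame")[["x_um", "y_um", "z_um"]].to_numpy()
    return clf._classify_one(xyz)


def movement_fractions(ts: TrackSet, geometry: ScarGeometry,
                       min_movement_um: float = DEFAULT_MIN_MOVEMENT_UM, **kwargs) -> dict:
    """Class counts/fractions for a track set, plus the excluded-track count."""
    clf = ScarDirectionClassifier(
        scar_center=tuple(geometry.center), min_movement_um=min_movement_um, **kwargs
    ).fit()
    pred = clf.predict(ts)
    table = clf.fraction_summary(ts)
    n_single = sum(
        1 for _, grp in ts.data.groupby("track_id", sort=False) if len(grp) < 2
    )
    return {
        "per_track": pred,
        "summary": table,
        "n_classified": int(len(pred)),
        "n_excluded_single_point": int(n_single),
        "min_movement_um": float(min_movement_um),
        "scar_center_um": [float(v) for v in geometry.center],
    }


def time_coded_trajectories(ts: TrackSet) -> pd.DataFrame:
    """Plot-ready table with per-track time normalised to [0, 1].

    Normalisation is by elapsed time (first point 0, last point 1), so
    irregularly sampled tracks ramp by clock time, not by index.  A
    single-point track gets normalised time 0.  Intended for blue-to-red
    colour ramps of trajectories; rendering is left to the plotting layer.
    """
    out = ts.data.copy()
    t0 = out.groupby("track_id")["time_min"].transform("min")
    t1 = out.groupby("track_id")["time_min"].transform("max")
    span = t1 - t0
    norm = np.where(span > 0, (out["time_min"] - t0) / span.replace(0, np.nan), 0.0)
    out["time_norm"] = np.nan_to_num(norm, nan=0.0)
    return out[["track_id", "time_norm", "frame", "time_min", "x_um", "y_um", "z_um"]]
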