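"""Movement-similarity of neighbouring cells.

For every pair of consecutive time points, the neighbourhood of each cell
is taken from a Delaunay triangulation of the cell positions: two cells
are neighbours when they share a simplex of the triangulation.  For each
neighbour pair (u, v) with movement vectors u and v over the same frame
pair, the intermediate angle

    alpha(u, v) = arccos( (u . v) / (|u| |v|) )          [degrees]

measures how aligned their displacements are.  Averaging all pair angles
gives one movement-similarity score per track set; under the inverted
convention (the headline score) this is reported as 180 deg minus the mean
angle, so a perfectly coordinated cohort scores 180 deg and isotropic
random motion scores ~90 deg (cos alpha is uniform on [-1, 1] for
isotropic 3D directions, so E[alpha] = 90 deg).

The scorer is exposed as a scikit-learn style estimator
(:class:`MovementSimilarity`) plus a thin functional wrapper
(:func:`similarity`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree
from sklearn.base import BaseEstimator

from .io import TrackSet
from .kinematics import movement_vectors

ZERO_NORM_EPS_UM = 1e-9  # below this a displacement has no direction
_COPLANAR_TOL_UM = 1e-9


class UndefinedAngleError(ValueError):
    """Angle requested for a zero-length movement vector."""


class NoNeighborPairsError(ValueError):
    """No frame pair yields a neighbour pair with two nonzero vectors."""


@dataclass(frozen=True)
class NeighborGraph:
    """Per-frame symmetric neighbour adjacency.

    ``construction`` records whether edges came from a Delaunay
    triangulation or from the deterministic k-nearest-neighbour fallback
    used for tiny or degenerate (collinear/coplanar-in-2D) configurations.
    """

    frame: int
    edges: frozenset  # frozenset of frozenset({id_a, id_b})
    construction: str  # "delaunay" | "knn_fallback"
    n_points: int

    def neighbors_of(self, cell_id) -> set:
        out = set()
        for e in self.edges:
            if cell_id in e:
                (other,) = set(e) - {cell_id}
                out.add(other)
        return out


def delaunay_neighbors(ids, positions, frame: int = 0) -> NeighborGraph:
    """Neighbour graph at one frame: edges are point pairs sharing a simplex
    of the Delaunay triangulation of the positions.

    Coplanar clouds (z-extent ~ 0) are triangulated in 2D.  With fewer than
    5 points in 3D (or 3 in 2D), or a configuration Qhull rejects as
    degenerate, a deterministic k-nearest-neighbour graph with
    k = min(6, n-1) is used instead and marked ``knn_fallback``.
    """
    ids = list(ids)
    pts = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(ids)
    if n != len(pts):
        raise ValueError("ids and positions length mismatch")
    if n < 2:
        raise ValueError("no neighborhood definable with fewer than 2 points")
    planar = np.ptp(pts[:, 2]) <= _COPLANAR_TOL_UM
    work = pts[:, :2] if planar else pts
    min_pts = 3 if planar else 5
    edges: set[frozenset] | None = None
    construction = "delaunay"
    if n >= min_pts:
        try:
            tri = Delaunay(work)
            edges = set()
            for simplex in tri.simplices:
                for i in range(len(simplex)):
                    for j in range(i + 1, len(simplex)):
                        edges.add(frozenset((ids[simplex[i]], ids[simplex[j]])))
        except QhullError:
            edges = None
    if edges is None:
        construction = "knn_fallback"
        k = min(6, n - 1)
        tree = cKDTree(pts)
        _, nbr = tree.query(pts, k=k + 1)  # first hit is the point itself
        edges = set()
        for i in range(n):
            for j in np.atleast_1d(nbr[i])[1:]:
                if j < n and j != i:
                    edges.add(frozenset((ids[i], ids[int(j)])))
    return NeighborGraph(frame=frame, edges=frozenset(edges), construction=construction, n_points=n)


def pair_angle(u, v, eps: float = ZERO_NORM_EPS_UM) -> float:
    """Intermediate angle between two movement vectors, in degrees.

    The normalised dot product is clamped to [-1, 1] before arccos to
    absorb floating-point overshoot.  Symmetric in its arguments; raises
    :class:`UndefinedAngleError` when either vector is shorter than eps.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu <= eps or nv <= eps:
        raise UndefinedAngleError("pair angle undefined for zero-length movement vector")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass
class SimilarityResult:
    """Pairwise angles, per-cell means, and the global similarity score.

    ``global_inverted = 180 - global_raw`` exactly; the inverted score is
    the headline statistic (90 deg = random, 180 deg = coordinated).
    """

    pair_angles: pd.DataFrame  # frame, frame_next, cell_u, cell_v, angle_deg
    per_cell: pd.DataFrame     # frame, frame_next, track_id, mean_angle_deg, n_neighbors
    global_raw: float
    global_inverted: float
    convention: str = "inverted"
    n_pairs: int = 0
    excluded_pairs: int = 0
    graph_constructions: dict = field(default_factory=dict)

    @property
    def headline(self) -> float:
        return self.global_inverted if self.convention == "inverted" else self.global_raw

    def summary(self) -> dict:
        return {
            "global_raw_deg": self.global_raw,
            "global_inverted_deg": self.global_inverted,
            "convention": self.convention,
            "n_pairs": self.n_pairs,
            "n_excluded": self.excluded_pairs,
        }


class MovementSimilarity(BaseEstimator):
    """Neighbourhood movement-similarity scorer.

    Parameters
    ----------
    graph_frame : {"pair_start", "pair_end"}
        Which endpoint of each frame pair anchors the Delaunay
        triangulation (positions change between frames; default the start).
    averaging : {"pair_level", "cell_then_global"}
        ``pair_level`` averages every valid edge angle with equal weight
        ("all angles were averaged"); ``cell_then_global`` first averages
        over each cell's incident edges, then over cells.
    convention : {"inverted", "raw"}
        Which score :attr:`SimilarityResult.headline` reports.
    gap_policy : {"consecutive_recorded", "strict_frames"}
        Passed to movement-vector extraction.

    Attributes (after :meth:`fit`)
    ------------------------------
    result_ : SimilarityResult
    global_raw_, global_inverted_ : float
    pair_angles_, per_cell_ : pandas.DataFrame
    n_pairs_, n_excluded_ : int
    """

    def __init__(
        self,
        graph_frame: str = "pair_start",
        averaging: str = "pair_level",
        convention: str = "inverted",
        gap_policy: str = "consecutive_recorded",
    ):
        self.graph_frame = graph_frame
        self.averaging = averaging
        self.convention = convention
        self.gap_policy = gap_policy

    def _validate_params(self):
        if self.graph_frame not in ("pair_start", "pair_end"):
            raise ValueError(f"graph_frame must be 'pair_start' or 'pair_end', got {self.graph_frame!r}")
        if self.averaging not in ("pair_level", "cell_then_global"):
            raise ValueError(f"averaging must be 'pair_level' or 'cell_then_global', got {self.averaging!r}")
        if self.convention not in ("inverted", "raw"):
            raise ValueError(f"convention must be 'inverted' or 'raw', got {self.convention!r}")

    def fit(self, ts: TrackSet, y=None) -> "MovementSimilarity":
        """Compute pair angles and the global score for a track set."""
        self._validate_params()
        vectors = movement_vectors(ts, gap_policy=self.gap_policy)
        angle_rows = []
        excluded = 0
        constructions: dict[int, str] = {}
        if len(vectors) > 0:
            vec_lookup = {
                (r.track_id, int(r.frame), int(r.frame_next)): np.array([r.dx_um, r.dy_um, r.dz_um])
                for r in vectors.itertuples(index=False)
            }
            frame_pairs = sorted(
                {(int(f), int(fn)) for f, fn in zip(vectors["frame"], vectors["frame_next"])}
            )
            for f, fn in frame_pairs:
                anchor = f if self.graph_frame == "pair_start" else fn
                pos = ts.positions_at(anchor)
                if len(pos) < 2:
                    continue
                graph = delaunay_neighbors(pos.index, pos.to_numpy(), frame=anchor)
                constructions[anchor] = graph.construction
                for edge in graph.edges:
                    a, b = sorted(edge, key=str)
                    ua = vec_lookup.get((a, f, fn))
                    ub = vec_lookup.get((b, f, fn))
                    if ua is None or ub is None:
                        continue  # one endpoint has no step spanning this pair
                    try:
                        ang = pair_angle(ua, ub)
                    except UndefinedAngleError:
                        excluded += 1
                        continue
                    angle_rows.append((f, fn, a, b, ang))
        pair_angles = pd.DataFrame(
            angle_rows, columns=["frame", "frame_next", "cell_u", "cell_v", "angle_deg"]
        )
        if len(pair_angles) == 0:
            raise NoNeighborPairsError("no co-moving neighbor pairs")
        per_cell = _per_cell_means(pair_angles)
        if self.averaging == "pair_level":
            global_raw = float(pair_angles["angle_deg"].mean())
        else:
            global_raw = float(per_cell["mean_angle_deg"].mean())
        self.result_ = SimilarityResult(
            pair_angles=pair_angles,
            per_cell=per_cell,
            global_raw=global_raw,
            global_inverted=180.0 - global_raw,
            convention=self.convention,
            n_pairs=len(pair_angles),
            excluded_pairs=excluded,
            graph_constructions=constructions,
        )
        self.pair_angles_ = pair_angles
        self.per_cell_ = per_cell
        self.global_raw_ = global_raw
        self.global_inverted_ = 180.0 - global_raw
        self.n_pairs_ = len(pair_angles)
        self.n_excluded_ = excluded
        return self

    def score(self, ts: TrackSet | None = None) -> float:
        """Headline similarity of the fitted track set (fits ``ts`` if given)."""
        if ts is not None:
            self.fit(ts)
        return self.result_.headline


def _per_cell_means(pair_angles: pd.DataFrame) -> pd.DataFrame:
    long = pd.concat(
        [
            pair_angles.rename(columns={"cell_u": "track_id"})[["frame", "frame_next", "track_id", "angle_deg"]],
            pair_angles.rename(columns={"cell_v": "track_id"})[["frame", "frame_next", "track_id", "angle_deg"]],
        ],
        ignore_index=True,
    )
    return (
        long.groupby(["frame", "frame_next", "track_id"])["angle_deg"]
        .agg(mean_angle_deg="mean", n_neighbors="size")
        .reset_index()
    )


def similarity(
    ts: TrackSet,
    graph_frame: str = "pair_start",
    averaging: str = "pair_level",
    convention: str = "inverted",
    gap_policy: str = "consecutive_recorded",
) -> SimilarityResult:
    """Functional wrapper over :class:`MovementSimilarity`."""
    est = MovementSimilarity(
        graph_frame=graph_frame, averaging=averaging,
        convention=convention, gap_policy=gap_policy,
    )
    return est.fit(ts).result_


def similarity_map(result: SimilarityResult, ts: TrackSet | None = None) -> pd.DataFrame:
    """Per-cell, per-frame-pair table for colour-mapping trajectories.

    Columns: ``frame, track_id, mean_angle_deg, inverted_deg, n_neighbors``.
    If ``ts`` is given, cells that moved on a frame pair but had no valid
    neighbour edge are emitted too, with ``n_neighbors = 0`` and NaN angles.
    """
    per_cell = result.per_cell.copy()
    per_cell["inverted_deg"] = 180.0 - per_cell["mean_angle_deg"]
    out = per_cell[["frame", "frame_next", "track_id", "mean_angle_deg", "inverted_deg", "n_neighbors"]]
    if ts is not None:
        vectors = movement_vectors(ts)
        moved = vectors[["frame", "frame_next", "track_id"]].drop_duplicates()
        merged = moved.merge(out, on=["frame", "frame_next", "track_id"], how="left")
        merged["n_neighbors"] = merged["n_neighbors"].fillna(0).astype(int)
        out = merged
    return out.sort_values(["frame", "track_id"], kind="mergesort").reset_index(drop=True)
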