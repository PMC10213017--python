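"""Delaunay neighbour graphs and the movement-similarity angle statistic."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from migkit import (
    MovementSimilarity,
    NoNeighborPairsError,
    TrackSet,
    UndefinedAngleError,
    delaunay_neighbors,
    pair_angle,
    similarity,
    similarity_map,
)
from migkit.simulate import SimulationParams, simulate

from conftest import make_trackset, random_rotation


# ---------------------------------------------------------------- pair_angle

@pytest.mark.parametrize("u, v, expected", [
    ((1, 0, 0), (2, 0, 0), 0.0),        # parallel
    ((1, 0, 0), (0, 1, 0), 90.0),       # orthogonal
    ((1, 0, 0), (-1, 0, 0), 180.0),     # antiparallel
    ((1, 1, 0), (1, 0, 0), 45.0),       # diagonal
    ((3, 4, 0), (0, -5, 0), 143.13010235415598),  # arccos(-0.8)
])
def test_pair_angle_hand_cases(u, v, expected):
    assert pair_angle(u, v) == pytest.approx(expected, abs=1e-12)
    assert pair_angle(v, u) == pytest.approx(expected, abs=1e-12)


def test_pair_angle_clamps_numerical_overshoot():
    # normalised dot product of a vector with itself can exceed 1 by an ulp
    u = np.array([0.1, 0.2, 0.30000000000000004])
    assert pair_angle(u, u) == 0.0
    assert pair_angle(u, -u) == 180.0


def test_pair_angle_zero_vector_is_undefined():
    with pytest.raises(UndefinedAngleError):
        pair_angle((0, 0, 0), (1, 0, 0))
    with pytest.raises(UndefinedAngleError):
        pair_angle((1, 0, 0), (1e-12, 0, 0))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(-100, 100), min_size=3, max_size=3),
    st.lists(st.floats(-100, 100), min_size=3, max_size=3),
    st.floats(0.01, 1000),
)
def test_pair_angle_symmetric_and_scale_free(u, v, s):
    u, v = np.array(u), np.array(v)
    if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
        return
    a = pair_angle(u, v)
    assert 0.0 <= a <= 180.0
    assert pair_angle(v, u) == pytest.approx(a, abs=1e-9)
    assert pair_angle(s * u, v) == pytest.approx(a, abs=1e-7)


def test_pair_angle_rotation_invariant():
    rng = np.random.default_rng(4)
    for _ in range(20):
        u, v = rng.standard_normal((2, 3))
        R = random_rotation(rng)
        assert pair_angle(R @ u, R @ v) == pytest.approx(pair_angle(u, v), abs=1e-8)


# ------------------------------------------------------------ neighbor graph

def test_tetrahedron_is_complete_graph():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0.3, 0.3, 0.3]])
    g = delaunay_neighbors(list("abcde"), pts)
    assert g.construction == "delaunay"
    # 5 points, interior point connects to all: at minimum the hull edges exist
    assert frozenset(("a", "b")) in g.edges


def test_single_tetrahedron_all_pairs():
    pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10], [2, 2, 2]])
    g = delaunay_neighbors(range(5), pts)
    assert g.n_points == 5


def test_two_points_knn_fallback_single_edge():
    g = delaunay_neighbors(["a", "b"], np.array([[0, 0, 0], [1, 1, 1]]))
    assert g.construction == "knn_fallback"
    assert g.edges == frozenset({frozenset(("a", "b"))})


def test_collinear_points_fall_back_deterministically():
    pts = np.array([[float(i), 0, 0] for i in range(6)])
    g1 = delaunay_neighbors(range(6), pts)
    g2 = delaunay_neighbors(range(6), pts)
    assert g1.construction == "knn_fallback"
    assert g1.edges == g2.edges


def test_fewer_than_two_points_rejected():
    with pytest.raises(ValueError, match="fewer than 2"):
        delaunay_neighbors(["a"], np.array([[0, 0, 0]]))


def test_coplanar_cloud_triangulated_in_2d():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.random((10, 2)) * 100, np.zeros(10)])
    g = delaunay_neighbors(range(10), pts)
    assert g.construction == "delaunay"


def _brute_delaunay_edges(pts):
    """Empty-circumsphere enumeration of Delaunay simplices (independent of
    scipy.spatial.Delaunay; linear algebra only)."""
    pts = np.asarray(pts, float)
    n, dim = pts.shape
    edges = set()
    for simplex in combinations(range(n), dim + 1):
        P = pts[list(simplex)]
        A = 2 * (P[1:] - P[0])
        b = (P[1:] ** 2).sum(axis=1) - (P[0] ** 2).sum()
        try:
            center = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        r2 = ((P[0] - center) ** 2).sum()
        d2 = ((pts - center) ** 2).sum(axis=1)
        others = np.ones(n, bool)
        others[list(simplex)] = False
        if (d2[others] < r2 * (1 - 1e-9)).any():
            continue
        for i, j in combinations(simplex, 2):
            edges.add(frozenset((i, j)))
    return edges


@pytest.mark.parametrize("seed", range(5))
def test_delaunay_edges_match_brute_force_3d(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 14))
    pts = rng.random((n, 3)) * 100
    g = delaunay_neighbors(range(n), pts)
    assert g.construction == "delaunay"
    assert set(g.edges) == _brute_delaunay_edges(pts)


@pytest.mark.parametrize("seed", range(3))
def test_delaunay_edges_match_brute_force_2d(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(6, 12))
    pts = np.column_stack([rng.random((n, 2)) * 100, np.zeros(n)])
    g = delaunay_neighbors(range(n), pts)
    assert set(g.edges) == _brute_delaunay_edges(pts[:, :2])


# ---------------------------------------------------------------- similarity

def test_identical_drift_scores_exactly_180():
    ts = make_trackset({
        tid: [(x0 + 2.0 * f, y0 + 3.0 * f, 1.0 * f) for f in range(5)]
        for tid, (x0, y0) in {"a": (0, 0), "b": (30, 0), "c": (0, 30), "d": (40, 40)}.items()
    })
    res = similarity(ts)
    assert (res.pair_angles["angle_deg"] == 0).all()
    assert res.global_raw == 0.0
    assert res.global_inverted == 180.0


def test_two_orthogonal_cells():
    ts = make_trackset({
        "a": [(0, 0, 0), (1, 0, 0)],
        "b": [(10, 0, 0), (10, 1, 0)],
    })
    res = similarity(ts)
    assert res.n_pairs == 1
    assert res.global_raw == pytest.approx(90.0, abs=1e-12)
    assert res.global_inverted == pytest.approx(90.0, abs=1e-12)


def test_isotropic_random_walk_scores_near_90():
    """Monte-Carlo check of the analytic E[alpha] = 90 deg for isotropic steps."""
    ts, _ = simulate(SimulationParams(model="random_walk", n_cells=200, n_frames=30, seed=123))
    res = similarity(ts)
    assert res.global_inverted == pytest.approx(90.0, abs=1.0)


def test_inverted_is_180_minus_raw_exactly():
    ts, _ = simulate(SimulationParams(model="collective", n_cells=30, n_frames=8,
                                      coordination=0.5, seed=2))
    res = similarity(ts)
    assert res.global_inverted == 180.0 - res.global_raw


def test_rigid_motion_and_scaling_leave_angles_unchanged():
    ts, _ = simulate(SimulationParams(model="collective", n_cells=20, n_frames=6,
                                      coordination=0.6, seed=8, boundary="none"))
    base = similarity(ts).pair_angles.set_index(["frame", "cell_u", "cell_v"])["angle_deg"]
    rng = np.random.default_rng(8)
    R = random_rotation(rng)
    xyz = ts.data[["x_um", "y_um", "z_um"]].to_numpy()
    for transform in [xyz + [500.0, -200.0, 30.0], xyz @ R.T, xyz * 3.7]:
        moved = ts.data.copy()
        moved[["x_um", "y_um", "z_um"]] = transform
        got = similarity(TrackSet(moved, ts.frame_interval)).pair_angles
        got = got.set_index(["frame", "cell_u", "cell_v"])["angle_deg"]
        # rigid motions and uniform scaling preserve the Delaunay graph too
        assert set(got.index) == set(base.index)
        np.testing.assert_allclose(got[base.index], base, atol=1e-6)


def test_pipeline_angles_equal_direct_formula():
    """Oracle: every reported angle equals the three-term arccos evaluated
    directly from the raw coordinates, to 1e-9 degrees."""
    ts, _ = simulate(SimulationParams(model="collective", n_cells=50, n_frames=20,
                                      coordination=0.4, seed=77))
    res = similarity(ts)
    pos = {
        (r.track_id, r.frame): np.array([r.x_um, r.y_um, r.z_um])
        for r in ts.data.itertuples(index=False)
    }
    for r in res.pair_angles.itertuples(index=False):
        u = pos[(r.cell_u, r.frame_next)] - pos[(r.cell_u, r.frame)]
        v = pos[(r.cell_v, r.frame_next)] - pos[(r.cell_v, r.frame)]
        num = u[0] * v[0] + u[1] * v[1] + u[2] * v[2]
        den = np.sqrt((u ** 2).sum()) * np.sqrt((v ** 2).sum())
        expected = np.degrees(np.arccos(np.clip(num / den, -1, 1)))
        assert r.angle_deg == pytest.approx(expected, abs=1e-9)


def test_stationary_neighbors_excluded_not_poisoned():
    ts = make_trackset({
        "a": [(0, 0, 0), (1, 0, 0)],
        "b": [(10, 0, 0), (11, 0, 0)],
        "c": [(5, 8, 0), (5, 8, 0)],   # stationary: zero-length vector
    })
    res = similarity(ts)
    assert res.n_pairs == 1            # only a-b survives
    assert res.excluded_pairs == 2     # a-c and b-c dropped
    assert res.global_inverted == 180.0


def test_no_valid_pairs_raises():
    ts = make_trackset({"a": [(0, 0, 0)] * 3, "b": [(5, 5, 0)] * 3})
    with pytest.raises(NoNeighborPairsError, match="no co-moving"):
        similarity(ts)


def test_averaging_and_graph_frame_options():
    ts, _ = simulate(SimulationParams(model="collective", n_cells=25, n_frames=6,
                                      coordination=0.5, seed=3))
    flat = similarity(ts, averaging="pair_level")
    cellwise = similarity(ts, averaging="cell_then_global")
    assert flat.global_raw != cellwise.global_raw  # different weightings in general
    anchored_end = similarity(ts, graph_frame="pair_end")
    assert anchored_end.n_pairs > 0


def test_estimator_api():
    from sklearn.base import clone
    est = MovementSimilarity(convention="raw")
    params = est.get_params()
    assert params["convention"] == "raw"
    cloned = clone(est)
    assert cloned.get_params() == params
    ts = make_trackset({"a": [(0, 0, 0), (1, 0, 0)], "b": [(5, 0, 0), (6, 0, 0)]})
    est.fit(ts)
    assert est.global_inverted_ == 180.0
    assert est.score() == est.global_raw_   # raw convention headline
    with pytest.raises(ValueError, match="convention"):
        MovementSimilarity(convention="bogus").fit(ts)


# ------------------------------------------------------------ similarity_map

def test_similarity_map_mover_without_valid_edges_gets_zero_neighbors():
    # frame pair (0,1): a and b move (one valid edge); frame pair (1,2):
    # only c moves, so c appears with no valid neighbours
    ts = make_trackset({
        "a": [(0, 0, 0), (1, 0, 0), (1, 0, 0)],
        "b": [(10, 0, 0), (11, 0, 0), (11, 0, 0)],
        "c": [(5, 8, 0), (5, 8, 0), (5, 9, 0)],
    })
    res = similarity(ts)
    table = similarity_map(res, ts)
    c_row = table[(table.track_id == "c") & (table.frame == 1)]
    assert len(c_row) == 1
    assert c_row.n_neighbors.item() == 0
    assert np.isnan(c_row.mean_angle_deg.item())
    a_row = table[(table.track_id == "a") & (table.frame == 0)]
    assert a_row.n_neighbors.item() == 1
    assert a_row.inverted_deg.item() == pytest.approx(180.0)


def test_similarity_map_coordinated_all_180(toy):
    ts = make_trackset({
        "a": [(0, 0, 0), (1, 0, 0), (2, 0, 0)],
        "b": [(10, 0, 0), (11, 0, 0), (12, 0, 0)],
    })
    table = similarity_map(similarity(ts))
    assert (table["inverted_deg"] == 180.0).all()


def test_mixed_cohorts_cohort_scores_higher():
    """Labelled synthetic data: coordinated cells' mean inverted similarity
    exceeds the random cells'."""
    from migkit import make_fixture
    ts, labels = make_fixture("mixed_cohorts")
    res = similarity(ts)
    table = similarity_map(res, ts)
    merged = table.merge(labels[["track_id", "model"]], on="track_id")
    means = merged.groupby("model")["inverted_deg"].mean()
    assert means["collective"] > means["random_walk"]
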