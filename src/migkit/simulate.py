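"""Seeded synthetic cell tracks with ground-truth labels.

Three motility models cover the statistical regimes the analysis is built
to distinguish:

``collective``
    Fibroblast-like directed migration.  Each step points along a convex
    blend of a drift direction (toward the scar centre by default, or a
    fixed global axis via ``drift_direction``) and an isotropic noise
    direction, weighted by ``coordination`` in [0, 1]; the blended
    direction is renormalised so every motile step has magnitude
    ``speed_mean * frame_interval``, making speed coordination-invariant
    and leaving the neighbour-angle statistic as the discriminating
    signal.

``random_walk``
    I.i.d. isotropic steps of fixed magnitude (uniform directions on the
    sphere from normalised Gaussian triples).

``intermittent``
    Adipocyte-like stop-and-go motion: a per-cell two-state Markov chain
    switches between a stationary state (zero step) and a motile state
    that keeps a persistent random heading for the duration of each bout.

Positions are confined to a box arena emulating a Ø 2 mm explant
(clipping at the walls, with clipped cells flagged, since clipping
distorts angles locally).  Identical parameters and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import RegionOfInterest, TrackSet

MODELS = ("collective", "random_walk", "intermittent")

DEFAULT_ARENA = RegionOfInterest(x=(0.0, 2000.0), y=(0.0, 2000.0), z=(0.0, 100.0))
DEFAULT_SPEED_UM_PER_MIN = 0.3  # fibroblast-scale crawling speed


class SimulationParameterError(ValueError):
    pass


@dataclass
class SimulationParams:
    """Parameters of one synthetic track-set simulation.

    switch_rates are the per-frame transition probabilities
    (stationary->motile, motile->stationary) of the intermittent model;
    p_initial_motile is the probability a cell starts in the motile state.
    """

    model: str = "random_walk"
    n_cells: int = 100
    n_frames: int = 20
    frame_interval: float = 15.0
    arena: RegionOfInterest = field(default_factory=lambda: DEFAULT_ARENA)
    scar_center: tuple[float, float, float] | None = None  # default: arena centre
    speed_mean: float = DEFAULT_SPEED_UM_PER_MIN
    coordination: float = 0.8
    drift_direction: tuple[float, float, float] | None = None
    switch_rates: tuple[float, float] = (0.2, 0.2)
    p_initial_motile: float = 0.5
    boundary: str = "clip"
    seed: int = 0

    def __post_init__(self):
        self.validate()
        if self.scar_center is None:
            a = self.arena
            z = a.z if a.z is not None else (0.0, 0.0)
            self.scar_center = (
                (a.x[0] + a.x[1]) / 2, (a.y[0] + a.y[1]) / 2, (z[0] + z[1]) / 2,
            )

    def validate(self):
        if self.model not in MODELS:
            raise SimulationParameterError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.n_cells < 2:
            raise SimulationParameterError(f"n_cells must be >= 2, got {self.n_cells}")
        if self.n_frames < 2:
            raise SimulationParameterError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.frame_interval <= 0:
            raise SimulationParameterError(f"frame_interval must be > 0, got {self.frame_interval}")
        if self.speed_mean <= 0:
            raise SimulationParameterError(f"speed_mean must be > 0, got {self.speed_mean}")
        if not 0.0 <= self.coordination <= 1.0:
            raise SimulationParameterError(f"coordination must be in [0, 1], got {self.coordination}")
        for name, p in (("switch_rates[0]", self.switch_rates[0]),
                        ("switch_rates[1]", self.switch_rates[1]),
                        ("p_initial_motile", self.p_initial_motile)):
            if not 0.0 <= p <= 1.0:
                raise SimulationParameterError(f"{name} must be a probability in [0, 1], got {p}")
        if self.boundary not in ("clip", "none"):
            raise SimulationParameterError(f"boundary must be 'clip' or 'none', got {self.boundary!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arena"] = {"x": list(self.arena.x), "y": list(self.arena.y),
                      "z": list(self.arena.z) if self.arena.z is not None else None}
        return d


def _unit_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform directions on the unit sphere (normalised Gaussian triples)."""
    v = rng.standard_normal((n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # resample any numerically-degenerate draw
    while (norm < 1e-12).any():
        bad = norm[:, 0] < 1e-12
        v[bad] = rng.standard_normal((bad.sum(), 3))
        norm = np.linalg.norm(v, axis=1, keepdims=True)
    return v / norm


def _initial_positions(rng: np.random.Generator, n: int, arena: RegionOfInterest) -> np.ndarray:
    lo = np.array([arena.x[0], arena.y[0], arena.z[0] if arena.z else 0.0])
    hi = np.array([arena.x[1], arena.y[1], arena.z[1] if arena.z else 0.0])
    return lo + rng.random((n, 3)) * (hi - lo)


def simulate(
    params: SimulationParams,
    initial_positions: np.ndarray | None = None,
) -> tuple[TrackSet, pd.DataFrame]:
    """Generate one synthetic TrackSet plus its ground-truth label table.

    The label table has one row per track: ``track_id, model,
    intended_class`` (movement class guaranteed by construction, empty
    when not determinable), ``boundary_contact`` (True when arena clipping
    altered the trajectory), and ``states`` (the S/M state string of the
    intermittent chain, empty otherwise).

    ``initial_positions`` overrides the uniform-in-arena spawn (used by
    deterministic fixtures).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, T = params.n_cells, params.n_frames
    dt = params.frame_interval
    step_len = params.speed_mean * dt
    scar = np.asarray(params.scar_center, dtype=float)

    if initial_positions is None:
        pos = _initial_positions(rng, n, params.arena)
    else:
        pos = np.asarray(initial_positions, dtype=float).reshape(n, 3).copy()
    positions = np.empty((T, n, 3))
    positions[0] = pos
    clipped = np.zeros(n, dtype=bool)
    states = np.empty((T - 1, n), dtype="U1") if params.model == "intermittent" else None

    if params.model == "intermittent":
        motile = rng.random(n) < params.p_initial_motile
        headings = _unit_sphere(rng, n)
    drift_axis = None
    if params.drift_direction is not None:
        drift_axis = np.asarray(params.drift_direction, dtype=float)
        norm = np.linalg.norm(drift_axis)
        if norm <= 0:
            raise SimulationParameterError("drift_direction must be a nonzero vector")
        drift_axis = drift_axis / norm

    p_sm, p_ms = params.switch_rates
    for t in range(1, T):
        cur = positions[t - 1]
        if params.model == "random_walk":
            step = _unit_sphere(rng, n) * step_len
        elif params.model == "collective":
            if drift_axis is not None:
                drift = np.broadcast_to(drift_axis, (n, 3)).copy()
                dist = np.full(n, np.inf)
            else:
                to_scar = scar - cur
                dist = np.linalg.norm(to_scar, axis=1)
                drift = np.where(dist[:, None] > 1e-12, to_scar / np.maximum(dist, 1e-12)[:, None], 0.0)
            c = params.coordination
            if c >= 1.0:
                direction = drift
            else:
                noise = _unit_sphere(rng, n)
                blend = c * drift + (1 - c) * noise
                bn = np.linalg.norm(blend, axis=1, keepdims=True)
                # antipodal cancellation is a measure-zero draw; fall back to noise
                direction = np.where(bn > 1e-12, blend / np.maximum(bn, 1e-12), noise)
            step = direction * step_len
            # do not overshoot the scar under pure drift: arrive and stay
            arriving = dist < step_len
            if arriving.any():
                if c >= 1.0 and drift_axis is None:
                    step[arriving] = scar - cur[arriving]
        else:  # intermittent
            step = np.where(motile[:, None], headings * step_len, 0.0)
            states[t - 1] = np.where(motile, "M", "S")
            switch = rng.random(n)
            to_motile = ~motile & (switch < p_sm)
            to_stationary = motile & (switch < p_ms)
            if to_motile.any():
                headings[to_motile] = _unit_sphere(rng, int(to_motile.sum()))
            motile = (motile & ~to_stationary) | to_motile
        new = cur + step
        if params.boundary == "clip":
            lo = np.array([params.arena.x[0], params.arena.y[0],
                           params.arena.z[0] if params.arena.z else -np.inf])
            hi = np.array([params.arena.x[1], params.arena.y[1],
                           params.arena.z[1] if params.arena.z else np.inf])
            clipped_new = np.clip(new, lo, hi)
            clipped |= (clipped_new != new).any(axis=1)
            new = clipped_new
        positions[t] = new

    ids = [f"sim_{i:04d}" for i in range(n)]
    rows = {
        "track_id": np.repeat(ids, T),
        "frame": np.tile(np.arange(T), n),
        "time_min": np.tile(np.arange(T) * dt, n),
        "x_um": positions[:, :, 0].T.ravel(),
        "y_um": positions[:, :, 1].T.ravel(),
        "z_um": positions[:, :, 2].T.ravel(),
    }
    ts = TrackSet(pd.DataFrame(rows), frame_interval=dt,
                  meta={"simulated": True, "params": params.to_dict()})
    labels = pd.DataFrame({
        "track_id": ids,
        "model": params.model,
        "intended_class": [_intended_class(params, positions[0, i], clipped[i]) for i in range(n)],
        "boundary_contact": clipped,
        "states": ["".join(states[:, i]) for i in range(n)] if states is not None else "",
    })
    return ts, labels


def _intended_class(params: SimulationParams, start: np.ndarray, was_clipped: bool) -> str:
    """Movement class guaranteed by construction, or '' when stochastic."""
    if was_clipped:
        return ""
    if params.model == "intermittent" and params.switch_rates[0] == 0 and params.p_initial_motile == 0:
        return "minimal"
    if params.model == "collective" and params.coordination >= 1.0 and params.drift_direction is None:
        # pure drift toward the scar: endpoint is closed-form
        d0 = float(np.linalg.norm(np.asarray(params.scar_center) - start))
        travel = min(d0, params.speed_mean * params.frame_interval * (params.n_frames - 1))
        return "toward_scar" if travel >= 5.0 else "minimal"
    return ""


FIXTURES = ("coordinated_pure", "random_pure", "mixed_cohorts", "toy_printed")


def make_fixture(name: str, **overrides) -> tuple[TrackSet, pd.DataFrame]:
    """Deterministic small TrackSets for tests and demos.

    ``toy_printed`` is a hand-written 3-cell, 4-frame set whose every
    statistic is hand-computable; see :func:`toy_printed_expectations`.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    if name == "toy_printed":
        return _toy_printed()
    if name == "coordinated_pure":
        grid = np.array([
            [50.0 * i, 50.0 * j, 0.0] for i in range(4) for j in range(4)
        ])
        p = SimulationParams(
            model="collective", n_cells=16, n_frames=10, coordination=1.0,
            drift_direction=(1.0, 0.0, 0.0), boundary="none",
            scar_center=(5000.0, 75.0, 0.0), seed=overrides.pop("seed", 3),
            **overrides,
        )
        ts, labels = simulate(p, initial_positions=grid)
        # moving +x toward a scar far along +x: toward_scar by construction
        labels["intended_class"] = "toward_scar"
        return ts, labels
    if name == "random_pure":
        p = SimulationParams(
            model="random_walk",
            n_cells=overrides.pop("n_cells", 12),
            n_frames=overrides.pop("n_frames", 8),
            seed=overrides.pop("seed", 7),
            **overrides,
        )
        return simulate(p)
    # mixed_cohorts: spatially interleaved coordinated + random cells
    seed = overrides.pop("seed", 11)
    n_each = overrides.pop("n_each", 20)
    n_frames = overrides.pop("n_frames", 15)
    coll, lab_c = simulate(SimulationParams(
        model="collective", n_cells=n_each, n_frames=n_frames,
        coordination=0.9, seed=seed, **overrides))
    rand, lab_r = simulate(SimulationParams(
        model="random_walk", n_cells=n_each, n_frames=n_frames,
        seed=seed + 1, **overrides))
    def _prefix(df, tag):
        df = df.copy()
        df["track_id"] = tag + df["track_id"].astype(str)
        return df
    data = pd.concat([_prefix(coll.data, "coll_"), _prefix(rand.data, "rand_")],
                     ignore_index=True)
    labels = pd.concat([_prefix(lab_c, "coll_"), _prefix(lab_r, "rand_")],
                       ignore_index=True)
    ts = TrackSet(data, frame_interval=coll.frame_interval,
                  meta={"simulated": True, "fixture": "mixed_cohorts"})
    return ts, labels


def _toy_printed() -> tuple[TrackSet, pd.DataFrame]:
    rows = []
    # A and B translate by (3, 4, 0) each frame (5 um steps, 3-4-5 triangle);
    # C moves straight down by (0, -5, 0).
    for f in range(4):
        rows.append(("A", f, 15.0 * f, 0.0 + 3.0 * f, 0.0 + 4.0 * f, 0.0))
        rows.append(("B", f, 15.0 * f, 100.0 + 3.0 * f, 0.0 + 4.0 * f, 0.0))
        rows.append(("C", f, 15.0 * f, 50.0, 80.0 - 5.0 * f, 0.0))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "time_min", "x_um", "y_um", "z_um"])
    ts = TrackSet(df, frame_interval=15.0, meta={"fixture": "toy_printed"})
    labels = pd.DataFrame({
        "track_id": ["A", "B", "C"],
        "model": "toy",
        "intended_class": ["toward_scar", "away_from_scar", "toward_scar"],
        "boundary_contact": False,
        "states": "",
    })
    return ts, labels


def toy_printed_expectations() -> dict:
    """Hand-computed ground truth for the toy_printed fixture.

    Every value below was derived by hand before the pipeline existed:
    steps are 3-4-5 triangles or axis-aligned 5 um moves; the three cells
    form a triangle at every frame so the Delaunay graph is complete; the
    A-C and B-C angle is arccos(-20 / 25) = arccos(-0.8).
    """
    angle_ac = 143.13010235415598  # degrees, = arccos(-0.8)
    global_raw = (0.0 + 2 * angle_ac) / 3  # edges AB, AC, BC each frame pair
    return {
        "scar_center_um": (50.0, 40.0, 0.0),
        "n_frame_pairs": 3,
        "step_magnitude_um": 5.0,
        "speed_um_per_min": 5.0 / 15.0,
        "summed_mean_displacement_um": [5.0, 10.0, 15.0],
        "edges_per_frame": [{"A", "B"}, {"A", "C"}, {"B", "C"}],
        "pair_angle_deg": {("A", "B"): 0.0, ("A", "C"): angle_ac, ("B", "C"): angle_ac},
        "global_raw_deg": global_raw,          # 95.420068...
        "global_inverted_deg": 180.0 - global_raw,  # 84.579932...
        "classes": {"A": "toward_scar", "B": "away_from_scar", "C": "toward_scar"},
        "fractions": {"toward_scar": 2 / 3, "away_from_scar": 1 / 3, "minimal": 0.0},
    }
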