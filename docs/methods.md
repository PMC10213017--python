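# Methods

## Data model

A *track* is the time-ordered position sequence of one cell recovered
from time-lapse microscopy: `(track_id, frame, time_min, x_um, y_um,
z_um)`, one row per recorded time point. A *TrackSet* is a collection of
tracks sharing one frame clock with a fixed frame interval (default
15 min, the cadence of typical explant live videos). Frames must be
strictly increasing within a track; duplicate `(track_id, frame)` rows
are rejected at read time. 2D inputs are accepted by zero-filling z
(and flagging the fill in the set's metadata), since every downstream
formula reduces correctly when z components are 0.

Cropping to a spatial window (e.g. a 700 µm × 700 µm scar region) is
selection-based: a track is kept or dropped whole, never truncated, so
per-track net displacements remain well-defined. Two policies exist —
keep tracks that *start* inside the window (default, matching a cropped
field of view that is then tracked) or tracks with *any* point inside.

## Kinematics

Movement vectors are displacements between consecutive *recorded* points
of a track (default `gap_policy="consecutive_recorded"`); trackers drop
frames, and the elapsed time `dt` carries the true interval. The
alternative `strict_frames` keeps only adjacent-frame pairs, for
sensitivity checks. Instantaneous speed is magnitude/dt in µm/min
(µm/h available for display). Per-frame aggregates are taken over the
vectors whose pair starts at that frame.

The summed mean-displacement curve is the cumulative sum, over frames,
of the per-frame *mean step magnitude* — i.e. means are taken first,
then added up — which is non-decreasing by construction. The alternative
reading (mean over per-cell cumulative paths) is deliberately not the
default; the chosen order of operations matches "mean displacements,
added up".

## Neighbourhood movement similarity

For each frame pair (f, f′) the neighbourhood is recomputed from a
Delaunay triangulation of cell positions (positions change every frame).
Cells sharing a simplex are direct neighbours. The triangulation is
anchored at the pair's start frame by default (`graph_frame="pair_end"`
is available; the choice is not canonical and both are exposed).
Coplanar clouds (z-extent ≈ 0) are triangulated in 2D. Configurations
with fewer than 5 points in 3D (3 in 2D), or that the triangulation
library rejects as degenerate (collinear points), fall back to a
deterministic k-nearest-neighbour graph with k = min(6, n−1) — jittering
positions would break reproducibility.

For every edge whose two cells both moved over (f, f′), the intermediate
angle between their movement vectors is

    alpha(u, v) = arccos( (u . v) / (|u| |v|) )   in degrees.

The dot-product argument is clamped to [−1, 1] before arccos to absorb
floating-point overshoot. Zero-length vectors (stationary cells, norm
≤ 10⁻⁹ µm) have no direction; such pairs are excluded and counted
(`n_excluded`) rather than assigned an arbitrary angle.

All pair angles are averaged into one score. Default averaging is
`pair_level` (every valid edge angle weighted equally — the flat reading
of "all angles averaged"); `cell_then_global` (per-cell means first,
then the grand mean) is exposed because the pooling order is a genuine
free choice. The headline score is the *inverted* value 180° − mean α,
which ranges from ≈ 90° for random motion (for isotropic 3D directions
cos α is uniform on [−1, 1], so E[α] = 90°) to 180° for perfectly
coordinated motion. An alternative display convention runs 0°
(coordinated) to 90° (random) on the raw scale; both `raw` and
`inverted` are reported in every summary, and the convention used is
recorded, because the two conventions are easily conflated.

Exact endpoints and floating point: the score is exactly 180° only when
every cosine evaluates to exactly 1, which holds when parallel steps are
exactly representable (e.g. axis-aligned drift). Generic parallel
vectors land within ~10⁻⁶ degrees of the endpoint.

## Directionality

Each track with ≥ 2 points is classified by its net displacement
d = (last − first): if |d| < 5 µm the track is `minimal`; otherwise it is
`toward_scar` when the Euclidean distance to the scar centre strictly
decreases from first to last point, else `away_from_scar`. A track whose
distance is exactly unchanged is therefore `away_from_scar` (it moved,
but not inward). The 5 µm gate applies to the *net* displacement by
default; a path-length option exists because "minimal movement" could be
read either way. Endpoint-based judgement mirrors manual annotation of
start/end positions; a per-step majority-vote mode (`mode="stepwise"`)
is provided as an alternative. Distances are 3D by default with a
projected-2D option for thin explants. The scar centre must be supplied
(it is identified visually on real data; for synthetic data it is the
generator's drift target).

Raising the threshold can only grow the `minimal` class (monotone), and
class fractions always sum to 1 over classifiable tracks; single-point
tracks are excluded and counted.

## Synthetic track generator

The generator emulates the statistical structure of explant migration,
not its biophysics (no adhesion, ECM mechanics, or cell–cell forces, and
no morphology). Defaults: 15 min frame interval; a 2000 × 2000 × 100 µm
arena emulating a Ø 2 mm explant with the scar centre at the arena
centre; mean motile speed 0.3 µm/min (a fibroblast-scale crawling speed,
chosen as an order-of-magnitude realistic value since speed axes on real
data are instrument-dependent; it is fully configurable and no
conclusion depends on it).

Models, with every motile step of magnitude `speed_mean × dt`:

- **collective** — step direction is the renormalised convex blend
  `coordination × drift + (1 − coordination) × noise` of the drift
  direction and an isotropic unit vector. Renormalising the blend keeps
  expected speed exactly coordination-invariant, so the similarity
  angle — not speed — is the statistic that separates coordination
  levels. Drift points toward the scar centre by default; a fixed global
  axis (`drift_direction`) produces strictly parallel vectors, the
  configuration used for the exact 180° endpoint. Under pure toward-scar
  drift a cell arriving within one step of the centre stops there rather
  than overshooting.
- **random_walk** — i.i.d. directions uniform on the sphere (normalised
  Gaussian triples, the standard construction).
- **intermittent** — a per-cell two-state Markov chain
  (stationary ↔ motile, per-frame switch probabilities, default 0.2/0.2);
  each motile bout keeps one persistent random heading, stationary
  frames take zero steps. State sequences are emitted in the labels.

Positions are clipped at the arena walls (not reflected); clipping
distorts step directions locally, so wall-contacted cells are flagged in
the labels, and a `boundary="none"` option disables confinement for
calibration runs. Identical parameters and seed give bit-identical
output. Labels carry the model, the intended movement class where it is
guaranteed by construction (pure drift toward the scar, or a frozen
stationary chain), and the wall-contact flag, so downstream statistics
can be tested by label recovery.

Calibration note: mean *motile* step magnitude equals `speed_mean × dt`
by construction in all three models; for the intermittent model the
stationary zero-steps are excluded from that statement.

What passing tests on synthetic data do not show: real nuclei-detection
tracks have missed detections, track fragmentation and drift artifacts,
variable per-cell speeds, and spatially structured density — none of
which the generator produces. Results on synthetic data validate the
statistics' implementation and discriminating power, not their
robustness to imaging noise.

## Problem sizes and numerics

The validation suite runs instances up to 200 cells × 50 frames, which
gives >10⁴ neighbour-pair angles — enough for the random-walk score to
settle within 1° of 90° — and completes in seconds. The Monte-Carlo
endpoint checks fix their seeds; the Delaunay edge oracle
(empty-circumsphere enumeration) runs on 8–14 point clouds where the
O(n⁵) brute force is cheap. Angle comparisons between the pipeline and
direct formula evaluation are asserted to 10⁻⁹ degrees.

## Known limitations

- The Delaunay graph on a point cloud with cospherical ties is not
  unique; random-position inputs are in general position, but gridded
  data may produce tie-broken edge sets that differ between libraries
  (angles are unaffected in the coordinated limit).
- The intended-class label is only emitted where construction guarantees
  it; intermediate coordination levels yield stochastic classes by
  design.
- `away_from_scar` pools every non-inward mover, including exactly
  tangential motion.
- The CLI analyze pipeline requires at least one co-moving neighbour
  pair; a fully stationary field is an error, not a zero score.
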