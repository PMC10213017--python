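# migkit

Quantification of 3D cell migration from single-cell tracks, built for
time-lapse imaging of wound/explant cultures in which fibroblasts migrate
collectively toward a central scar region while adipocyte-lineage cells
move intermittently and at random.

Given track tables (one row per cell per time point, positions in µm),
migkit computes:

- **Movement vectors and velocities** — per-cell 3D displacements between
  consecutive recorded time points, instantaneous speeds (µm/min),
  per-frame means, and the summed mean-displacement curve.
- **Neighbourhood movement similarity** — per frame pair, cell
  neighbourhoods come from a Delaunay triangulation of positions (cells
  sharing a simplex are direct neighbours). For each neighbour pair with
  movement vectors *u*, *v*, the intermediate angle

  α(u, v) = arccos[ (uₓvₓ + u_yv_y + u_zv_z) / (|u| |v|) ]

  is evaluated; all angles are averaged into one score. Under the
  headline *inverted* convention (180° − mean α), isotropic random motion
  scores ≈ 90° (cos α is uniform on [−1, 1] for isotropic 3D directions)
  and perfectly coordinated motion scores 180°.
- **Directionality classification** — each track's net displacement is
  classed as `toward_scar`, `away_from_scar`, or `minimal` (net movement
  below 5 µm), relative to a supplied scar-centre coordinate.
- **Synthetic tracks** — a seeded generator for collective drift,
  isotropic random walks, and two-state (stationary/motile) intermittent
  motility, with ground-truth labels, so the whole analysis can be
  exercised and validated without imaging data.

The two analysis statistics are exposed as scikit-learn style estimators
(`MovementSimilarity`, `ScarDirectionClassifier`) with functional wrappers,
plus a `migkit` command-line pipeline.

## Worked example

Simulate a coordinated cohort (100 cells, 20 frames at 15 min/frame,
coordination 0.9) and analyse it:

```sh
migkit simulate --model collective --coordination 0.9 \
    --n-cells 100 --n-frames 20 --seed 4 --out demo.csv
migkit analyze demo.csv --out-dir demo_out --scar-center 1000,1000,50
```

The analyze command prints the similarity summary and writes
`demo_out/report.json` plus per-table CSVs:

```json
{"convention": "inverted", "global_inverted_deg": 149.5270049098333,
 "global_raw_deg": 30.472995090166705, "n_excluded": 0, "n_pairs": 11878}
```

Read: over 11,878 neighbour-pair angles the mean intermediate angle was
30.5°, i.e. an inverted similarity of 149.5° — far above the ≈ 90° of
random motion, as expected for a cohort whose steps are 90% drift. The
report also shows every track classified `toward_scar` (fraction 1.0), a
mean speed of 0.3 µm/min, and a summed mean displacement of 85.5 µm over
the 19 frame intervals.

The same pipeline runs on real exports: use `--dialect imaris` for
position tables with `Position X/Y/Z`, `Time`, `TrackID` columns, and
`--roi xmin,xmax,ymin,ymax` to crop e.g. a 700 µm × 700 µm scar window.

Library equivalent:

```python
from migkit import SimulationParams, simulate, similarity

ts, labels = simulate(SimulationParams(model="collective",
                                       coordination=0.9, n_cells=100,
                                       n_frames=20, seed=4))
print(similarity(ts).global_inverted)
```

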