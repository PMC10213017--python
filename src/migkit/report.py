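"""Machine-readable analysis report: assembly and schema validation.

The report captures everything needed to reproduce a run — an input
digest, the resolved configuration, the seed — alongside the kinematics,
similarity and directionality summaries.  A JSON schema for the report
ships with the package (``schemas/report.schema.json``) and is checked by
a small built-in validator covering the keyword subset the schema uses.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from . import __version__
from .io import TrackSet
from .kinematics import frame_speed_summary, movement_vectors, summed_mean_displacement
from .similarity import SimilarityResult


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_report(
    ts: TrackSet,
    input_path,
    sim_result: SimilarityResult,
    directionality: dict,
    config: dict,
    seed: int | None = None,
) -> dict:
    vectors = movement_vectors(ts, gap_policy=config.get("gap_policy", "consecutive_recorded"))
    speeds = frame_speed_summary(vectors)
    smd = summed_mean_displacement(vectors)
    frac = directionality["summary"]
    report = {
        "schema": "migkit-analysis-report/1",
        "software": {"name": "migkit", "version": __version__},
        "seed": seed,
        "config": config,
        "input": {
            "path": str(input_path),
            "sha256": file_digest(input_path),
            "n_tracks": int(ts.n_tracks),
            "n_frames": int(len(ts.frames)),
            "n_points": int(len(ts.data)),
            "frame_interval_min": float(ts.frame_interval),
        },
        "kinematics": {
            "n_vectors": int(len(vectors)),
            "mean_speed_um_per_min": float(vectors["magnitude_um"].div(vectors["dt_min"]).mean())
            if len(vectors) else 0.0,
            "per_frame_mean_speed": {
                str(int(r.frame)): float(r.mean_speed) for r in speeds.itertuples(index=False)
            },
            "summed_mean_displacement_um": [float(v) for v in smd["cumulative_um"]],
        },
        "similarity": {k: (float(v) if isinstance(v, float) else v)
                       for k, v in sim_result.summary().items()},
        "directionality": {
            "classes": {
                str(r.movement_class): {"count": int(r.count), "fraction": float(r.fraction)}
                for r in frac.itertuples(index=False)
            },
            "n_classified": int(directionality["n_classified"]),
            "n_excluded_single_point": int(directionality["n_excluded_single_point"]),
            "min_movement_um": float(directionality["min_movement_um"]),
            "scar_center_um": [float(v) for v in directionality["scar_center_um"]],
        },
    }
    return report


def load_schema() -> dict:
    with resources.files("migkit").joinpath("schemas/report.schema.json").open() as fh:
        return json.load(fh)


_TYPES = {
    "object": dict, "array": list, "string": str,
    "boolean": bool, "integer": int,
}


def _check(obj, schema, path, errors):
    typ = schema.get("type")
    if typ is not None:
        if typ == "number":
            ok = isinstance(obj, (int, float)) and not isinstance(obj, bool)
        elif typ == "integer":
            ok = isinstance(obj, int) and not isinstance(obj, bool)
        elif isinstance(typ, list):
            ok = any(_type_ok(obj, t) for t in typ)
        else:
            ok = _type_ok(obj, typ)
        if not ok:
            errors.append(f"{path}: expected type {typ}, got {type(obj).__name__}")
            return
    if "enum" in schema and obj not in schema["enum"]:
        errors.append(f"{path}: {obj!r} not in enum {schema['enum']}")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                errors.append(f"{path}: missing required key '{key}'")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check(obj[key], sub, f"{path}.{key}", errors)
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            known = set(schema.get("properties", {}))
            for key in obj:
                if key not in known:
                    _check(obj[key], extra, f"{path}.{key}", errors)
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            _check(item, schema["items"], f"{path}[{i}]", errors)


def _type_ok(obj, typ):
    if typ == "number":
        return isinstance(obj, (int, float)) and not isinstance(obj, bool)
    if typ == "null":
        return obj is None
    py = _TYPES.get(typ)
    return py is not None and isinstance(obj, py) and not (py is int and isinstance(obj, bool))


def validate_report(report: dict, schema: dict | None = None) -> list[str]:
    """Return a list of schema violations (empty when the report is valid)."""
    if schema is None:
        schema = load_schema()
    errors: list[str] = []
    _check(report, schema, "$", errors)
    return errors
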