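"""File formats: point and unit-count CSVs, scheme and map tables, experiment
configuration files and run manifests.

All tables are plain comma-separated UTF-8 with a header row and '.' decimal
separator; coordinates are unitless planar values (no CRS handling).
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, fields

import numpy as np
import pandas as pd
import yaml

from .aggregation import AggregationScheme
from .mapping import CaseSet, PaletteCalibration, RiskMap
from .reference import DiscreteReference
from .regions import StudyRegion
from .simulate import ExperimentConfig

__all__ = [
    "read_points_csv",
    "write_points_csv",
    "read_unit_table",
    "write_unit_table",
    "write_scheme_csv",
    "read_scheme_csv",
    "write_riskmap_csv",
    "write_palette_csv",
    "load_experiment_config",
    "write_manifest",
]

UNIT_COLUMNS = ["unit_id", "centroid_x", "centroid_y", "population", "cases"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_points_csv(path) -> np.ndarray:
    """Continuous case locations: columns ``x``, ``y``, one case per row."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["x", "y"], path)
    pts = df[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(pts).all():
        bad = int(np.nonzero(~np.isfinite(pts).all(axis=1))[0][0])
        raise ValueError(f"{path}: non-finite coordinate in data row {bad + 1}")
    return pts


def write_points_csv(points, path) -> None:
    pd.DataFrame(np.atleast_2d(points), columns=["x", "y"]).to_csv(path, index=False)


def read_unit_table(path) -> tuple[pd.DataFrame, DiscreteReference, CaseSet]:
    """Aggregation-unit table: ``unit_id, centroid_x, centroid_y, population,
    cases``.

    Returns the validated table together with the discrete reference model
    (population masses, normalized) and the discrete case set (counts kept as
    reals — dispersed assignments may make them non-integer).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, UNIT_COLUMNS, path)
    if df["unit_id"].duplicated().any():
        dup = df.loc[df["unit_id"].duplicated(), "unit_id"].iloc[0]
        raise ValueError(f"{path}: duplicate unit_id {dup!r}")
    if (df["population"] < 0).any():
        raise ValueError(f"{path}: negative population")
    if (df["cases"] < 0).any():
        raise ValueError(f"{path}: negative case count")
    if df["population"].sum() <= 0:
        raise ValueError(f"{path}: total population must be positive")
    centroids = df[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    masses = df["population"].to_numpy(dtype=float)
    masses = masses / masses.sum()
    reference = DiscreteReference(centroids, masses, unit_ids=df["unit_id"].to_numpy())
    cases = CaseSet.from_counts(
        centroids, df["cases"].to_numpy(dtype=float), unit_ids=df["unit_id"].to_numpy()
    )
    return df, reference, cases


def write_unit_table(df: pd.DataFrame, path) -> None:
    df[UNIT_COLUMNS].to_csv(path, index=False)


def write_scheme_csv(scheme: AggregationScheme, path, reference: DiscreteReference | None = None) -> None:
    masses = reference.masses if reference is not None else np.full(scheme.m, np.nan)
    pd.DataFrame(
        {
            "cell_id": np.arange(scheme.m),
            "lo_x": scheme.cells[:, 0],
            "lo_y": scheme.cells[:, 1],
            "side": scheme.side_length,
            "centroid_x": scheme.centroids[:, 0],
            "centroid_y": scheme.centroids[:, 1],
            "reference_mass": masses,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_scheme_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(
        df, ["cell_id", "lo_x", "lo_y", "side", "centroid_x", "centroid_y"], path
    )
    return df


def write_riskmap_csv(risk_map: RiskMap, path) -> None:
    pd.DataFrame(
        {
            "grid_x": risk_map.grid.points[:, 0],
            "grid_y": risk_map.grid.points[:, 1],
            "score": risk_map.scores,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_palette_csv(palette: PaletteCalibration, path) -> None:
    pd.DataFrame({"level": palette.levels, "threshold": palette.thresholds}).to_csv(
        path, index=False, float_format="%.17g"
    )


def load_experiment_config(path) -> ExperimentConfig:
    """Experiment configuration from a flat key/value YAML file; unknown keys
    are rejected by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat mapping of keys to values")
    valid = {f.name for f in fields(ExperimentConfig)}
    for key in raw:
        if key not in valid:
            raise ValueError(f"{path}: unknown config key {key!r}")
    for key in ("diameters", "sides"):
        if key in raw:
            raw[key] = tuple(float(v) for v in raw[key])
    return ExperimentConfig(**raw)


def write_manifest(path, payload: dict) -> None:
    """Write a run manifest atomically (temp file + rename) as JSON."""
    payload = dict(payload)
    directory = os.path.dirname(os.fspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
            fh.write("\n")
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, StudyRegion):
        return asdict(obj)
    return str(obj)
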