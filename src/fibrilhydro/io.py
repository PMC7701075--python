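"""CSV/YAML readers and writers for the package's table schemas.

All writers emit a commented metadata header (tool version, weighting
basis, seeds, filter counts) so that processing steps remain
reconstructible from the files alone.  Readers validate schemas and
report offending rows by line number.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .auc_sweep_simulator import DetectorTrace, SpeciesSpec, SweepConfig
from .comminution_scaling import ComminutionSeries
from .distribution_engine import WeightedDistribution

__all__ = [
    "SchemaError",
    "read_afm_table",
    "read_distribution",
    "write_distribution",
    "write_trace",
    "read_sweep_config",
    "write_sweep_config",
    "read_comminution_series",
    "write_comminution_series",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def _read_csv(path: PathLike) -> tuple:
    """Read a CSV skipping '#' metadata lines; return (frame, metadata)."""
    meta = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
        else:
            break
    body = "\n".join(lines[body_start:])
    if not body.strip():
        raise SchemaError(f"{path}: no data rows found")
    frame = pd.read_csv(_io.StringIO(body))
    return frame, meta


def _meta_header(**kwargs) -> str:
    lines = [f"# fibrilhydro_version = {__version__}"]
    for key, val in kwargs.items():
        if val is not None:
            lines.append(f"# {key} = {val}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# AFM length tables
# ---------------------------------------------------------------------------

def read_afm_table(path: PathLike) -> pd.DataFrame:
    """Read an AFM table with columns ``length_nm[, height_nm]``."""
    frame, _ = _read_csv(path)
    if "length_nm" not in frame.columns:
        raise SchemaError(
            f"{path}: missing required column 'length_nm' "
            f"(found {list(frame.columns)})"
        )
    bad = frame.index[~np.isfinite(frame["length_nm"]) | (frame["length_nm"] <= 0)]
    if len(bad):
        raise SchemaError(
            f"{path}: row {int(bad[0]) + 2}: column 'length_nm' must be a "
            "positive number"
        )
    return frame


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

def write_distribution(dist: WeightedDistribution, path: PathLike) -> None:
    """Write a distribution as CSV with a metadata header.

    Length distributions use the ``length_nm,density`` schema,
    s-distributions ``s_svedberg,density``.
    """
    col = "length_nm" if dist.axis_kind == "length" else "s_svedberg"
    header = _meta_header(
        weighting=dist.weighting,
        axis_kind=dist.axis_kind,
        discrete=dist.discrete,
        **{k: v for k, v in dist.metadata.items() if np.isscalar(v)},
    )
    frame = pd.DataFrame({col: dist.grid, "density": dist.density})
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)


def read_distribution(path: PathLike) -> WeightedDistribution:
    """Read a distribution CSV (``length_nm|s_svedberg`` x
    ``density|cumulative``).

    Cumulative input is converted to a density on ingest (finite
    differences of the cumulative at the grid nodes) and flagged in
    ``metadata["converted_from_cumulative"]``.
    """
    frame, meta = _read_csv(path)
    if "length_nm" in frame.columns:
        axis_kind, axis_col = "length", "length_nm"
    elif "s_svedberg" in frame.columns:
        axis_kind, axis_col = "sedimentation_coefficient", "s_svedberg"
    else:
        raise SchemaError(
            f"{path}: need a 'length_nm' or 's_svedberg' column "
            f"(found {list(frame.columns)})"
        )
    grid = frame[axis_col].to_numpy(float)
    converted = False
    if "density" in frame.columns:
        dens = frame["density"].to_numpy(float)
    elif "cumulative" in frame.columns:
        cum = frame["cumulative"].to_numpy(float)
        if np.any(np.diff(cum) < -1e-9):
            raise SchemaError(f"{path}: 'cumulative' column must be non-decreasing")
        dens = np.gradient(cum, grid)
        dens = np.clip(dens, 0.0, None)
        converted = True
    else:
        raise SchemaError(
            f"{path}: need a 'density' or 'cumulative' column "
            f"(found {list(frame.columns)})"
        )
    weighting = meta.get("weighting", "number")
    discrete = str(meta.get("discrete", "False")).lower() == "true"
    dist = WeightedDistribution(
        axis_kind, grid, dens, weighting, discrete=discrete,
        metadata={"source_file": str(path), "converted_from_cumulative": converted},
    )
    return dist.normalized()


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_trace(trace: DetectorTrace, path: PathLike) -> None:
    """Write a detector trace as ``time_s,signal[,crossing]`` CSV."""
    header = _meta_header(seed=trace.metadata.get("seed"))
    frame = pd.DataFrame({"time_s": trace.times, "signal": trace.signal})
    if trace.crossing is not None:
        frame["crossing"] = trace.crossing
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# sweep configuration
# ---------------------------------------------------------------------------

def write_sweep_config(
    config: SweepConfig, species: list, path: PathLike
) -> None:
    """Write a sweep run file (YAML)."""
    doc = {
        "rotor_rpm": config.rotor_rpm,
        "meniscus_cm": config.meniscus_m * 100.0,
        "bottom_cm": config.bottom_m * 100.0,
        "detector_cm": config.detector_m * 100.0,
        "duration_s": config.duration_s,
        "dt_s": config.dt_s,
        "n_particles": config.n_particles,
        "seed": config.seed,
        "cutoff_svedberg": config.cutoff_svedberg,
        "species": [
            {
                "s_svedberg": sp.s_svedberg,
                "ffo": sp.frictional_ratio,
                "density_kg_m3": sp.density,
                "abundance": sp.abundance,
            }
            for sp in species
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_sweep_config(path: PathLike) -> tuple:
    """Read a sweep run file; returns (SweepConfig, [SpeciesSpec])."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a YAML mapping")
    try:
        species = [
            SpeciesSpec(
                s_svedberg=float(sp["s_svedberg"]),
                frictional_ratio=float(sp.get("ffo", 1.5)),
                density=float(sp.get("density_kg_m3", 1331.6 * 1.02)),
                abundance=float(sp.get("abundance", 1.0)),
            )
            for sp in doc["species"]
        ]
        config = SweepConfig(
            rotor_rpm=float(doc.get("rotor_rpm", 30000.0)),
            meniscus_m=float(doc.get("meniscus_cm", 5.9)) / 100.0,
            bottom_m=float(doc.get("bottom_cm", 7.2)) / 100.0,
            detector_m=float(doc.get("detector_cm", 6.9)) / 100.0,
            duration_s=float(doc.get("duration_s", 7200.0)),
            dt_s=float(doc.get("dt_s", 0.5)),
            n_particles=int(doc.get("n_particles", 100_000)),
            seed=int(doc.get("seed", 0)),
            cutoff_svedberg=float(doc.get("cutoff_svedberg", 10.0)),
        )
    except KeyError as err:
        raise SchemaError(f"{path}: missing required key {err}") from err
    return config, species


# ---------------------------------------------------------------------------
# comminution series
# ---------------------------------------------------------------------------

def read_comminution_series(path: PathLike) -> ComminutionSeries:
    """Read ``rpm,seconds,length_nm,statistic,source`` CSV."""
    frame, _ = _read_csv(path)
    missing = [c for c in ComminutionSeries.REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad = frame.index[~np.isfinite(frame["length_nm"]) | (frame["length_nm"] <= 0)]
    if len(bad):
        raise SchemaError(
            f"{path}: row {int(bad[0]) + 2}: 'length_nm' must be positive"
        )
    return ComminutionSeries(frame)


def write_comminution_series(series: ComminutionSeries, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header())
        series.table.to_csv(fh, index=False)
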