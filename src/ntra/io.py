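"""Delimited-text readers and writers for histograms, cohorts and reports.

All files are plain comma-separated text.  Writers prepend ``#`` comment
lines carrying the package version, the seed and a short hash of the
generating configuration, so any output can be traced back to the run that
produced it; readers skip those lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import PARAM_NAMES, RadiodensityHistogram
from .simulate import LEF_TASKS

COHORT_COLUMNS = (
    "id", "age", "sex", "bmi", "pa",
    *(f"{t}_baseline" for t in LEF_TASKS),
    *(f"{t}_followup" for t in LEF_TASKS),
    *PARAM_NAMES,
)

FIT_TABLE_COLUMNS = (
    "subject", *PARAM_NAMES, "objective", "r_squared", "converged",
)


def config_hash(config) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed=None, config=None) -> str:
    lines = [f"# ntra version {__version__}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    if config is not None:
        lines.append(f"# config {config_hash(config)}")
    return "\n".join(lines) + "\n"


def _write_csv(path, df: pd.DataFrame, seed=None, config=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(seed, config))
        df.to_csv(fh, index=False, float_format="%.6g")


def write_histogram(path, hist: RadiodensityHistogram, seed=None, config=None):
    df = pd.DataFrame({
        "bin_center_hu": hist.bin_centers,
        "count": hist.counts,
    })
    _write_csv(path, df, seed, config)


def read_histogram(path) -> RadiodensityHistogram:
    """Read a two-column (bin_center_hu, count) histogram file."""
    df = pd.read_csv(path, comment="#")
    for col in ("bin_center_hu", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    centers = df["bin_center_hu"].to_numpy(dtype=float)
    counts = df["count"].to_numpy(dtype=float)
    if len(centers) < 2:
        raise ValueError(f"{path}: need at least two bins")
    widths = np.diff(centers)
    if not np.allclose(widths, widths[0]):
        raise ValueError(f"{path}: bin centers must be evenly spaced")
    w = widths[0]
    edges = np.concatenate([centers - w / 2, [centers[-1] + w / 2]])
    return RadiodensityHistogram(bin_edges=edges, counts=counts)


def write_voxels(path, hu_values, seed=None, config=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed, config))
        for v in np.asarray(hu_values, dtype=float):
            fh.write(f"{v:.6g}\n")


def read_voxels(path) -> np.ndarray:
    """Read a one-HU-value-per-line voxel file."""
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            values.append(float(line))
    if not values:
        raise ValueError(f"{path}: no voxel values found")
    return np.asarray(values)


def write_fit_table(path, rows, seed=None, config=None) -> None:
    """Write per-subject fit results (one row per subject).

    ``rows`` is an iterable of dicts with keys :data:`FIT_TABLE_COLUMNS`.
    """
    df = pd.DataFrame(list(rows), columns=list(FIT_TABLE_COLUMNS))
    _write_csv(path, df, seed, config)


def write_cohort(path, cohort: pd.DataFrame, seed=None, config=None) -> None:
    _write_csv(path, cohort[list(COHORT_COLUMNS)], seed, config)


def read_cohort(path) -> pd.DataFrame:
    """Read and schema-check a cohort table."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    return df


def write_report(out_dir, report, seed=None, config=None) -> dict:
    """Write every pipeline table plus a structured summary; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in report.to_tables().items():
        path = out_dir / f"{name}.csv"
        _write_csv(path, table, seed, config)
        paths[name] = path
    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(report.summary(), fh, indent=2, default=float)
        fh.write("\n")
    paths["summary"] = summary_path
    return paths
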