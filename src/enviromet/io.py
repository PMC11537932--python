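"""CSV/JSON readers and writers for the pipeline's table dialects.

All CSVs are comma-separated, UTF-8, "." decimal, with a header row.
Numeric round trips are exact to float repr. Empty tables and missing
columns raise :class:`DataError` naming the problem.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import pandas as pd

from .exceptions import DataError

__all__ = [
    "read_table",
    "write_plots",
    "read_plots",
    "write_weather",
    "read_weather",
    "write_soil",
    "read_soil",
    "write_production",
    "read_production",
    "write_matrix",
    "read_matrix",
    "write_blues",
    "read_blues",
    "write_clusters",
    "read_clusters",
    "write_json",
    "read_json",
    "file_sha256",
]

PathLike = Union[str, Path]

PLOTS_COLUMNS = ["genotype", "location", "year", "replicate", "row", "column", "yield"]
WEATHER_COLUMNS = ["location", "day", "variable", "value"]
BLUES_COLUMNS = ["trial", "genotype", "blue", "se"]


def read_table(path: PathLike, required: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"{name} file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise DataError(f"{name} table is empty: {path}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{name} table {path} is missing columns {missing}")
    return df


def write_plots(plots: pd.DataFrame, path: PathLike) -> None:
    plots[PLOTS_COLUMNS].to_csv(path, index=False)


def read_plots(path: PathLike) -> pd.DataFrame:
    df = read_table(path, PLOTS_COLUMNS, "plot")
    df["location"] = df["location"].astype(str)
    return df


def write_weather(weather: pd.DataFrame, path: PathLike) -> None:
    """Wide per-location daily table -> long (location, day, variable, value)."""
    long = weather.melt(id_vars=["location", "day"], var_name="variable", value_name="value")
    long.sort_values(["location", "day", "variable"], kind="stable").to_csv(path, index=False)


def read_weather(path: PathLike) -> pd.DataFrame:
    """Long weather CSV -> wide table with one column per variable."""
    df = read_table(path, WEATHER_COLUMNS, "weather")
    wide = df.pivot_table(index=["location", "day"], columns="variable", values="value")
    wide = wide.reset_index()
    wide.columns.name = None
    wide["location"] = wide["location"].astype(str)
    return wide


def write_soil(soil: pd.DataFrame, path: PathLike) -> None:
    soil.to_csv(path, index=False)


def read_soil(path: PathLike) -> pd.DataFrame:
    df = read_table(path, ["location"], "soil")
    df["location"] = df["location"].astype(str)
    return df


def write_production(production: pd.DataFrame, path: PathLike) -> None:
    production.to_csv(path, index=False)


def read_production(path: PathLike) -> pd.DataFrame:
    return read_table(path, ["county", "production_share"], "production")


def write_matrix(M: pd.DataFrame, path: PathLike, index_label: str = "environment") -> None:
    """Square or rectangular matrix with row ids (W, Omega, centroids...)."""
    M.to_csv(path, index_label=index_label)


def read_matrix(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"matrix file not found: {path}")
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise DataError(f"matrix table is empty: {path}")
    df.index = df.index.astype(str)
    return df


def write_blues(blues: pd.DataFrame, path: PathLike) -> None:
    df = blues.copy()
    df["trial"] = df["location"].astype(str) + ":" + df["year"].astype(str)
    df[BLUES_COLUMNS].to_csv(path, index=False)


def read_blues(path: PathLike) -> pd.DataFrame:
    df = read_table(path, BLUES_COLUMNS, "BLUE")
    parts = df["trial"].astype(str).str.rsplit(":", n=1, expand=True)
    if parts.shape[1] != 2 or parts.isna().any().any():
        raise DataError(f"BLUE table {path}: trial ids must look like LOCATION:YEAR")
    df["location"] = parts[0]
    df["year"] = parts[1]
    return df[["location", "year", "genotype", "blue", "se"]]


def write_clusters(assignments: pd.Series, path: PathLike) -> None:
    assignments.rename("cluster").rename_axis("environment").to_csv(path)


def read_clusters(path: PathLike) -> pd.Series:
    df = read_table(path, ["environment", "cluster"], "cluster")
    s = df.set_index("environment")["cluster"].astype(int)
    s.index = s.index.astype(str)
    return s


def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(
        obj if isinstance(obj, str) else json.dumps(obj, indent=1, sort_keys=True, default=str)
    )


def read_json(path: PathLike):
    path = Path(path)
    if not path.exists():
        raise DataError(f"JSON file not found: {path}")
    return json.loads(path.read_text())


def file_sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
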