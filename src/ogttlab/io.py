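"""CSV/JSON/YAML interchange formats and run configuration.

OGTT long format: ``subject_id,time_min,glucose_mmol_l,insulin_mu_l``
with one row per subject and timepoint; an empty cell is a missing
measurement (never zero).  Feature tables travel as a wide CSV plus a
sidecar schema CSV tagging each column ``numeric`` or ``categorical``.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .edes import ModelParameters, OGTT_TIMES
from .fitting import OGTTResponse
from .regression import FeatureTable

__all__ = [
    "OGTT_HEADER",
    "read_ogtt",
    "write_ogtt",
    "read_features",
    "write_features",
    "read_params",
    "write_params",
    "RunConfig",
    "load_config",
    "config_hash",
    "write_run_log",
]

OGTT_HEADER = ["subject_id", "time_min", "glucose_mmol_l", "insulin_mu_l"]


def read_ogtt(path: str | Path, grid: Sequence[float] = OGTT_TIMES) -> list[OGTTResponse]:
    """Read a long-format OGTT CSV into responses on the fixed grid.

    Errors name the offending row: unknown header, duplicate
    (subject, time) pairs, or times outside the sampling grid.
    """
    path = Path(path)
    grid = [float(t) for t in grid]
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != OGTT_HEADER:
            raise ValueError(f"{path}: expected header {','.join(OGTT_HEADER)!r}, got {header}")
        data: dict[str, dict[float, tuple[float, float]]] = {}
        order: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            sid, t_str, g_str, i_str = (c.strip() for c in row)
            try:
                t = float(t_str)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: invalid time {t_str!r}") from None
            if t not in grid:
                raise ValueError(f"{path}:{lineno}: time {t} not on the sampling grid {grid}")
            g = float(g_str) if g_str else np.nan
            i = float(i_str) if i_str else np.nan
            if sid not in data:
                data[sid] = {}
                order.append(sid)
            if t in data[sid]:
                raise ValueError(f"{path}:{lineno}: duplicate row for ({sid}, {t:g})")
            data[sid][t] = (g, i)
    out = []
    for sid in order:
        glucose = np.array([data[sid].get(t, (np.nan, np.nan))[0] for t in grid])
        insulin = np.array([data[sid].get(t, (np.nan, np.nan))[1] for t in grid])
        out.append(OGTTResponse(sid, np.array(grid), glucose, insulin))
    return out


def _cell(v: float) -> str:
    return "" if v is None or (isinstance(v, float) and np.isnan(v)) else repr(float(v))


def write_ogtt(responses: Iterable[OGTTResponse], path: str | Path) -> None:
    """Write responses in the long format; missing values become empty cells."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(OGTT_HEADER)
        for r in responses:
            for t, g, i in zip(r.times, r.glucose, r.insulin):
                w.writerow([r.subject_id, f"{t:g}", _cell(g), _cell(i)])


def write_features(table: FeatureTable, path: str | Path,
                   schema_path: str | Path) -> None:
    table.data.to_csv(path, index=False)
    with Path(schema_path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["column", "kind"])
        for col, kind in table.schema.items():
            w.writerow([col, kind])


def read_features(path: str | Path, schema_path: str | Path) -> FeatureTable:
    schema: dict[str, str] = {}
    with Path(schema_path).open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["column", "kind"]:
            raise ValueError(f"{schema_path}: expected header 'column,kind'")
        for row in reader:
            if row:
                schema[row[0]] = row[1]
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col, kind in schema.items():
        if kind == "categorical" and col in df.columns:
            df[col] = df[col].astype(object).where(df[col].notna(), np.nan)
    return FeatureTable(data=df, schema=schema)


def write_params(params: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(params.to_json() + "\n")


def read_params(path: str | Path) -> ModelParameters:
    return ModelParameters.from_json(Path(path).read_text())


@dataclass
class RunConfig:
    """Resolved pipeline configuration; every seed is explicit."""

    seed: int = 0
    n_subjects: int = 300
    class_mix: dict[str, float] = field(default_factory=lambda: {
        "NGM": 0.48, "IFG": 0.18, "IGT": 0.05, "IFG&IGT": 0.08, "T2DM": 0.21})
    glucose_cv: float = 0.03
    insulin_cv: float = 0.08
    missing_prob: float = 0.02
    params_to_fit: list[str] = field(default_factory=lambda: ["k1", "k5", "k6", "k8"])
    outer_k: int = 5
    inner_k: int = 5
    grid: str = "default"        # "default" | "fast"
    exclusion_strict: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; unknown keys are rejected, omitted keys default."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig().to_dict())
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_run_log(path: str | Path, records: Iterable[dict]) -> None:
    """Append line-delimited JSON records to the run log."""
    with Path(path).open("a") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")
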