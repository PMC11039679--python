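"""Tidy trace/snapshot tables: schema, readers, writers, validation.

Trace tables are long-format CSV, one row per cell x timepoint, columns
``cell_id, mode, dose, perturbation, t_h, foxo1_nuc_frac, p53_nuc, dead``.
Missing samples (after cell death) are written as empty fields with
``dead = 1``; floats are printed with 6 significant digits.  Snapshot
tables carry one row per cell: ``cell_id, mode, dose, perturbation,
foxo1_nuc_frac, log_p53``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellTrace",
    "TraceSchemaError",
    "TRACE_COLUMNS",
    "SNAPSHOT_COLUMNS",
    "read_traces",
    "write_traces",
    "read_snapshot",
    "write_snapshot",
    "validate_traces",
    "iter_traces",
    "get_trace",
]

TRACE_COLUMNS = [
    "cell_id",
    "mode",
    "dose",
    "perturbation",
    "t_h",
    "foxo1_nuc_frac",
    "p53_nuc",
    "dead",
]
SNAPSHOT_COLUMNS = ["cell_id", "mode", "dose", "perturbation", "foxo1_nuc_frac", "log_p53"]

_GRID_TOL = 1e-9


class TraceSchemaError(ValueError):
    """A trace/snapshot table violates the schema."""


@dataclass
class CellTrace:
    """One cell's time series on a uniform grid.

    ``foxo1_nuc_frac`` and ``p53_nuc`` are aligned to ``t`` with NaN for
    missing (post-death) samples; ``death_time`` is None for survivors.
    """

    cell_id: str
    mode: str
    dose: float
    perturbation: str
    t: np.ndarray
    foxo1_nuc_frac: np.ndarray
    p53_nuc: np.ndarray
    death_time: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.foxo1_nuc_frac = np.asarray(self.foxo1_nuc_frac, dtype=float)
        self.p53_nuc = np.asarray(self.p53_nuc, dtype=float)
        if not (len(self.t) == len(self.foxo1_nuc_frac) == len(self.p53_nuc)):
            raise TraceSchemaError(f"cell {self.cell_id}: channel lengths differ")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else np.nan

    @property
    def observed(self) -> np.ndarray:
        """Mask of frames observed before death (either channel present)."""
        return np.isfinite(self.foxo1_nuc_frac) | np.isfinite(self.p53_nuc)

    @property
    def last_observed_time(self) -> float | None:
        obs = np.flatnonzero(self.observed)
        return float(self.t[obs[-1]]) if obs.size else None


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TraceSchemaError(f"{what} is missing columns {missing}")


def _check_cell(sub: pd.DataFrame, cell_id: str) -> list[str]:
    """Reasons this cell's rows violate the trace invariants."""
    reasons: list[str] = []
    t = sub["t_h"].to_numpy(dtype=float)
    if len(t) == 0:
        return ["no rows"]
    if pd.Index(t).has_duplicates:
        reasons.append("duplicated (cell_id, t_h) rows")
    if np.any(np.diff(t) <= 0):
        reasons.append("t_h not strictly increasing")
    # tolerance accommodates 6-significant-digit printing of the time column
    elif len(t) > 2 and np.max(np.abs(np.diff(t) - (t[1] - t[0]))) > 1e-3:
        reasons.append("non-uniform time grid")
    f = sub["foxo1_nuc_frac"].to_numpy(dtype=float)
    p = sub["p53_nuc"].to_numpy(dtype=float)
    bad_f = np.flatnonzero(np.isfinite(f) & ((f < 0) | (f > 1)))
    if bad_f.size:
        reasons.append(
            f"foxo1_nuc_frac outside [0, 1] at t_h={t[bad_f[0]]:g} (cell {cell_id})"
        )
    bad_p = np.flatnonzero(np.isfinite(p) & (p < 0))
    if bad_p.size:
        reasons.append(f"negative p53_nuc at t_h={t[bad_p[0]]:g} (cell {cell_id})")
    dead = sub["dead"].to_numpy(dtype=float) > 0
    if dead.any():
        first_dead = int(np.flatnonzero(dead)[0])
        if not dead[first_dead:].all():
            reasons.append("dead flag not a suffix")
        if np.any(np.isfinite(f[dead]) | np.isfinite(p[dead])):
            reasons.append("post-death samples present")
    return reasons


def validate_traces(df: pd.DataFrame) -> pd.DataFrame:
    """Report-only validation: one row per cell with pass/fail and reasons."""
    _require_columns(df, TRACE_COLUMNS, "trace table")
    records = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        reasons = _check_cell(sub.sort_values("t_h"), str(cell_id))
        records.append(
            {"cell_id": cell_id, "ok": not reasons, "reasons": "; ".join(reasons)}
        )
    return pd.DataFrame.from_records(records, columns=["cell_id", "ok", "reasons"])


def read_traces(path, validate: bool = True) -> pd.DataFrame:
    """Read a tidy trace CSV; raises :class:`TraceSchemaError` on violations."""
    df = pd.read_csv(path, dtype={"cell_id": str, "mode": str, "perturbation": str})
    _require_columns(df, TRACE_COLUMNS, f"trace file {path}")
    df = df[TRACE_COLUMNS]
    if df.empty:
        return df.assign(dead=df.get("dead", pd.Series(dtype=int)))
    df["dead"] = df["dead"].fillna(0).astype(int)
    if validate:
        report = validate_traces(df)
        bad = report.loc[~report["ok"]]
        if not bad.empty:
            first = bad.iloc[0]
            raise TraceSchemaError(
                f"invalid trace table ({len(bad)} cells fail); first: "
                f"cell {first['cell_id']}: {first['reasons']}"
            )
    return df


def write_traces(df: pd.DataFrame, path) -> None:
    """Write a tidy trace table as CSV with 6-significant-digit floats."""
    _require_columns(df, TRACE_COLUMNS, "trace table")
    df[TRACE_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def read_snapshot(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "mode": str, "perturbation": str})
    _require_columns(df, SNAPSHOT_COLUMNS, f"snapshot file {path}")
    df = df[SNAPSHOT_COLUMNS]
    f = df["foxo1_nuc_frac"]
    bad = df.index[(f < 0) | (f > 1)]
    if len(bad):
        row = df.loc[bad[0]]
        raise TraceSchemaError(
            f"foxo1_nuc_frac outside [0, 1] for cell {row['cell_id']}"
        )
    return df


def write_snapshot(df: pd.DataFrame, path) -> None:
    _require_columns(df, SNAPSHOT_COLUMNS, "snapshot table")
    df[SNAPSHOT_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def get_trace(df: pd.DataFrame, cell_id: str) -> CellTrace:
    sub = df.loc[df["cell_id"] == cell_id].sort_values("t_h")
    if sub.empty:
        raise KeyError(f"cell {cell_id!r} not in table")
    return _trace_from_rows(sub, cell_id)


def iter_traces(df: pd.DataFrame):
    """Yield :class:`CellTrace` objects, one per cell, in cell_id order."""
    for cell_id, sub in df.groupby("cell_id", sort=True):
        yield _trace_from_rows(sub.sort_values("t_h"), str(cell_id))


def _trace_from_rows(sub: pd.DataFrame, cell_id: str) -> CellTrace:
    dead = sub["dead"].to_numpy(dtype=float) > 0
    t = sub["t_h"].to_numpy(dtype=float)
    death_time = float(t[np.flatnonzero(dead)[0]]) if dead.any() else None
    return CellTrace(
        cell_id=cell_id,
        mode=str(sub["mode"].iloc[0]),
        dose=float(sub["dose"].iloc[0]),
        perturbation=str(sub["perturbation"].iloc[0]),
        t=t,
        foxo1_nuc_frac=sub["foxo1_nuc_frac"].to_numpy(dtype=float),
        p53_nuc=sub["p53_nuc"].to_numpy(dtype=float),
        death_time=death_time,
    )


def traces_to_string(df: pd.DataFrame) -> str:
    buf = io.StringIO()
    write_traces(df, buf)
    return buf.getvalue()
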