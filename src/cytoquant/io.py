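"""Reading and writing the tabular formats used across the pipelines.

The canonical trace format is a header CSV with columns ``cell_id``,
``time_s``, ``intensity`` and an optional ``condition`` column (cells
without one are labelled ``"unlabeled"``). Deposit files carry
``cell_id, deposit_time_s``. All times are seconds as floats; no frame
index convention is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "TraceTable",
    "read_traces",
    "write_traces",
    "read_deposits",
    "write_deposits",
]

TRACE_COLUMNS = ["cell_id", "condition", "time_s", "intensity"]


@dataclass(frozen=True)
class TraceTable:
    """Per-cell fluorescence time series for one or more conditions.

    Wraps a long-format :class:`pandas.DataFrame` with columns
    ``cell_id``, ``condition``, ``time_s``, ``intensity``. Invariants
    (checked at construction): times strictly increasing within a cell,
    every cell has at least two samples.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"trace table missing columns: {missing}")
        for cell_id, sub in self.frame.groupby("cell_id", sort=False):
            t = sub["time_s"].to_numpy(dtype=float)
            if len(t) < 2:
                raise ValidationError(
                    f"cell {cell_id!r} has {len(t)} sample(s); need >= 2"
                )
            if not np.all(np.diff(t) > 0):
                raise ValidationError(
                    f"cell {cell_id!r} has non-monotone or duplicate timestamps"
                )
            conds = sub["condition"].unique()
            if len(conds) != 1:
                raise ValidationError(
                    f"cell {cell_id!r} has multiple condition labels: {list(conds)}"
                )

    @property
    def cell_ids(self) -> list[str]:
        return list(self.frame["cell_id"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())

    @property
    def n_cells(self) -> int:
        return self.frame["cell_id"].nunique()

    def condition_of(self, cell_id: str) -> str:
        sub = self.frame.loc[self.frame["cell_id"] == cell_id, "condition"]
        if sub.empty:
            raise KeyError(cell_id)
        return str(sub.iloc[0])

    def get(self, cell_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(times, intensities)`` for one cell, time-sorted."""
        sub = self.frame[self.frame["cell_id"] == cell_id]
        if sub.empty:
            raise KeyError(cell_id)
        return (
            sub["time_s"].to_numpy(dtype=float),
            sub["intensity"].to_numpy(dtype=float),
        )

    def iter_cells(self) -> Iterator[tuple[str, str, np.ndarray, np.ndarray]]:
        """Yield ``(cell_id, condition, times, intensities)`` per cell."""
        for cell_id, sub in self.frame.groupby("cell_id", sort=False):
            yield (
                str(cell_id),
                str(sub["condition"].iloc[0]),
                sub["time_s"].to_numpy(dtype=float),
                sub["intensity"].to_numpy(dtype=float),
            )

    def subset(self, condition: str) -> "TraceTable":
        sub = self.frame[self.frame["condition"] == condition]
        if sub.empty:
            raise KeyError(f"no cells with condition {condition!r}")
        return TraceTable(sub.reset_index(drop=True))


def read_traces(path: str | Path) -> TraceTable:
    """Read a trace CSV into a validated :class:`TraceTable`.

    Required columns: ``cell_id``, ``time_s``, ``intensity``. A missing
    ``condition`` column defaults to ``"unlabeled"``. Rows are sorted by
    time within each cell before validation, so only genuinely duplicate
    timestamps fail.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"cell_id", "time_s", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if "condition" not in df.columns:
        df["condition"] = "unlabeled"
    df["cell_id"] = df["cell_id"].astype(str)
    for col in ("time_s", "intensity"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column {col} is not numeric") from exc
    df = (
        df[TRACE_COLUMNS]
        .sort_values(["cell_id", "time_s"], kind="stable")
        .reset_index(drop=True)
    )
    return TraceTable(df)


def write_traces(table: TraceTable, path: str | Path) -> None:
    """Write a :class:`TraceTable` to CSV, preserving values to full
    double precision (round-trips through :func:`read_traces` are
    identity on values)."""
    table.frame.to_csv(path, index=False, float_format="%.17g")


def read_deposits(path: str | Path) -> dict[str, list[float]]:
    """Read a deposit CSV (``cell_id, deposit_time_s``) into a mapping
    from cell id to a sorted list of deposit times in seconds."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"cell_id", "deposit_time_s"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df["cell_id"] = df["cell_id"].astype(str)
    try:
        df["deposit_time_s"] = pd.to_numeric(df["deposit_time_s"])
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: deposit_time_s is not numeric") from exc
    out: dict[str, list[float]] = {}
    for cell_id, sub in df.groupby("cell_id", sort=False):
        out[str(cell_id)] = sorted(float(t) for t in sub["deposit_time_s"])
    return out


def write_deposits(deposits: dict[str, list[float]], path: str | Path) -> None:
    rows = [
        {"cell_id": cell, "deposit_time_s": t}
        for cell, times in deposits.items()
        for t in times
    ]
    pd.DataFrame(rows, columns=["cell_id", "deposit_time_s"]).to_csv(
        path, index=False, float_format="%.17g"
    )
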