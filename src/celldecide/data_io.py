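"""Reading, writing and slicing single-cell concentration tables.

A *cell table* holds one row per cell: an experimental condition — the
input (ligand) level in ng/mL and the exposure timepoint in minutes —
plus one column per measured output molecule, as linear-scale
concentrations in arbitrary fluorescence units.  All downstream model
fitting happens on the natural logarithm of these concentrations, so
values must be strictly positive; rows violating this are dropped at
read time and counted, never silently shifted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("celldecide")

#: canonical metadata column names used internally
CONDITION_COL = "condition_id"
INPUT_COL = "input_level"
TIME_COL = "timepoint"
_META_COLS = (CONDITION_COL, INPUT_COL, TIME_COL)


class SchemaError(ValueError):
    """A required column is missing or misnamed in the input file."""


class EmptyInputError(ValueError):
    """No usable rows remain after exclusions."""


def make_condition_id(input_level: float, timepoint: float) -> str:
    """Canonical label for the (input level, timepoint) pair that defines
    an experimental condition, e.g. ``"0.082@30"``."""
    return f"{input_level:g}@{timepoint:g}"


@dataclass
class CellTable:
    """Per-cell output concentrations with condition annotations.

    Parameters
    ----------
    data
        One row per cell.  Columns: ``condition_id``, ``input_level``
        (ng/mL), ``timepoint`` (min), plus one column per output
        molecule holding linear-scale concentrations.
    outputs
        Names of the output-molecule columns, in a fixed order.
    n_excluded
        Number of raw rows dropped because an output value was missing
        or nonpositive (the log transform would be undefined).
    """

    data: pd.DataFrame
    outputs: list[str]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in (*_META_COLS, *self.outputs) if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cell table is missing column(s): {missing}")
        vals = self.data[self.outputs].to_numpy(dtype=float)
        if vals.size and not np.all(vals > 0):
            raise ValueError("all output concentrations must be strictly positive")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        return list(dict.fromkeys(self.data[CONDITION_COL]))

    def condition(self, condition_id: str) -> CellTable:
        """Slice to the cells of one condition."""
        sub = self.data[self.data[CONDITION_COL] == condition_id]
        if sub.empty:
            raise KeyError(
                f"unknown condition {condition_id!r}; available: {self.conditions}"
            )
        return CellTable(sub.reset_index(drop=True), list(self.outputs))

    def select(self, input_level: float, timepoint: float) -> CellTable:
        """Slice by (input level, timepoint)."""
        return self.condition(make_condition_id(input_level, timepoint))


def _detect_delimiter(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if "\t" in header else ","


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, object] | None = None,
) -> CellTable:
    """Read a delimited text file (CSV/TSV, auto-detected) into a CellTable.

    ``schema`` maps the roles ``"input_level"``, ``"timepoint"`` and
    ``"outputs"`` (a mapping output-name → column-name, or a list of
    column names) to the file's columns; an optional ``"condition_id"``
    names an explicit condition column, otherwise the condition label is
    derived from (input_level, timepoint).  With ``schema=None`` the
    file is assumed to use the canonical column names, every
    non-metadata column being an output.

    Rows with missing or nonpositive output values are excluded and the
    exclusion count stored on the returned table (and logged).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_detect_delimiter(path), encoding="utf-8")

    if schema is None:
        schema = {
            INPUT_COL: INPUT_COL,
            TIME_COL: TIME_COL,
            "outputs": [c for c in raw.columns if c not in _META_COLS],
        }
        if CONDITION_COL in raw.columns:
            schema[CONDITION_COL] = CONDITION_COL

    for role in (INPUT_COL, TIME_COL):
        col = schema.get(role)
        if col is None or col not in raw.columns:
            raise SchemaError(f"required column for {role!r} ({col!r}) not in header")

    outputs_spec = schema.get("outputs")
    if not outputs_spec:
        raise SchemaError("schema must name at least one output column")
    if isinstance(outputs_spec, Mapping):
        output_map = dict(outputs_spec)
    else:
        output_map = {name: name for name in outputs_spec}
    for name, col in output_map.items():
        if col not in raw.columns:
            raise SchemaError(f"output column {col!r} (for {name!r}) not in header")

    df = pd.DataFrame(
        {
            INPUT_COL: pd.to_numeric(raw[schema[INPUT_COL]]),
            TIME_COL: pd.to_numeric(raw[schema[TIME_COL]]),
        }
    )
    cond_col = schema.get(CONDITION_COL)
    if cond_col is not None and cond_col in raw.columns:
        df[CONDITION_COL] = raw[cond_col].astype(str)
    else:
        df[CONDITION_COL] = [
            make_condition_id(a, t) for a, t in zip(df[INPUT_COL], df[TIME_COL])
        ]
    for name, col in output_map.items():
        df[name] = pd.to_numeric(raw[col], errors="coerce")

    outputs = list(output_map)
    ok = df[outputs].gt(0).all(axis=1) & df[outputs].notna().all(axis=1)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info(
            "read_cell_table: excluded %d row(s) with missing or nonpositive outputs",
            n_excluded,
        )
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise EmptyInputError(f"{path}: no usable rows after exclusions")
    cols = [CONDITION_COL, INPUT_COL, TIME_COL, *outputs]
    return CellTable(df[cols], outputs, n_excluded=n_excluded)


def write_cell_table(table: CellTable, path: str | Path, sep: str = ",") -> None:
    """Write a CellTable as delimited text with header (round-trips with
    :func:`read_cell_table`)."""
    cols = [CONDITION_COL, INPUT_COL, TIME_COL, *table.outputs]
    table.data[cols].to_csv(Path(path), sep=sep, index=False)


def log_transform(
    table: CellTable, outputs: Sequence[str] | None = None
) -> dict[str, np.ndarray]:
    """Natural-log concentrations per condition.

    Returns a mapping condition label → (n_cells, n_outputs) array of
    ln-concentrations, output columns in the requested order.  The log
    is always the natural logarithm.
    """
    if outputs is None:
        outputs = table.outputs
    unknown = [o for o in outputs if o not in table.outputs]
    if unknown:
        raise KeyError(f"unknown output(s): {unknown}; table has {table.outputs}")
    out: dict[str, np.ndarray] = {}
    for cond in table.conditions:
        vals = table.data.loc[
            table.data[CONDITION_COL] == cond, list(outputs)
        ].to_numpy(dtype=float)
        if not np.all(vals > 0):  # CellTable invariant; should be unreachable
            raise AssertionError("nonpositive concentration reached log_transform")
        out[cond] = np.log(vals)
    return out
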