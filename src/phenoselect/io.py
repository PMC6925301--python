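"""Reading and writing trait tables and run artifacts.

The CSV dialect is fixed: a header row, '.' as the decimal point, first
column ``sample_id``, then metadata columns (``label`` mandatory), then
the numeric trait columns with unique names.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .preprocess import FilterTrace
from .table import TraitTable

__all__ = [
    "read_trait_csv",
    "write_trait_csv",
    "read_replicate_map",
    "traces_to_json",
]


def read_trait_csv(
    path,
    label_column: str = "label",
    sample_id_column: str = "sample_id",
    metadata_columns: tuple[str, ...] = (),
) -> TraitTable:
    """Parse a trait CSV into a :class:`TraitTable`.

    All columns other than the sample id, the label and the declared
    metadata columns are traits and must be numeric; schema violations
    (missing label column, duplicate header, non-numeric trait cell) raise
    :class:`SchemaError` with row/column coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise SchemaError(f"duplicate header(s) in {path.name}: {dupes}")
    frame = pd.read_csv(path)
    if label_column not in frame.columns:
        raise SchemaError(f"{path.name}: missing label column {label_column!r}")
    return TraitTable.from_frame(
        frame,
        label_column=label_column,
        sample_id_column=sample_id_column,
        metadata_columns=metadata_columns,
    )


def write_trait_csv(table: TraitTable, path) -> None:
    """Write the fixed-dialect CSV: sample_id, label, metadata, traits."""
    table.to_frame().to_csv(path, index=False)


def read_replicate_map(path) -> dict[str, str]:
    """Two-column CSV (sample_id, replicate_group) -> mapping."""
    frame = pd.read_csv(path)
    cols = list(frame.columns)
    if len(cols) < 2:
        raise SchemaError("replicate map needs columns (sample_id, replicate_group)")
    return dict(zip(frame[cols[0]].astype(str), frame[cols[1]].astype(str)))


def traces_to_json(traces: list[FilterTrace], path=None) -> str:
    """Serialize filter traces to a JSON report (optionally to a file)."""
    text = json.dumps([t.to_dict() for t in traces], indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
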