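"""The trait table: the unit of data every pipeline stage consumes and emits.

A :class:`TraitTable` is a samples x traits numeric matrix with named
traits, per-sample identifiers, a class-label vector and optional
per-sample metadata (genotype, treatment, replicate group, ...).  It is a
thin, validated wrapper around numpy/pandas rather than a new container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["TraitTable"]


@dataclass
class TraitTable:
    """Samples x traits matrix with labels and optional metadata.

    Parameters
    ----------
    values:
        Numeric matrix of shape ``(n_samples, n_traits)``.  Missing
        measurements are represented as NaN.
    trait_names:
        Unique column names, one per trait.
    sample_ids:
        One identifier per row.
    labels:
        Integer class label per sample.  Binary pipelines use ``{0, 1}``.
    metadata:
        Optional per-sample columns (genotype, treatment, day, replicate
        group) indexed like ``sample_ids``.
    """

    values: np.ndarray
    trait_names: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.trait_names = list(self.trait_names)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-D samples x traits matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise SchemaError(
                f"{len(self.sample_ids)} sample ids for {n} rows of values"
            )
        if len(self.labels) != n:
            raise SchemaError(f"{len(self.labels)} labels for {n} rows of values")
        if len(self.trait_names) != p:
            raise SchemaError(
                f"{len(self.trait_names)} trait names for {p} columns of values"
            )
        if len(set(self.trait_names)) != p:
            dupes = sorted({t for t in self.trait_names if self.trait_names.count(t) > 1})
            raise SchemaError(f"duplicate trait names: {dupes}")
        if self.metadata is not None and len(self.metadata) != n:
            raise SchemaError("metadata row count does not match values")

    # -- basic geometry -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    # -- subsetting (never mutates; filters only remove, never edit) ----

    def subset_traits(self, names: list[str]) -> "TraitTable":
        """Return a table restricted to ``names``, in the given order."""
        missing = [t for t in names if t not in self.trait_names]
        if missing:
            raise SchemaError(f"traits not in table: {missing}")
        idx = [self.trait_names.index(t) for t in names]
        return TraitTable(
            values=self.values[:, idx].copy(),
            trait_names=list(names),
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            metadata=None if self.metadata is None else self.metadata.copy(),
        )

    def subset_samples(self, row_idx) -> "TraitTable":
        """Return a table restricted to the given row positions."""
        row_idx = np.asarray(row_idx)
        return TraitTable(
            values=self.values[row_idx].copy(),
            trait_names=list(self.trait_names),
            sample_ids=[self.sample_ids[i] for i in row_idx],
            labels=self.labels[row_idx].copy(),
            metadata=None
            if self.metadata is None
            else self.metadata.iloc[row_idx].reset_index(drop=True),
        )

    def copy(self) -> "TraitTable":
        return self.subset_samples(np.arange(self.n_samples))

    # -- pandas bridge ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: sample_id, label, metadata columns, trait columns."""
        out = pd.DataFrame({"sample_id": self.sample_ids, "label": self.labels})
        if self.metadata is not None:
            for col in self.metadata.columns:
                out[col] = self.metadata[col].to_numpy()
        for j, t in enumerate(self.trait_names):
            out[t] = self.values[:, j]
        return out

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        label_column: str = "label",
        sample_id_column: str = "sample_id",
        metadata_columns: tuple[str, ...] = (),
    ) -> "TraitTable":
        """Build a table from a tidy frame; all remaining columns are traits."""
        if label_column not in frame.columns:
            raise SchemaError(f"missing label column {label_column!r}")
        if sample_id_column in frame.columns:
            sample_ids = frame[sample_id_column].astype(str).tolist()
        else:
            sample_ids = [f"s{i:05d}" for i in range(len(frame))]
        reserved = {label_column, sample_id_column, *metadata_columns}
        trait_cols = [c for c in frame.columns if c not in reserved]
        for col in trait_cols:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"non-numeric trait cell at row {row}, column {col!r}: "
                    f"{frame[col].iloc[row]!r}"
                )
        meta = None
        present_meta = [c for c in metadata_columns if c in frame.columns]
        if present_meta:
            meta = frame[present_meta].reset_index(drop=True)
        return cls(
            values=frame[trait_cols].to_numpy(dtype=float),
            trait_names=trait_cols,
            sample_ids=sample_ids,
            labels=frame[label_column].to_numpy(),
            metadata=meta,
        )
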