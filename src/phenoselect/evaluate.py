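"""Repeated stratified k-fold cross-validation and rank-fraction sweeps.

The harness evaluates each classifier on the top 10%..50% and 100% of the
SVM-RFE trait ranking (or on explicit top-k counts), mirroring the layout
of a methods x rank-fraction accuracy table.  Two ranking protocols are
supported:

``rank_inside_fold``
    The ranking is recomputed on every training fold, so held-out rows
    never influence trait selection, tuning, or standardization.  This is
    the statistically sound default.
``rank_once``
    A fixed, externally supplied trait subset is evaluated.  Ranking on
    the full table before cross-validation leaks test information and
    inflates accuracy; the mode exists to reproduce that protocol, not to
    endorse it.

Accuracies aggregate as the mean over folds within a repeat, then the mean
and standard error over repeats.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .classify import ClassifierSpec, fit_arrays, predict_arrays
from .errors import ConfigurationError, DataError, LabelError
from .ranking import RankingResult, rfe_rank_arrays, select_top
from .seeds import derive_seed
from .table import TraitTable

__all__ = [
    "CVProtocol",
    "CVResult",
    "AccuracyTable",
    "cv_partitions",
    "repeated_cv",
    "fraction_sweep",
    "count_sweep",
    "summarize",
]


@dataclass
class CVProtocol:
    """k folds x repeats, stratified by default."""

    k: int = 10
    repeats: int = 10
    stratified: bool = True
    rank_mode: str = "rank_inside_fold"
    seed: int = 0

    def validate(self) -> None:
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")
        if self.rank_mode not in ("rank_inside_fold", "rank_once"):
            raise ConfigurationError(
                "rank_mode must be rank_inside_fold or rank_once"
            )


@dataclass
class CVResult:
    """Per-fold accuracies plus their repeat-level summary."""

    fold_accuracies: np.ndarray  # (repeats, k)
    fold_sizes: np.ndarray  # (repeats, k)
    mean_accuracy: float
    se: float
    spec: ClassifierSpec
    subset: str
    model_seconds: float = 0.0
    rank_seconds: float = 0.0

    @property
    def repeat_means(self) -> np.ndarray:
        return self.fold_accuracies.mean(axis=1)


@dataclass
class AccuracyTable:
    """methods x rank-subset grid of CV summaries."""

    methods: list[str]
    columns: list[str]
    mean: np.ndarray
    se: np.ndarray
    runtime: np.ndarray  # tune+fit+predict seconds per cell
    cells: dict[tuple[str, str], CVResult] = field(default_factory=dict)
    failed: list[tuple[str, str, str]] = field(default_factory=list)

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        scale = 100.0 if percent else 1.0
        return pd.DataFrame(
            self.mean * scale, index=self.methods, columns=self.columns
        )

    def to_tsv(self, path) -> None:
        """Accuracy grid in percent, fixed formatting (byte-reproducible)."""
        with open(path, "w") as fh:
            fh.write("method\t" + "\t".join(self.columns) + "\n")
            for i, m in enumerate(self.methods):
                row = "\t".join(f"{100 * self.mean[i, j]:.4f}" for j in range(len(self.columns)))
                fh.write(f"{m}\t{row}\n")


def cv_partitions(protocol: CVProtocol, labels: np.ndarray):
    """The seeded fold partitions, one list of (train, test) per repeat.

    This is exactly the sequence :func:`repeated_cv` iterates, exposed so
    that audits (e.g. leakage probes) can address individual test folds.
    """
    protocol.validate()
    labels = np.asarray(labels)
    if protocol.stratified:
        smallest = np.bincount(np.searchsorted(np.unique(labels), labels)).min()
        if protocol.k > smallest:
            raise ConfigurationError(
                f"stratified {protocol.k}-fold impossible: smallest class has "
                f"{smallest} samples"
            )
    out = []
    for r in range(protocol.repeats):
        rs = derive_seed(protocol.seed, "fold-shuffle", r)
        if protocol.stratified:
            splitter = StratifiedKFold(
                n_splits=protocol.k, shuffle=True, random_state=rs
            )
        else:
            splitter = KFold(n_splits=protocol.k, shuffle=True, random_state=rs)
        out.append(list(splitter.split(np.zeros(len(labels)), labels)))
    return out


def _column_indices(trait_names: list[str], chosen: list[str]) -> list[int]:
    pos = {t: j for j, t in enumerate(trait_names)}
    return [pos[t] for t in chosen]


def repeated_cv(
    table: TraitTable,
    spec: ClassifierSpec,
    protocol: CVProtocol,
    select: int | float | None = None,
    subset: Sequence[str] | None = None,
    rank_C: float = 1.0,
    rank_standardize: bool = True,
    test_fold_transform: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    _ranking_cache: dict[tuple[int, int], RankingResult] | None = None,
) -> CVResult:
    """Repeated stratified k-fold CV of one classifier.

    ``select`` (count or fraction, ``rank_inside_fold``) reruns SVM-RFE on
    every training fold and keeps its top traits; ``subset``
    (``rank_once``) evaluates a fixed trait list.  With neither, all
    traits are used and ranking is bypassed.

    ``test_fold_transform`` is a diagnostic hook: it receives the held-out
    rows (all traits) and their labels and returns a replacement matrix,
    used only at prediction time.  It exists to audit information leakage
    and plays no part in normal evaluation.
    """
    protocol.validate()
    if select is not None and subset is not None:
        raise ConfigurationError("give either select or subset, not both")
    if protocol.rank_mode == "rank_once" and select is not None:
        raise ConfigurationError(
            "rank_once evaluates a fixed subset; pass subset=, not select="
        )
    if len(np.unique(table.labels)) != 2:
        raise LabelError("repeated_cv requires binary labels")
    if not np.all(np.isfinite(table.values)):
        raise DataError("table contains missing values; preprocess first")

    names = table.trait_names
    fixed_cols = None
    if subset is not None:
        missing = [t for t in subset if t not in names]
        if missing:
            raise DataError(f"subset traits not in table: {missing}")
        fixed_cols = _column_indices(names, list(subset))
    ranking_cache = _ranking_cache if _ranking_cache is not None else {}

    partitions = cv_partitions(protocol, table.labels)
    acc = np.zeros((protocol.repeats, protocol.k))
    sizes = np.zeros((protocol.repeats, protocol.k), dtype=int)
    model_seconds = 0.0
    rank_seconds = 0.0
    X, y = table.values, table.labels
    for r, folds in enumerate(partitions):
        for f, (tr, te) in enumerate(folds):
            if select is not None:
                key = (r, f)
                if key not in ranking_cache:
                    t0 = time.perf_counter()
                    ranking_cache[key] = rfe_rank_arrays(
                        X[tr], y[tr], names, C=rank_C, standardize=rank_standardize
                    )
                    rank_seconds += time.perf_counter() - t0
                chosen = select_top(ranking_cache[key], select)
                cols = _column_indices(names, chosen)
            else:
                cols = fixed_cols if fixed_cols is not None else list(range(len(names)))
            t0 = time.perf_counter()
            fold_spec = spec.with_seed(derive_seed(protocol.seed, spec.method, r, f))
            model = fit_arrays(
                fold_spec, X[tr][:, cols], y[tr], [names[c] for c in cols]
            )
            X_te = X[te]
            if test_fold_transform is not None:
                X_te = test_fold_transform(X_te.copy(), y[te])
            pred = predict_arrays(model, X_te[:, cols])
            model_seconds += time.perf_counter() - t0
            acc[r, f] = float(np.mean(pred == y[te]))
            sizes[r, f] = len(te)

    repeat_means = acc.mean(axis=1)
    se = (
        float(np.std(repeat_means, ddof=1) / np.sqrt(protocol.repeats))
        if protocol.repeats > 1
        else 0.0
    )
    if select is not None:
        subset_desc = f"top {select}"
    elif subset is not None:
        subset_desc = f"fixed ({len(subset)} traits)"
    else:
        subset_desc = "all traits"
    return CVResult(
        fold_accuracies=acc,
        fold_sizes=sizes,
        mean_accuracy=float(repeat_means.mean()),
        se=se,
        spec=spec,
        subset=subset_desc,
        model_seconds=model_seconds,
        rank_seconds=rank_seconds,
    )


def _sweep(
    table: TraitTable,
    specs: Sequence[ClassifierSpec],
    selections: Sequence[int | float],
    column_labels: Sequence[str],
    protocol: CVProtocol,
    rank_C: float,
) -> AccuracyTable:
    methods = [s.method for s in specs]
    if len(set(methods)) != len(methods):
        raise ConfigurationError("duplicate methods in sweep")
    mean = np.full((len(specs), len(selections)), np.nan)
    se = np.full_like(mean, np.nan)
    runtime = np.full_like(mean, np.nan)
    cells: dict[tuple[str, str], CVResult] = {}
    failed: list[tuple[str, str, str]] = []
    # fold rankings depend only on the training fold, so all cells that
    # rank can share one cache keyed by (repeat, fold)
    cache: dict[tuple[int, int], RankingResult] = {}
    for i, spec in enumerate(specs):
        for j, sel in enumerate(selections):
            label = column_labels[j]
            try:
                is_all = (isinstance(sel, float) and sel >= 1.0) or (
                    isinstance(sel, int) and sel >= table.n_traits
                )
                res = repeated_cv(
                    table,
                    spec,
                    protocol,
                    select=None if is_all else sel,
                    rank_C=rank_C,
                    _ranking_cache=cache,
                )
            except Exception as exc:  # continue other cells, mark this one
                failed.append((spec.method, label, f"{type(exc).__name__}: {exc}"))
                continue
            cells[(spec.method, label)] = res
            mean[i, j] = res.mean_accuracy
            se[i, j] = res.se
            runtime[i, j] = res.model_seconds
    return AccuracyTable(
        methods=methods,
        columns=list(column_labels),
        mean=mean,
        se=se,
        runtime=runtime,
        cells=cells,
        failed=failed,
    )


def fraction_sweep(
    table: TraitTable,
    specs: Sequence[ClassifierSpec],
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 1.0),
    protocol: CVProtocol | None = None,
    rank_C: float = 1.0,
) -> AccuracyTable:
    """CV accuracy of every method on each rank-feature fraction.

    Fraction ``f`` keeps the top ``ceil(f * p)`` traits of the per-fold
    SVM-RFE ranking; the ``1.0`` column uses all traits and bypasses
    ranking entirely.  Per-cell wall-clock (tune + fit + predict) is
    recorded for runtime profiles; ranking time is accounted separately
    because fold rankings are shared across cells.
    """
    if not fractions:
        raise ConfigurationError("fractions must be non-empty")
    for f in fractions:
        if not 0.0 < float(f) <= 1.0:
            raise ConfigurationError(f"fraction {f} outside (0, 1]")
    protocol = protocol or CVProtocol()
    labels = [f"{int(round(100 * f))}%" for f in fractions]
    return _sweep(table, specs, [float(f) for f in fractions], labels, protocol, rank_C)


def count_sweep(
    table: TraitTable,
    specs: Sequence[ClassifierSpec],
    counts: Sequence[int] = (2, 4, 6, 8, 10),
    protocol: CVProtocol | None = None,
    rank_C: float = 1.0,
) -> AccuracyTable:
    """As :func:`fraction_sweep` but with explicit top-k trait counts."""
    if not counts:
        raise ConfigurationError("counts must be non-empty")
    for k in counts:
        if not 1 <= int(k) <= table.n_traits:
            raise ConfigurationError(f"count {k} outside [1, {table.n_traits}]")
    protocol = protocol or CVProtocol()
    labels = [f"k={int(k)}" for k in counts]
    return _sweep(table, specs, [int(k) for k in counts], labels, protocol, rank_C)


def summarize(accuracy_table: AccuracyTable) -> pd.DataFrame:
    """Tidy rows (method, subset, mean, SE, runtime) + per-method best flag."""
    rows = []
    for i, m in enumerate(accuracy_table.methods):
        finite = np.nan_to_num(accuracy_table.mean[i], nan=-1.0)
        best_j = int(np.argmax(finite)) if np.any(finite >= 0) else -1
        for j, c in enumerate(accuracy_table.columns):
            rows.append(
                {
                    "method": m,
                    "subset": c,
                    "mean_accuracy": accuracy_table.mean[i, j],
                    "se": accuracy_table.se[i, j],
                    "runtime_s": accuracy_table.runtime[i, j],
                    "best_for_method": j == best_j,
                }
            )
    return pd.DataFrame(rows)
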