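"""Phase (a) of the framework: filtering replicated trait tables.

Image-export pipelines code missing measurements as ``0``; replicated
plants carry gross outliers; and image-derived traits are heavily
redundant.  The stages here address each in a fixed order:

1. :func:`drop_empty_values`   -- resolve zero/NaN-coded missing entries
2. :func:`remove_outliers`     -- Grubbs or Bonferroni outlier test per
   (replicate group x trait), flagged cells set to missing
3. :func:`reproducibility_filter` -- keep traits whose replicate pairs
   correlate (Pearson r >= r_min)
4. :func:`vif_stepwise`        -- drop the most collinear traits until
   every variance inflation factor is below a cap

Every filter is a projection (idempotent for fixed parameters) and never
edits a retained numeric value: filters only remove or flag rows, columns
or cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DataError,
    DegenerateInputError,
    DimensionalityError,
    InsufficientDataError,
)
from .table import TraitTable

logger = logging.getLogger("phenoselect.preprocess")

__all__ = [
    "FilterTrace",
    "OutlierFlag",
    "OutlierReport",
    "PreprocessConfig",
    "drop_empty_values",
    "grubbs_critical_value",
    "grubbs_outliers",
    "bonferroni_outliers",
    "studentized_residuals_and_bonferroni",
    "remove_outliers",
    "reproducibility_filter",
    "vif_stepwise",
    "compute_vifs",
    "preprocess_pipeline",
]


# ---------------------------------------------------------------------------
# audit records


@dataclass
class OutlierFlag:
    """One flagged observation: where it was and why."""

    index: int
    sample_id: str | None
    trait: str | None
    group: str | None
    statistic: float
    threshold: float  # Grubbs critical value, or Bonferroni-adjusted p


@dataclass
class OutlierReport:
    method: str  # "grubbs" | "bonferroni"
    alpha: float
    flagged: list[OutlierFlag] = field(default_factory=list)


@dataclass
class FilterTrace:
    """Audit log of one filtering stage."""

    stage: str
    samples_before: int
    samples_after: int
    traits_before: int
    traits_after: int
    removed_samples: list[str] = field(default_factory=list)
    removed_traits: list[str] = field(default_factory=list)
    flagged_cells: list[tuple[str, str]] = field(default_factory=list)
    reasons: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.samples_after != self.samples_before - len(self.removed_samples):
            raise ValueError("trace sample counts inconsistent with removals")
        if self.traits_after != self.traits_before - len(self.removed_traits):
            raise ValueError("trace trait counts inconsistent with removals")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "samples_before": self.samples_before,
            "samples_after": self.samples_after,
            "traits_before": self.traits_before,
            "traits_after": self.traits_after,
            "removed_samples": list(self.removed_samples),
            "removed_traits": list(self.removed_traits),
            "flagged_cells": [list(c) for c in self.flagged_cells],
            "reasons": self.reasons,
            "details": self.details,
        }


# ---------------------------------------------------------------------------
# missing values


def _missing_mask(
    table: TraitTable,
    zero_as_missing: bool,
    exempt_traits: Iterable[str],
) -> np.ndarray:
    mask = ~np.isfinite(table.values)
    if zero_as_missing:
        exempt = set(exempt_traits)
        zero_cols = [j for j, t in enumerate(table.trait_names) if t not in exempt]
        if zero_cols:
            mask[:, zero_cols] |= table.values[:, zero_cols] == 0.0
    return mask


def drop_empty_values(
    table: TraitTable,
    policy: str = "drop_sample",
    cutoff: float = 0.5,
    zero_as_missing: bool = True,
    exempt_traits: Iterable[str] = (),
) -> tuple[TraitTable, FilterTrace]:
    """Resolve missing measurements (NaN, and zero-coded empty values).

    ``policy``:
      * ``drop_sample`` -- remove every row containing a missing entry;
      * ``drop_trait``  -- remove traits whose missing fraction exceeds
        ``cutoff``; surviving missing entries stay masked as NaN;
      * ``mask``        -- only recode missing entries as NaN.

    ``exempt_traits`` lists traits whose genuine zeros must not be treated
    as missing.
    """
    if policy not in ("drop_sample", "drop_trait", "mask"):
        raise DataError(f"unknown missing-value policy {policy!r}")
    mask = _missing_mask(table, zero_as_missing, exempt_traits)
    n, p = table.values.shape

    if policy == "drop_sample":
        keep_rows = ~mask.any(axis=1)
        out = table.subset_samples(np.flatnonzero(keep_rows))
        removed = [table.sample_ids[i] for i in np.flatnonzero(~keep_rows)]
        trace = FilterTrace(
            stage="drop_empty_values",
            samples_before=n,
            samples_after=out.n_samples,
            traits_before=p,
            traits_after=p,
            removed_samples=removed,
            reasons={s: "contains missing/zero-coded value" for s in removed},
        )
        return out, trace

    values = table.values.copy()
    values[mask] = np.nan
    masked = TraitTable(
        values, table.trait_names, table.sample_ids, table.labels, table.metadata
    )
    if policy == "mask":
        cells = [
            (table.sample_ids[i], table.trait_names[j])
            for i, j in zip(*np.nonzero(mask))
        ]
        trace = FilterTrace(
            stage="drop_empty_values",
            samples_before=n,
            samples_after=n,
            traits_before=p,
            traits_after=p,
            flagged_cells=cells,
        )
        return masked, trace

    # drop_trait
    frac = mask.mean(axis=0)
    keep = [t for t, f in zip(table.trait_names, frac) if f <= cutoff]
    if not keep:
        raise DataError("drop_empty_values removed every trait")
    out = masked.subset_traits(keep)
    removed = [t for t in table.trait_names if t not in keep]
    trace = FilterTrace(
        stage="drop_empty_values",
        samples_before=n,
        samples_after=n,
        traits_before=p,
        traits_after=len(keep),
        removed_traits=removed,
        reasons={
            t: f"missing fraction {frac[table.trait_names.index(t)]:.3f} > {cutoff}"
            for t in removed
        },
    )
    return out, trace


# ---------------------------------------------------------------------------
# outlier tests


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(
    values,
    alpha: float = 0.05,
    iterate: bool = True,
    max_iter: int = 20,
) -> OutlierReport:
    """Two-sided Grubbs test for outliers in a normal sample.

    Computes ``G = max |x_i - mean| / s`` and flags the extreme point when
    ``G`` exceeds the critical value; by default the test is repeated on
    the reduced sample until nothing is flagged or fewer than 3 points
    remain.  Ties between equidistant extremes flag the lower index.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise DataError("grubbs_outliers expects a 1-D vector")
    if len(x) < 3:
        raise InsufficientDataError(f"Grubbs test needs N >= 3, got {len(x)}")
    if np.std(x, ddof=1) == 0:
        raise DegenerateInputError("zero sample variance: no outlier declared")

    report = OutlierReport(method="grubbs", alpha=alpha)
    active = list(range(len(x)))
    for _ in range(max_iter if iterate else 1):
        sub = x[active]
        n = len(sub)
        if n < 3:
            break
        s = np.std(sub, ddof=1)
        if s == 0:
            break
        dev = np.abs(sub - np.mean(sub))
        pos = int(np.argmax(dev))  # first max wins on exact ties
        g = dev[pos] / s
        crit = grubbs_critical_value(n, alpha)
        if g <= crit:
            break
        report.flagged.append(
            OutlierFlag(
                index=active[pos],
                sample_id=None,
                trait=None,
                group=None,
                statistic=float(g),
                threshold=float(crit),
            )
        )
        del active[pos]
    return report


def studentized_residuals_and_bonferroni(values) -> tuple[np.ndarray, np.ndarray]:
    """Externally studentized residuals and Bonferroni-adjusted p-values.

    The location-only model has leverage 1/N everywhere; the deleted
    residual variance is ``s_(i)^2 = (RSS - e_i^2/(1-h)) / (N-2)`` and the
    studentized residual is referred to a t distribution on N-2 degrees of
    freedom; the two-sided tail probability is multiplied by N and capped
    at 1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise DataError("expected a 1-D vector")
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"Bonferroni outlier test needs N >= 4, got {n}")
    e = x - np.mean(x)
    rss = float(np.sum(e**2))
    if rss == 0:
        raise DegenerateInputError("zero sample variance: no outlier declared")
    h = 1.0 / n
    s_del_sq = np.maximum((rss - e**2 / (1.0 - h)) / (n - 2), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_ext = e / np.sqrt(s_del_sq * (1.0 - h))
    r_ext = np.where(np.isfinite(r_ext), r_ext, np.inf * np.sign(e))
    p_adj = np.minimum(n * 2.0 * stats.t.sf(np.abs(r_ext), n - 2), 1.0)
    return r_ext, p_adj


def bonferroni_outliers(values, alpha: float = 0.05) -> OutlierReport:
    """Bonferroni outlier test on the location-only model.

    Flags observations whose Bonferroni-adjusted two-sided p-value (see
    :func:`studentized_residuals_and_bonferroni`) falls below ``alpha``.
    """
    r_ext, p_adj = studentized_residuals_and_bonferroni(values)
    report = OutlierReport(method="bonferroni", alpha=alpha)
    for i in np.flatnonzero(p_adj < alpha):
        report.flagged.append(
            OutlierFlag(
                index=int(i),
                sample_id=None,
                trait=None,
                group=None,
                statistic=float(r_ext[i]),
                threshold=float(p_adj[i]),
            )
        )
    return report


def remove_outliers(
    table: TraitTable,
    method: str = "grubbs",
    alpha: float = 0.05,
    group_columns: tuple[str, ...] = (),
    iterate: bool = True,
) -> tuple[TraitTable, FilterTrace, OutlierReport]:
    """Apply an outlier test per (replicate group x trait) and mask flags.

    Groups come from the metadata columns in ``group_columns`` (typically
    genotype and treatment); with no grouping every sample forms one
    group.  Flagged cells are set to missing -- whole samples are kept so
    their other traits survive.
    """
    if method not in ("grubbs", "bonferroni"):
        raise DataError(f"unknown outlier method {method!r}")
    test = grubbs_outliers if method == "grubbs" else bonferroni_outliers

    if group_columns:
        if table.metadata is None:
            raise DataError("group_columns given but table has no metadata")
        missing = [c for c in group_columns if c not in table.metadata.columns]
        if missing:
            raise DataError(f"metadata columns not found: {missing}")
        keys = (
            table.metadata[list(group_columns)].astype(str).agg("|".join, axis=1)
        )
    else:
        keys = pd.Series(["all"] * table.n_samples)

    values = table.values.copy()
    report = OutlierReport(method=method, alpha=alpha)
    skipped: dict[str, str] = {}
    for group in sorted(keys.unique()):
        rows = np.flatnonzero((keys == group).to_numpy())
        for j, trait in enumerate(table.trait_names):
            col = values[rows, j]
            ok = np.isfinite(col)
            if ok.sum() == 0:
                continue
            try:
                sub_report = test(col[ok], alpha=alpha, **(
                    {"iterate": iterate} if method == "grubbs" else {}
                ))
            except (InsufficientDataError, DegenerateInputError) as exc:
                skipped[f"{group}/{trait}"] = str(exc)
                continue
            sub_rows = rows[ok]
            for flag in sub_report.flagged:
                i = int(sub_rows[flag.index])
                values[i, j] = np.nan
                report.flagged.append(
                    OutlierFlag(
                        index=i,
                        sample_id=table.sample_ids[i],
                        trait=trait,
                        group=group,
                        statistic=flag.statistic,
                        threshold=flag.threshold,
                    )
                )

    out = TraitTable(
        values, table.trait_names, table.sample_ids, table.labels, table.metadata
    )
    trace = FilterTrace(
        stage=f"outliers_{method}",
        samples_before=table.n_samples,
        samples_after=table.n_samples,
        traits_before=table.n_traits,
        traits_after=table.n_traits,
        flagged_cells=[(f.sample_id, f.trait) for f in report.flagged],
        details={"skipped_groups": skipped, "alpha": alpha},
    )
    return out, trace, report


# ---------------------------------------------------------------------------
# reproducibility


def _replicate_pairs(
    table: TraitTable, replicate_map: str | Mapping[str, str] | pd.Series
) -> list[tuple[int, int]]:
    """Row-index pairs of replicated measurements, deterministic order."""
    if isinstance(replicate_map, str):
        if table.metadata is None or replicate_map not in table.metadata.columns:
            raise DataError(f"replicate column {replicate_map!r} not in metadata")
        groups = table.metadata[replicate_map].astype(str)
    else:
        mapping = dict(replicate_map)
        groups = pd.Series([mapping.get(s, None) for s in table.sample_ids])
    pairs: list[tuple[int, int]] = []
    frame = pd.DataFrame({"g": groups, "i": np.arange(table.n_samples)})
    for _, grp in frame.dropna().groupby("g", sort=True):
        idx = grp["i"].tolist()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                pairs.append((idx[a], idx[b]))
    return pairs


def reproducibility_filter(
    table: TraitTable,
    replicate_map: str | Mapping[str, str] | pd.Series,
    r_min: float = 0.7,
) -> tuple[TraitTable, FilterTrace]:
    """Keep traits whose replicate measurements correlate (Pearson r).

    For every trait the paired replicate values (all within-group pairs of
    samples sharing a replicate group) form two vectors whose Pearson
    correlation estimates trait reproducibility; traits with
    ``r < r_min`` are removed.  Traits with fewer than 3 complete pairs or
    degenerate pair variance are marked "not assessable" and retained.
    ``r_min = 0`` disables the filter.
    """
    if not 0.0 <= r_min <= 1.0:
        raise DataError("r_min must lie in [0, 1]")
    pairs = _replicate_pairs(table, replicate_map)
    r_by_trait: dict[str, float | None] = {}
    not_assessable: list[str] = []
    for j, trait in enumerate(table.trait_names):
        u, v = [], []
        for a, b in pairs:
            xa, xb = table.values[a, j], table.values[b, j]
            if np.isfinite(xa) and np.isfinite(xb):
                u.append(xa)
                v.append(xb)
        if len(u) < 3 or np.std(u) == 0 or np.std(v) == 0:
            r_by_trait[trait] = None
            not_assessable.append(trait)
            continue
        r_by_trait[trait] = float(stats.pearsonr(u, v)[0])

    if r_min == 0.0:
        keep = list(table.trait_names)
    else:
        keep = [
            t
            for t in table.trait_names
            if r_by_trait[t] is None or r_by_trait[t] >= r_min
        ]
    if not keep:
        raise DataError("reproducibility filter removed every trait")
    removed = [t for t in table.trait_names if t not in keep]
    out = table.subset_traits(keep)
    trace = FilterTrace(
        stage="reproducibility",
        samples_before=table.n_samples,
        samples_after=table.n_samples,
        traits_before=table.n_traits,
        traits_after=len(keep),
        removed_traits=removed,
        reasons={t: f"replicate Pearson r = {r_by_trait[t]:.4f} < {r_min}" for t in removed},
        details={
            "r_by_trait": r_by_trait,
            "not_assessable": not_assessable,
            "n_pairs": len(pairs),
        },
    )
    return out, trace


# ---------------------------------------------------------------------------
# multicollinearity


def compute_vifs(values: np.ndarray) -> np.ndarray:
    """Variance inflation factor of every column.

    VIF_i = 1 / (1 - R_i^2) with R_i^2 from regressing column i on the
    remaining columns plus an intercept.  Perfect collinearity (including
    constant columns) yields +inf.
    """
    x = np.asarray(values, dtype=float)
    n, p = x.shape
    vifs = np.empty(p)
    for i in range(p):
        y = x[:, i]
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0.0:
            vifs[i] = np.inf  # constant column: collinear with the intercept
            continue
        a = np.column_stack([np.delete(x, i, axis=1), np.ones(n)])
        coef, _, _, _ = np.linalg.lstsq(a, y, rcond=None)
        rss = float(np.sum((y - a @ coef) ** 2))
        r2 = 1.0 - rss / tss
        vifs[i] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_stepwise(
    table: TraitTable, vif_max: float = 10.0
) -> tuple[TraitTable, FilterTrace]:
    """Stepwise removal of the most collinear traits.

    Recomputes all VIFs each round and removes the trait with the largest
    VIF while that maximum exceeds ``vif_max`` (ties: lowest column index);
    stops once at most two traits remain.  Missing entries are excluded
    row-wise (complete-case regression).
    """
    if table.n_traits < 2:
        raise DataError("vif_stepwise needs at least 2 traits")
    complete = np.all(np.isfinite(table.values), axis=1)
    x_full = table.values[complete]
    if x_full.shape[0] <= table.n_traits:
        raise DimensionalityError(
            f"VIF needs more complete samples ({x_full.shape[0]}) than traits "
            f"({table.n_traits}); apply missing-value and outlier filtering first"
        )
    surviving = list(range(table.n_traits))
    removal_sequence: list[tuple[str, float]] = []
    while len(surviving) > 2:
        vifs = compute_vifs(x_full[:, surviving])
        worst = int(np.argmax(vifs))  # first max wins on ties
        if vifs[worst] <= vif_max:
            break
        removal_sequence.append(
            (table.trait_names[surviving[worst]], float(vifs[worst]))
        )
        del surviving[worst]
    keep = [table.trait_names[i] for i in surviving]
    out = table.subset_traits(keep)
    final_vifs = compute_vifs(x_full[:, surviving])
    trace = FilterTrace(
        stage="vif_stepwise",
        samples_before=table.n_samples,
        samples_after=table.n_samples,
        traits_before=table.n_traits,
        traits_after=len(keep),
        removed_traits=[t for t, _ in removal_sequence],
        reasons={t: f"VIF = {v:.4g} > {vif_max}" for t, v in removal_sequence},
        details={
            "vif_max": vif_max,
            "final_vifs": {t: float(v) for t, v in zip(keep, final_vifs)},
            "removal_sequence": [[t, v] for t, v in removal_sequence],
        },
    )
    return out, trace


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PreprocessConfig:
    """Stage switches and parameters for :func:`preprocess_pipeline`."""

    drop_empty: bool = True
    missing_policy: str = "drop_sample"
    missing_cutoff: float = 0.5
    zero_as_missing: bool = True
    exempt_traits: tuple[str, ...] = ()

    outliers: bool = True
    outlier_method: str = "grubbs"
    outlier_alpha: float = 0.05
    group_columns: tuple[str, ...] = ()

    reproducibility: bool = False
    replicate_column: str = "replicate_group"
    r_min: float = 0.7

    vif: bool = True
    vif_max: float = 10.0


def preprocess_pipeline(
    table: TraitTable, config: PreprocessConfig
) -> tuple[TraitTable, list[FilterTrace]]:
    """Run the enabled stages in their fixed order and collect traces.

    Order: missing values -> outlier masking (then missing policy again,
    so masked cells are resolved) -> reproducibility -> VIF.
    """
    traces: list[FilterTrace] = []
    current = table
    try:
        if config.drop_empty:
            current, trace = drop_empty_values(
                current,
                policy=config.missing_policy,
                cutoff=config.missing_cutoff,
                zero_as_missing=config.zero_as_missing,
                exempt_traits=config.exempt_traits,
            )
            traces.append(trace)
        if config.outliers:
            current, trace, _ = remove_outliers(
                current,
                method=config.outlier_method,
                alpha=config.outlier_alpha,
                group_columns=config.group_columns,
            )
            traces.append(trace)
            if config.drop_empty and trace.flagged_cells:
                # flagged cells became missing; resolve them the same way
                current, trace2 = drop_empty_values(
                    current,
                    policy=config.missing_policy,
                    cutoff=config.missing_cutoff,
                    zero_as_missing=False,
                )
                traces.append(trace2)
        if config.reproducibility:
            current, trace = reproducibility_filter(
                current, config.replicate_column, r_min=config.r_min
            )
            traces.append(trace)
        if config.vif:
            current, trace = vif_stepwise(current, vif_max=config.vif_max)
            traces.append(trace)
    except DataError as exc:
        stage = traces[-1].stage if traces else "start"
        raise type(exc)(f"after stage {stage!r}: {exc}") from exc
    for trace in traces:
        logger.info(
            "%s: traits %d -> %d, samples %d -> %d, cells flagged %d",
            trace.stage, trace.traits_before, trace.traits_after,
            trace.samples_before, trace.samples_after, len(trace.flagged_cells),
        )
    return current, traces
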