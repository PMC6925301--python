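"""SVM-RFE: recursive feature elimination with a linear SVM.

A soft-margin linear SVM trained on the surviving traits yields the weight
vector ``w = sum_t alpha_t y_t x_t`` over its support vectors; the squared
weight ``w_i^2`` scores how much trait ``i`` contributes to the margin
(it is the leading term of the change in the SVM objective when the trait
is removed).  The trait with the smallest score is eliminated, the SVM is
retrained on the survivors, and the procedure repeats until every trait
has been eliminated, producing a complete ranking (best trait = the last
survivor).

Because ``w_i`` depends on the unit of trait ``i``, traits are z-scored
(mean 0, variance 1, training statistics) before ranking by default;
without standardization the criterion is unit-dependent and rankings are
not comparable across heterogeneous image-derived traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .errors import ConfigurationError, DataError, LabelError
from .table import TraitTable

__all__ = [
    "RankingResult",
    "linear_svm_weights",
    "svm_rfe",
    "rfe_rank_arrays",
    "select_top",
]

#: solver tolerance for the linear SVMs trained inside RFE; tight enough
#: that the squared-weight criterion is stable to well below ranking ties
SVM_TOL = 1e-8

#: squared weights below this are solver noise around an exactly-zero
#: weight (e.g. an inseparable surviving set has w = 0); they are snapped
#: to 0 so the deterministic lowest-index tie-break decides, independent
#: of which QP solver produced the weights
CRITERION_ZERO_TOL = 1e-10


@dataclass
class RankingResult:
    """Complete SVM-RFE output.

    ``ranked_traits`` lists traits best-first; ``elimination_order`` lists
    them in the order they were eliminated (worst first, final survivor
    last), so for single-trait steps it is ``ranked_traits`` reversed.
    ``criteria_history[k]`` maps every trait surviving at iteration ``k``
    to its squared weight.
    """

    ranked_traits: list[str]
    elimination_order: list[str]
    criteria_history: list[dict[str, float]] = field(default_factory=list)
    svm_cost: float = 1.0
    step_size: int = 1
    standardized: bool = True

    def __post_init__(self) -> None:
        if sorted(self.ranked_traits) != sorted(self.elimination_order):
            raise ValueError("ranking and elimination order disagree on traits")
        if len(set(self.ranked_traits)) != len(self.ranked_traits):
            raise ValueError("ranked_traits contains duplicates")
        for crit in self.criteria_history:
            if any(v < 0 for v in crit.values()):
                raise ValueError("squared-weight criteria must be >= 0")


def _check_binary(y: np.ndarray) -> None:
    classes = np.unique(y)
    if len(classes) < 2:
        raise LabelError("training labels contain a single class")
    if len(classes) > 2:
        raise LabelError(
            f"SVM-RFE supports binary labels only, got classes {classes.tolist()}"
        )


def linear_svm_weights(X, y, C: float = 1.0, tol: float = SVM_TOL) -> np.ndarray:
    """Weight vector of a soft-margin linear SVM, one entry per column.

    Returns ``w = sum_t alpha_t y_t x_t`` over the support vectors.  A
    zero column receives weight exactly 0; flipping all labels flips the
    sign of ``w`` and leaves ``w_i^2`` unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if C <= 0:
        raise ConfigurationError("SVM cost C must be > 0")
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite values in the training matrix")
    _check_binary(y)
    svc = SVC(kernel="linear", C=C, tol=tol)
    svc.fit(X, y)
    return svc.coef_.ravel().copy()


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)  # constant columns stay constant (at 0)
    return (X - mu) / sd


def rfe_rank_arrays(
    X,
    y,
    trait_names: list[str] | None = None,
    C: float = 1.0,
    step_size: int = 1,
    standardize: bool = True,
) -> RankingResult:
    """SVM-RFE on raw arrays; the array-level core behind :func:`svm_rfe`.

    Each round trains a linear SVM on the surviving columns, scores every
    survivor by its squared weight, and eliminates the ``step_size``
    lowest-scoring traits (ties: lowest column index first).  The final
    survivor is ranked first without a degenerate single-trait training
    round.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise DataError("X must be 2-D")
    n, p = X.shape
    if trait_names is None:
        trait_names = [f"trait_{j + 1:03d}" for j in range(p)]
    if len(trait_names) != p:
        raise DataError("trait_names length must match columns of X")
    if step_size < 1:
        raise ConfigurationError("step_size must be >= 1")
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite values in the training matrix")
    _check_binary(y)

    if p == 1:
        return RankingResult(
            ranked_traits=list(trait_names),
            elimination_order=list(trait_names),
            criteria_history=[],
            svm_cost=C,
            step_size=step_size,
            standardized=standardize,
        )

    Xw = _standardize(X) if standardize else X
    surviving = list(range(p))
    eliminated: list[int] = []
    history: list[dict[str, float]] = []
    while len(surviving) > 1:
        w = linear_svm_weights(Xw[:, surviving], y, C=C)
        crit = w**2
        crit[crit < CRITERION_ZERO_TOL] = 0.0
        history.append(
            {trait_names[t]: float(c) for t, c in zip(surviving, crit)}
        )
        k = min(step_size, len(surviving) - 1)
        # stable argsort: equal criteria eliminate the lower column index first
        drop_local = np.argsort(crit, kind="stable")[:k]
        dropped = [surviving[i] for i in drop_local.tolist()]
        eliminated.extend(dropped)
        surviving = [t for t in surviving if t not in dropped]
    eliminated.extend(surviving)  # the survivor, eliminated last = rank 1

    elimination_order = [trait_names[t] for t in eliminated]
    return RankingResult(
        ranked_traits=list(reversed(elimination_order)),
        elimination_order=elimination_order,
        criteria_history=history,
        svm_cost=C,
        step_size=step_size,
        standardized=standardize,
    )


def svm_rfe(
    table: TraitTable,
    C: float = 1.0,
    step_size: int = 1,
    standardize: bool = True,
) -> RankingResult:
    """Rank the traits of a labeled table by SVM-RFE."""
    return rfe_rank_arrays(
        table.values,
        table.labels,
        trait_names=table.trait_names,
        C=C,
        step_size=step_size,
        standardize=standardize,
    )


def select_top(ranking: RankingResult, k_or_fraction: int | float) -> list[str]:
    """First ``k`` ranked traits; a float fraction ``f`` maps to ceil(f*p).

    An ``int`` is an explicit count in ``[1, p]``; a ``float`` must lie in
    ``(0, 1]`` (so ``1`` means the single best trait while ``1.0`` means
    all traits).
    """
    p = len(ranking.ranked_traits)
    if isinstance(k_or_fraction, bool):
        raise ConfigurationError("k must be an int count or float fraction")
    if isinstance(k_or_fraction, int):
        k = k_or_fraction
        if not 1 <= k <= p:
            raise ConfigurationError(f"k = {k} outside [1, {p}]")
    else:
        f = float(k_or_fraction)
        if not 0.0 < f <= 1.0:
            raise ConfigurationError(f"fraction = {f} outside (0, 1]")
        k = math.ceil(f * p)
    return ranking.ranked_traits[:k]
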