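"""Two-class multivariate-normal trait simulator.

The generator draws ``n1`` samples from ``N_p(mu1, V)`` and ``n2`` samples
from ``N_p(mu1 + eps * 1_S, V)``: two p-variate normal populations sharing a
constant covariance matrix ``V``, whose mean vectors differ by a common
scalar shift ``eps`` on an (optionally restricted) informative subset ``S``
of traits.  Under this model the best achievable classification accuracy
with equal priors has the closed form

    Phi(Delta / 2),   Delta^2 = (mu2 - mu1)' V^{-1} (mu2 - mu1),

which :func:`bayes_accuracy` exposes as an analytic oracle for calibrating
classifiers and cross-validation harnesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError
from .table import TraitTable

__all__ = [
    "EpsilonGrid",
    "SimulationConfig",
    "make_covariance",
    "simulate_two_class",
    "bayes_accuracy",
]

COV_FAMILIES = ("identity", "compound_symmetry", "ar1", "custom")


@dataclass(frozen=True)
class EpsilonGrid:
    """A grid of mean shifts ``start, start+step, ..., <= stop``.

    When a config carries a grid rather than a scalar, each replicate
    generation uses one grid value, either cycling through the grid in
    order (``round_robin``) or drawing uniformly at random (``random``).
    """

    start: float
    stop: float
    step: float

    def values(self) -> np.ndarray:
        if self.step <= 0:
            raise ConfigurationError("epsilon grid step must be > 0")
        if self.stop < self.start:
            raise ConfigurationError("epsilon grid stop must be >= start")
        n = int(round((self.stop - self.start) / self.step)) + 1
        vals = self.start + self.step * np.arange(n)
        return vals[vals <= self.stop + 1e-12]


@dataclass
class SimulationConfig:
    """Full specification of the two-population generator.

    ``informative_subset`` holds 0-based trait indices that receive the
    mean shift; ``None`` shifts every trait.  ``epsilon_policy`` selects
    how a grid epsilon is mapped onto replicate generations.
    """

    n1: int
    n2: int
    p: int
    epsilon: float | EpsilonGrid = 1.0
    cov_family: str = "compound_symmetry"
    sigma: float = 1.0
    rho: float = 0.0
    mu1: np.ndarray | None = None
    informative_subset: list[int] | None = None
    seed: int = 0
    epsilon_policy: str = "round_robin"
    custom_cov: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ConfigurationError("n1 and n2 must each be >= 1")
        if self.p < 1:
            raise ConfigurationError("p must be >= 1")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if self.cov_family not in COV_FAMILIES:
            raise ConfigurationError(
                f"cov_family must be one of {COV_FAMILIES}, got {self.cov_family!r}"
            )
        if self.epsilon_policy not in ("round_robin", "random"):
            raise ConfigurationError("epsilon_policy must be round_robin or random")
        if self.mu1 is not None and len(np.atleast_1d(self.mu1)) != self.p:
            raise ConfigurationError("mu1 length must equal p")
        if self.informative_subset is not None:
            s = set(self.informative_subset)
            if not s:
                raise ConfigurationError("informative_subset must be non-empty")
            if not s.issubset(range(self.p)):
                raise ConfigurationError(
                    "informative_subset indices must lie in [0, p)"
                )

    # convenience used throughout: the base mean as an array
    def mean1(self) -> np.ndarray:
        if self.mu1 is None:
            return np.zeros(self.p)
        return np.asarray(self.mu1, dtype=float)

    def shift_vector(self, epsilon: float) -> np.ndarray:
        d = np.zeros(self.p)
        idx = (
            np.arange(self.p)
            if self.informative_subset is None
            else np.asarray(sorted(self.informative_subset))
        )
        d[idx] = epsilon
        return d


def make_covariance(
    cov_family: str,
    p: int,
    sigma: float = 1.0,
    rho: float = 0.0,
    custom: np.ndarray | None = None,
) -> np.ndarray:
    """Build the p x p covariance matrix for a named family.

    identity           sigma^2 * I (rho ignored)
    compound_symmetry  diagonal sigma^2, off-diagonal sigma^2 * rho;
                       positive definite iff -1/(p-1) < rho < 1
    ar1                entry (i, j) = sigma^2 * rho^|i-j|; needs |rho| < 1
    custom             caller-supplied symmetric positive-definite matrix
    """
    if p < 1:
        raise ConfigurationError("p must be >= 1")
    if sigma <= 0:
        raise ConfigurationError("sigma must be > 0")
    if cov_family == "identity":
        return sigma**2 * np.eye(p)
    if cov_family == "compound_symmetry":
        lower = -1.0 / (p - 1) if p > 1 else -np.inf
        if not (lower < rho < 1.0):
            raise ConfigurationError(
                f"compound symmetry needs -1/(p-1) = {lower:.4g} < rho < 1, "
                f"got rho = {rho}"
            )
        v = sigma**2 * ((1.0 - rho) * np.eye(p) + rho * np.ones((p, p)))
        return v
    if cov_family == "ar1":
        if not abs(rho) < 1.0:
            raise ConfigurationError(f"AR(1) needs |rho| < 1, got rho = {rho}")
        lags = np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
        return sigma**2 * rho**lags
    if cov_family == "custom":
        if custom is None:
            raise ConfigurationError("custom covariance family needs a matrix")
        v = np.asarray(custom, dtype=float)
        if v.shape != (p, p):
            raise ConfigurationError(f"custom covariance must be {p}x{p}")
        if not np.allclose(v, v.T):
            raise ConfigurationError("custom covariance must be symmetric")
        try:
            np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            raise ConfigurationError(
                "custom covariance is not positive definite"
            ) from None
        return v
    raise ConfigurationError(f"unknown covariance family {cov_family!r}")


def _config_covariance(config: SimulationConfig) -> np.ndarray:
    return make_covariance(
        config.cov_family, config.p, config.sigma, config.rho, config.custom_cov
    )


def _resolve_epsilon(config: SimulationConfig, replicate_index: int) -> float:
    if not isinstance(config.epsilon, EpsilonGrid):
        return float(config.epsilon)
    grid = config.epsilon.values()
    if config.epsilon_policy == "round_robin":
        return float(grid[replicate_index % len(grid)])
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1_000_003, int(replicate_index)])
    )
    return float(rng.choice(grid))


def simulate_two_class(
    config: SimulationConfig, replicate_index: int = 0
) -> TraitTable:
    """Draw one labeled trait table from the two-population model.

    The first ``n1`` rows are class 0 (``N(mu1, V)``), the remaining ``n2``
    rows class 1 (``N(mu1 + eps * 1_S, V)``).  Output is bit-identical for
    identical config and ``replicate_index``.
    """
    config.validate()
    v = _config_covariance(config)
    eps = _resolve_epsilon(config, replicate_index)
    mu1 = config.mean1()
    mu2 = mu1 + config.shift_vector(eps)

    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(replicate_index)])
    )
    chol = np.linalg.cholesky(v)
    z = rng.standard_normal((config.n1 + config.n2, config.p))
    x = z @ chol.T
    x[: config.n1] += mu1
    x[config.n1 :] += mu2

    labels = np.concatenate(
        [np.zeros(config.n1, dtype=int), np.ones(config.n2, dtype=int)]
    )
    return TraitTable(
        values=x,
        trait_names=[f"trait_{j + 1:03d}" for j in range(config.p)],
        sample_ids=[f"s{i + 1:05d}" for i in range(config.n1 + config.n2)],
        labels=labels,
    )


def bayes_accuracy(config: SimulationConfig) -> float:
    """Optimal equal-prior accuracy Phi(Delta/2) of the configured model.

    Delta is the Mahalanobis distance between the two class means under
    the shared covariance.  Requires a scalar epsilon.
    """
    config.validate()
    if isinstance(config.epsilon, EpsilonGrid):
        raise ConfigurationError(
            "bayes_accuracy needs a scalar epsilon, not a grid"
        )
    v = _config_covariance(config)
    d = config.shift_vector(float(config.epsilon))
    try:
        sol = np.linalg.solve(v, d)
    except np.linalg.LinAlgError as exc:
        raise DataError(f"singular covariance matrix: {exc}") from exc
    delta_sq = float(d @ sol)
    return float(stats.norm.cdf(np.sqrt(max(delta_sq, 0.0)) / 2.0))
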