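"""Genetic-algorithm descriptor-subset selection.

Candidate subsets of a fixed size are scored by leave-one-out
cross-validated Q² and screened with the QUIK collinearity rule: a
subset is acceptable only when the multivariate correlation of its
descriptor block augmented with the response (Kxy) exceeds that of the
descriptor block alone (Kxx) by at least a threshold ΔK.  Subsets
failing QUIK keep their Q² score but carry a large penalty, so the
search still has a gradient through infeasible regions while the
reported winner is always feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix

_QUIK_PENALTY = 1e3


@dataclass
class GAConfig:
    """Settings of the evolutionary search.

    The published workflow fixes the subset size at six descriptors;
    the genetic operators (tournament of 2, uniform index-set
    crossover, single-descriptor point mutation) are this package's
    own reproducible defaults.
    """

    subset_size: int = 6
    population_size: int = 100
    generations: int = 200
    mutation_rate: float = 0.3
    crossover_rate: float = 0.9
    elitism: int = 2
    seed: int = 0
    quik_delta: float = 0.05
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        for r in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.elitism < 0 or self.elitism > self.population_size:
            raise ValueError("elitism must lie in [0, population_size]")


@dataclass
class Chromosome:
    indices: tuple[int, ...]
    fitness: float

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("chromosome indices must be unique")


@dataclass
class SelectionResult:
    """Ranked feasible subsets plus the per-generation fitness trace."""

    best_subsets: list[tuple[tuple[str, ...], float]]
    trace_best: list[float]
    trace_mean: list[float]
    config: GAConfig

    @property
    def best_names(self) -> tuple[str, ...]:
        return self.best_subsets[0][0]

    @property
    def best_fitness(self) -> float:
        return self.best_subsets[0][1]


# ---------------------------------------------------------------------------
# Fitness and the QUIK rule


def q2_loo_fitness(X, y) -> float:
    """Leave-one-out cross-validated Q² = 1 - PRESS/TSS.

    Uses the hat-matrix identity for OLS: the LOO residual of point i
    equals e_i / (1 - h_ii), so no refitting is needed.  Singular
    subsets score -inf.
    """
    arr = _as_array(X)
    yv = np.asarray(y, dtype=float)
    n, p = arr.shape
    if n <= p + 1:
        raise ValueError("need more rows than descriptors + 1")
    D = np.column_stack([np.ones(n), arr])
    q, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    if diag.min() <= diag.max() * n * np.finfo(float).eps:
        return -np.inf
    h = np.einsum("ij,ij->i", q, q)
    resid = yv - q @ (q.T @ yv)
    denom = 1.0 - h
    if np.any(denom <= 1e-12):
        return -np.inf
    press = float(np.sum((resid / denom) ** 2))
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss == 0:
        return -np.inf
    return 1.0 - press / tss


def k_statistic(M: np.ndarray) -> float:
    """Todeschini's multivariate K correlation index of a column block.

    K = sum_j |λ_j/Σλ - 1/p| / (2(p-1)/p), with λ the eigenvalues of
    the correlation matrix: 0 for mutually orthogonal columns, 1 for
    perfect collinearity.
    """
    M = np.asarray(M, dtype=float)
    p = M.shape[1]
    if p < 2:
        raise ValueError("K needs at least 2 columns")
    sd = M.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance column in K computation")
    corr = np.corrcoef(M, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    frac = lam / lam.sum()
    return float(np.sum(np.abs(frac - 1.0 / p)) / (2.0 * (p - 1) / p))


@dataclass
class QuikResult:
    kxx: float
    kxy: float
    delta: float
    passed: bool


def quik_filter(X, y, delta: float = 0.05) -> QuikResult:
    """QUIK rule: accept a subset only if Kxy - Kxx >= delta."""
    arr = _as_array(X)
    yv = np.asarray(y, dtype=float).reshape(-1, 1)
    kxx = k_statistic(arr)
    kxy = k_statistic(np.hstack([arr, yv]))
    return QuikResult(kxx=kxx, kxy=kxy, delta=kxy - kxx, passed=kxy - kxx >= delta)


def _as_array(X) -> np.ndarray:
    if isinstance(X, DescriptorMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# Evolution


def _subset_score(
    arr: np.ndarray,
    y: np.ndarray,
    subset: tuple[int, ...],
    quik_delta: float,
    cache: dict,
) -> float:
    if subset in cache:
        return cache[subset]
    Xs = arr[:, list(subset)]
    score = q2_loo_fitness(Xs, y)
    if np.isfinite(score) and len(subset) >= 2:
        try:
            if not quik_filter(Xs, y, quik_delta).passed:
                score -= _QUIK_PENALTY
        except ValueError:
            score = -np.inf
    cache[subset] = score
    return score


def evolve(pool: DescriptorMatrix | pd.DataFrame, y=None, config: GAConfig | None = None) -> SelectionResult:
    """Run the GA over a descriptor pool and return ranked subsets.

    Deterministic for a given seed.  Raises when no evaluated subset
    satisfies the QUIK rule.
    """
    config = config or GAConfig()
    if isinstance(pool, DescriptorMatrix):
        if y is None:
            y = pool.activity
        names = pool.descriptor_names
        arr = pool.values
    else:
        names = list(pool.columns)
        arr = pool.to_numpy(dtype=float)
    if y is None:
        raise ValueError("y required")
    yv = np.asarray(y, dtype=float)
    n_cols = arr.shape[1]
    k = config.subset_size
    if n_cols < k:
        raise ValueError(f"pool has {n_cols} columns, need >= {k}")
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple[int, ...], float] = {}

    def score(subset: tuple[int, ...]) -> float:
        return _subset_score(arr, yv, subset, config.quik_delta, cache)

    if n_cols == k:
        subset = tuple(range(n_cols))
        fit = score(subset)
        return _result([(subset, fit)], [fit], [fit], config, names)

    population = [
        tuple(sorted(rng.choice(n_cols, size=k, replace=False)))
        for _ in range(config.population_size)
    ]
    trace_best: list[float] = []
    trace_mean: list[float] = []

    for _gen in range(config.generations):
        fits = np.array([score(s) for s in population])
        order = np.argsort(-fits, kind="stable")
        trace_best.append(float(fits[order[0]]))
        finite = fits[np.isfinite(fits)]
        trace_mean.append(float(finite.mean()) if len(finite) else -np.inf)

        next_pop = [population[i] for i in order[: config.elitism]]
        while len(next_pop) < config.population_size:
            p1 = _tournament(population, fits, rng)
            p2 = _tournament(population, fits, rng)
            if rng.random() < config.crossover_rate:
                child = _crossover(p1, p2, k, rng)
            else:
                child = p1
            if rng.random() < config.mutation_rate:
                child = _mutate(child, n_cols, rng)
            next_pop.append(child)
        population = next_pop

    fits = np.array([score(s) for s in population])
    ranked = sorted(cache.items(), key=lambda kv: (-kv[1], kv[0]))
    feasible = [(s, f) for s, f in ranked if np.isfinite(f) and f > -_QUIK_PENALTY / 2]
    if not feasible:
        raise RuntimeError(
            "no descriptor subset passed the QUIK rule; consider relaxing quik_delta"
        )
    trace_best.append(float(max(fits)))
    finite = fits[np.isfinite(fits)]
    trace_mean.append(float(finite.mean()) if len(finite) else -np.inf)
    return _result(feasible[: config.top_k], trace_best, trace_mean, config, names)


def _result(pairs, trace_best, trace_mean, config, names) -> SelectionResult:
    named = [(tuple(names[i] for i in subset), float(f)) for subset, f in pairs]
    return SelectionResult(
        best_subsets=named,
        trace_best=trace_best,
        trace_mean=trace_mean,
        config=config,
    )


def _tournament(population, fits, rng) -> tuple[int, ...]:
    i, j = rng.integers(0, len(population), size=2)
    return population[i] if fits[i] >= fits[j] else population[j]


def _crossover(p1, p2, k, rng) -> tuple[int, ...]:
    common = sorted(set(p1) & set(p2))
    rest = sorted(set(p1) ^ set(p2))
    need = k - len(common)
    pick = rng.choice(len(rest), size=need, replace=False)
    return tuple(sorted(common + [rest[i] for i in pick]))


def _mutate(subset, n_cols, rng) -> tuple[int, ...]:
    current = set(subset)
    outside = sorted(set(range(n_cols)) - current)
    if not outside:
        return subset
    drop = subset[rng.integers(0, len(subset))]
    add = outside[rng.integers(0, len(outside))]
    return tuple(sorted((current - {drop}) | {add}))


def exhaustive_best(
    pool: DescriptorMatrix | pd.DataFrame,
    y=None,
    subset_size: int = 6,
    quik_delta: float = 0.05,
) -> tuple[tuple[str, ...], float]:
    """Enumerate every subset; the oracle the GA is tested against on
    small pools."""
    if isinstance(pool, DescriptorMatrix):
        if y is None:
            y = pool.activity
        names = pool.descriptor_names
        arr = pool.values
    else:
        names = list(pool.columns)
        arr = pool.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    cache: dict[tuple[int, ...], float] = {}
    best, best_fit = None, -np.inf
    for subset in combinations(range(arr.shape[1]), subset_size):
        f = _subset_score(arr, yv, subset, quik_delta, cache)
        if f > best_fit:
            best, best_fit = subset, f
    if best is None or best_fit <= -_QUIK_PENALTY / 2:
        raise RuntimeError("no feasible subset")
    return tuple(names[i] for i in best), float(best_fit)
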