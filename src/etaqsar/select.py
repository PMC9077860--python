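"""Genetic-algorithm descriptor selection under double cross-validation.

The outer loop of double cross-validation (DCV) is the train/test
division: the test set is never touched during selection.  Inside the
training set, candidate descriptor subsets (chromosomes) are scored by
repeated k-fold cross-validation — ordinary least squares fitted on each
calibration part, errors pooled over the validation parts — so that no
single fixed calibration/validation composition biases the choice of
descriptors.  A small generational GA (tournament selection, one-point
crossover, per-bit mutation, elitism of one) searches the subset space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import q2_external, r2, rmse
from .preprocess import DescriptorTable


@dataclass
class GaConfig:
    population: int = 50
    generations: int = 100
    crossover_p: float = 0.9
    mutation_p: float = 0.01
    elitism: int = 1
    max_subset_size: int = 5
    tournament_size: int = 2


@dataclass
class DcvConfig:
    """Inner-loop cross-validation and GA settings."""

    k_folds: int = 10
    n_repeats: int = 10
    ga: GaConfig = field(default_factory=GaConfig)
    seed: int = 0
    fitness: str = "mae"  # or "rmse"

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.ga.max_subset_size < 1:
            raise ValueError("max_subset_size must be >= 1")
        if self.fitness not in ("mae", "rmse"):
            raise ValueError("fitness must be 'mae' or 'rmse'")


@dataclass
class Chromosome:
    """A descriptor subset with its pooled validation-error fitness."""

    mask: tuple[int, ...]       # sorted column indices
    fitness: float

    def columns(self, names: list[str]) -> list[str]:
        return [names[i] for i in self.mask]


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels stratified by response quantile (stabilizes small-n folds)."""
    n = len(y)
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    # walk the response-sorted rows in blocks of k, dealing fold labels randomly
    for start in range(0, n, k):
        block = order[start:start + k]
        labels = rng.permutation(k)[: len(block)]
        folds[block] = labels
    return folds


def _ols_cv_errors(X: np.ndarray, y: np.ndarray, folds: np.ndarray, k: int) -> np.ndarray | None:
    """Pooled validation residuals of per-fold OLS fits; None if degenerate."""
    n, p = X.shape
    errors = np.empty(n)
    Xd = np.column_stack([np.ones(n), X])
    for f in range(k):
        val = folds == f
        cal = ~val
        if cal.sum() <= p + 1 or val.sum() == 0:
            return None
        coef, _, rank, _ = np.linalg.lstsq(Xd[cal], y[cal], rcond=None)
        if rank < p + 1:
            return None
        errors[val] = y[val] - Xd[val] @ coef
    return errors


def evaluate_subset(
    subset: tuple[int, ...] | list[int],
    train: DescriptorTable,
    cfg: DcvConfig,
) -> float:
    """Pooled k-fold validation error of an OLS model on the subset.

    Averages over ``n_repeats`` reshuffled fold assignments.  Returns
    +inf for empty, oversized, or rank-deficient subsets.
    """
    subset = tuple(sorted(subset))
    if not subset:
        return float("inf")
    X = train.X.iloc[:, list(subset)].to_numpy(dtype=float)
    y = train.y.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 2:
        return float("inf")
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    totals = []
    for _ in range(cfg.n_repeats):
        folds = _stratified_folds(y, cfg.k_folds, rng)
        errors = _ols_cv_errors(X, y, folds, cfg.k_folds)
        if errors is None:
            return float("inf")
        if cfg.fitness == "mae":
            totals.append(float(np.abs(errors).mean()))
        else:
            totals.append(float(np.sqrt((errors ** 2).mean())))
    return float(np.mean(totals))


def _random_mask(p: int, max_size: int, rng: np.random.Generator) -> tuple[int, ...]:
    size = int(rng.integers(1, max_size + 1))
    return tuple(sorted(rng.choice(p, size=min(size, p), replace=False).tolist()))


def _repair(bits: np.ndarray, max_size: int, rng: np.random.Generator) -> tuple[int, ...]:
    on = np.flatnonzero(bits)
    if on.size == 0:
        on = np.array([int(rng.integers(len(bits)))])
    if on.size > max_size:
        on = rng.choice(on, size=max_size, replace=False)
    return tuple(sorted(int(i) for i in on))


def run_ga(train: DescriptorTable, cfg: DcvConfig) -> list[Chromosome]:
    """GA subset search; returns the final population sorted by fitness.

    Deterministic under ``cfg.seed``.  Fitness evaluations are memoized by
    subset, so the cost is bounded by the number of distinct subsets
    visited.  Elitism makes the best fitness non-increasing over
    generations.
    """
    p = len(train.columns)
    ga = cfg.ga
    rng = np.random.default_rng(cfg.seed)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(mask: tuple[int, ...]) -> float:
        if mask not in cache:
            cache[mask] = evaluate_subset(mask, train, cfg)
        return cache[mask]

    if p == 1:
        only = (0,)
        return [Chromosome(only, fitness(only))]

    population = [_random_mask(p, ga.max_subset_size, rng) for _ in range(ga.population)]

    def sort_key(mask: tuple[int, ...]) -> tuple:
        return (fitness(mask), len(mask), mask)

    for _ in range(ga.generations):
        ranked = sorted(population, key=sort_key)
        next_pop = ranked[: ga.elitism]
        while len(next_pop) < ga.population:
            parents = []
            for _ in range(2):
                contenders = [population[int(rng.integers(len(population)))]
                              for _ in range(ga.tournament_size)]
                parents.append(min(contenders, key=sort_key))
            bits_a = np.zeros(p, dtype=bool)
            bits_b = np.zeros(p, dtype=bool)
            bits_a[list(parents[0])] = True
            bits_b[list(parents[1])] = True
            if rng.random() < ga.crossover_p:
                cut = int(rng.integers(1, p))
                child = np.concatenate([bits_a[:cut], bits_b[cut:]])
            else:
                child = bits_a.copy()
            flip = rng.random(p) < ga.mutation_p
            child ^= flip
            next_pop.append(_repair(child, ga.max_subset_size, rng))
        population = next_pop

    final = sorted(set(population), key=sort_key)
    return [Chromosome(mask, fitness(mask)) for mask in final]


# ---------------------------------------------------------------------------
# Selection report (external check on the untouched test set)
# ---------------------------------------------------------------------------

def dcv_report(
    candidates: list[Chromosome],
    train: DescriptorTable,
    test: DescriptorTable,
    top_m: int = 1,
) -> list[dict]:
    """Re-fit the top candidates on the full training set and report
    external metrics on the untouched test set.

    Results are never fed back into selection; ties in fitness are broken
    by subset size then column order.
    """
    names = train.columns
    ordered = sorted(candidates, key=lambda c: (c.fitness, len(c.mask), c.mask))
    reports = []
    for cand in ordered[:top_m]:
        cols = cand.columns(names)
        Xtr = train.X[cols].to_numpy(dtype=float)
        ytr = train.y.to_numpy(dtype=float)
        Xd = np.column_stack([np.ones(len(Xtr)), Xtr])
        coef, *_ = np.linalg.lstsq(Xd, ytr, rcond=None)
        yhat_tr = Xd @ coef
        Xte = test.X[cols].to_numpy(dtype=float)
        yte = test.y.to_numpy(dtype=float)
        yhat_te = np.column_stack([np.ones(len(Xte)), Xte]) @ coef
        q2f1, q2f2, rmse_te = q2_external(yte, yhat_te, float(ytr.mean()))
        reports.append({
            "descriptors": cols,
            "fitness": cand.fitness,
            "r2_train": r2(ytr, yhat_tr),
            "rmse_train": rmse(ytr, yhat_tr),
            "q2_f1": q2f1,
            "q2_f2": q2f2,
            "rmse_test": rmse_te,
            "coefficients": dict(zip(["intercept"] + cols, coef.tolist())),
        })
    return reports


def exhaustive_search(
    train: DescriptorTable, cfg: DcvConfig, subset_size: int
) -> list[Chromosome]:
    """Brute-force evaluation of every subset of a given size.

    Practical only for small pools; serves as the oracle for the GA and as
    the plain-MLR baseline mode.
    """
    from itertools import combinations

    p = len(train.columns)
    out = [
        Chromosome(mask, evaluate_subset(mask, train, cfg))
        for mask in combinations(range(p), subset_size)
    ]
    return sorted(out, key=lambda c: (c.fitness, len(c.mask), c.mask))


def save_selection_report(reports: list[dict], cfg: DcvConfig, path: str | Path) -> None:
    payload = {"config": asdict(cfg), "models": reports}
    Path(path).write_text(json.dumps(payload, indent=2))
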