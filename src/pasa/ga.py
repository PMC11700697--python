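"""Genetic-algorithm selection of feature optical wavelengths.

Individuals are wavelength-inclusion bit vectors over the 51-point grid.
Fitness is the RMSECV of a multiple linear regression of the binary class
response (cancer = 1, normal = 0) on the included APSD columns, under
seeded stratified cross-validation. Each generation culls individuals whose
RMSECV exceeds the population median, replenishes by two-point ("double")
crossover between randomly paired survivors, and mutates offspring bitwise.
Replicate runs accumulate a collection of retained models; per-wavelength
inclusion frequency across the collection highlights informative wavebands
and the globally best model defines the feature wavelengths.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .unsupervised import WavebandPartition


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters (study defaults)."""

    population_size: int = 64
    generations: int = 50
    runs: int = 100
    init_prob: float = 0.15
    mutation_rate: float = 0.005
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size % 2 or self.population_size < 4:
            raise ValueError("population size must be even and >= 4")
        if not 0.0 < self.init_prob < 1.0:
            raise ValueError("initial inclusion probability must lie in (0, 1)")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation rate must lie in [0, 1)")
        if self.cv_folds < 2:
            raise ValueError("RMSECV needs >= 2 folds")


@dataclass
class GAIndividual:
    """Wavelength-inclusion bit vector with its RMSECV fitness."""

    bits: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if not self.bits.any():
            raise ValueError("an individual must include at least one wavelength")

    def wavelengths(self, grid: np.ndarray) -> np.ndarray:
        return np.asarray(grid)[self.bits]


@dataclass
class GAModelCollection:
    """Retained best-of-run models across replicate runs."""

    grid: np.ndarray
    models: list[GAIndividual] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def best(self) -> GAIndividual:
        return min(self.models, key=lambda m: m.fitness)

    def best_wavelengths(self) -> np.ndarray:
        return np.sort(self.best.wavelengths(self.grid))

    def inclusion_frequency(self) -> np.ndarray:
        """Fraction of retained models including each wavelength."""
        return np.mean([m.bits for m in self.models], axis=0)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["rmsecv"] + [f"{w:g}" for w in self.grid])
            for m in self.models:
                writer.writerow([f"{m.fitness:.10g}"] + [int(b) for b in m.bits])

    def summary(self) -> dict:
        return {
            "n_models": self.n_models,
            "best_rmsecv": float(self.best.fitness),
            "best_wavelengths_nm": [float(w) for w in self.best_wavelengths()],
            "inclusion_frequency": {
                f"{w:g}": float(f)
                for w, f in zip(self.grid, self.inclusion_frequency())
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def _fold_assignment(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded fold labels, stratified by class for a binary response."""
    n = len(y)
    assignment = np.empty(n, dtype=int)
    classes = np.unique(y)
    if len(classes) == 2:
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            assignment[idx] = np.arange(len(idx)) % folds
    else:
        idx = rng.permutation(n)
        assignment[idx] = np.arange(n) % folds
    return assignment


def rmsecv_mlr(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    fold_labels: np.ndarray | None = None,
) -> float:
    """RMSECV of an intercept + least-squares MLR on the given columns.

    Cross-validated predictions use seeded class-stratified folds (or an
    explicit ``fold_labels`` assignment); the least-squares solve uses SVD,
    which degrades gracefully to the pseudo-inverse solution when the design
    is rank deficient.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 1:
        raise ValueError("at least one wavelength column is required")
    if fold_labels is None:
        fold_labels = _fold_assignment(y, folds, np.random.default_rng(seed))
    predictions = np.empty_like(y)
    for fold in np.unique(fold_labels):
        test = fold_labels == fold
        train = ~test
        if len(np.unique(y[train])) < 2 and X[train].std() == 0:
            raise ValueError("degenerate fold: single-class, intercept-only fit")
        design = np.column_stack([np.ones(train.sum()), X[train]])
        coef, *_ = np.linalg.lstsq(design, y[train], rcond=None)
        predictions[test] = np.column_stack([np.ones(test.sum()), X[test]]) @ coef
    return float(np.sqrt(np.mean((y - predictions) ** 2)))


def init_population(
    n_wavelengths: int, cfg: GAConfig, rng: np.random.Generator
) -> list[GAIndividual]:
    """Random inclusion bit vectors; empty individuals are re-drawn."""
    population = []
    while len(population) < cfg.population_size:
        bits = rng.random(n_wavelengths) < cfg.init_prob
        if bits.any():
            population.append(GAIndividual(bits))
    return population


def _evaluate(
    population: list[GAIndividual],
    X: np.ndarray,
    y: np.ndarray,
    fold_labels: np.ndarray,
    cache: dict[bytes, float],
) -> None:
    for ind in population:
        if ind.fitness is None:
            key = ind.bits.tobytes()
            if key not in cache:
                cache[key] = rmsecv_mlr(X[:, ind.bits], y, fold_labels=fold_labels)
            ind.fitness = cache[key]


def _two_point_crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap the gene segment between two random cut points."""
    n = len(a)
    i, j = sorted(rng.choice(n + 1, size=2, replace=False))
    child1, child2 = a.copy(), b.copy()
    child1[i:j], child2[i:j] = b[i:j], a[i:j]
    return child1, child2


def evolve_generation(
    population: list[GAIndividual],
    rng: np.random.Generator,
    cfg: GAConfig,
) -> list[GAIndividual]:
    """One selection / crossover / mutation step on an evaluated population.

    Individuals with RMSECV strictly above the median are culled; survivors
    are paired at random and bred by two-point crossover; offspring are
    mutated bitwise and the population is restored to its configured size.
    """
    if any(ind.fitness is None for ind in population):
        raise ValueError("population must be evaluated before evolution")
    fitness = np.array([ind.fitness for ind in population], dtype=float)
    median = np.median(fitness)
    survivors = [ind for ind in population if ind.fitness <= median]
    if len(survivors) < 2:
        survivors = survivors + init_population(
            len(population[0].bits), cfg, rng
        )[: 2 - len(survivors)]
    offspring: list[GAIndividual] = []
    n_bits = len(survivors[0].bits)
    while len(survivors) + len(offspring) < cfg.population_size:
        pa, pb = rng.choice(len(survivors), size=2, replace=False)
        for child_bits in _two_point_crossover(
            survivors[pa].bits, survivors[pb].bits, rng
        ):
            if cfg.mutation_rate > 0:
                flip = rng.random(n_bits) < cfg.mutation_rate
                child_bits = child_bits ^ flip
            if not child_bits.any():
                child_bits = child_bits.copy()
                child_bits[rng.integers(n_bits)] = True
            if len(survivors) + len(offspring) < cfg.population_size:
                offspring.append(GAIndividual(child_bits))
    return survivors + offspring


def run_ga(
    apsd_matrix: np.ndarray,
    response: np.ndarray,
    cfg: GAConfig | None = None,
    grid: np.ndarray | None = None,
) -> GAModelCollection:
    """Replicate GA runs; retain every strict improvement over the incumbent.

    Per run, the incumbent starts at the all-wavelength model's RMSECV on
    the run's folds; each generation whose best individual strictly improves
    the incumbent contributes one retained model, so a run yields a handful
    of models and the collection grows to at least on the order of the run
    count. The globally best model defines the feature wavelengths.
    """
    cfg = cfg or GAConfig()
    X = np.asarray(apsd_matrix, dtype=float)
    y = np.asarray(response, dtype=float)
    n_bits = X.shape[1]
    wl = np.arange(n_bits, dtype=float) if grid is None else np.asarray(grid, float)
    collection = GAModelCollection(wl)
    run_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.runs)
    for run_seq in run_seeds:
        rng = np.random.default_rng(run_seq)
        fold_labels = _fold_assignment(y, cfg.cv_folds, rng)
        cache: dict[bytes, float] = {}
        incumbent = rmsecv_mlr(X, y, fold_labels=fold_labels)
        population = init_population(n_bits, cfg, rng)
        _evaluate(population, X, y, fold_labels, cache)
        for _ in range(cfg.generations):
            population = evolve_generation(population, rng, cfg)
            _evaluate(population, X, y, fold_labels, cache)
            best = min(population, key=lambda ind: ind.fitness)
            if best.fitness < incumbent:
                incumbent = best.fitness
                collection.models.append(GAIndividual(best.bits.copy(), best.fitness))
    if not collection.models:
        raise RuntimeError("no GA run improved on the full-wavelength baseline")
    return collection


def waveband_composition(
    wavelengths: np.ndarray, partition: WavebandPartition
) -> dict[str, float]:
    """Percentage of a model's wavelengths in each chromophore's waveband(s)."""
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size == 0:
        raise ValueError("the model must include at least one wavelength")
    counts = {"collagen": 0, "water": 0, "lipid": 0}
    for w in wl:
        counts[partition.chromophore_of(w)] += 1
    return {name: 100.0 * c / wl.size for name, c in counts.items()}
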