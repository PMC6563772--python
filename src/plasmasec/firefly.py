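"""Wrapper feature selection by the discrete firefly algorithm, with comparators.

A candidate feature subset is a firefly: a real-valued latent position
``x`` in R^N and its binary mask ``s`` in {0,1}^N.  Brightness is the
fitness

    f = omega_alpha * MCC + omega_beta * (1 - n / N),

trading the cross-validated Matthews correlation coefficient of a
logistic classifier restricted to the subset against the subset size
``n``.  Each generation, every firefly is attracted towards every
brighter one:

    x_i <- x_i + beta0 * exp(-gamma * r_ij^2) * (s_j - s_i) + alpha * eps,

with ``r_ij`` the Euclidean distance between the bit masks (the square
root of the Hamming distance), ``gamma`` the light-absorption
coefficient, and ``eps`` per-dimension standard Gaussian noise.  The
latent position is discretised stochastically: bit k is set when
``sigmoid(x_k)`` exceeds an independent uniform draw.  The brightest
firefly performs a pure random walk.  The global best subset is
retained across generations (elitism), so the best-fitness trace is
non-decreasing.

Genetic-algorithm and binary-PSO comparators share the same fitness and
result contracts, and an exhaustive-search oracle enumerates every
non-empty mask for small N.

Subset fitness evaluations are memoized by mask, so repeated queries
are free and bit-identical.  All randomness in a run flows from one
seeded generator, making runs exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io_formats import LabeledDataset
from .model_eval import confusion, fit_logistic, metrics, predict_proba

__all__ = [
    "SwarmConfig",
    "ComparatorConfig",
    "FireflyState",
    "SelectionResult",
    "SubsetEvaluator",
    "light_intensity",
    "pair_distance",
    "attract_move",
    "binarize",
    "subset_fitness",
    "evaluate_subset",
    "run_dfa",
    "run_ga",
    "run_bpso",
    "exhaustive_search",
    "save_selection",
    "load_selection",
]


@dataclass
class SwarmConfig:
    """Shared optimizer settings.

    Defaults follow the published configuration: randomness
    ``alpha = 0.9``, absorption ``gamma = 0.5``, population 50, 3000
    generations, fitness weights 0.55 / 0.45.  ``beta0`` (base
    attractiveness) is the standard firefly-algorithm convention of 1.
    ``fitness_cv_folds = 0`` switches the fitness MCC from internal
    stratified cross-validation to training-set resubstitution.

    ``fitness_fold_seed`` fixes the internal CV fold assignment
    independently of the run seed, so every run (and the exhaustive
    oracle) optimises the exact same deterministic fitness function.
    """

    population: int = 50
    max_generations: int = 3000
    alpha: float = 0.9
    gamma: float = 0.5
    beta0: float = 1.0
    omega_alpha: float = 0.55
    omega_beta: float = 0.45
    seed: int = 0
    fitness_cv_folds: int = 5
    fitness_cv_repeats: int = 1
    fitness_fold_seed: int = 0
    stall_window: Optional[int] = None
    binarize_mode: str = "stochastic"  # or "fixed" (threshold 0.5)
    l2: float = 1.0
    fit_max_iter: int = 100

    def __post_init__(self) -> None:
        if abs(self.omega_alpha + self.omega_beta - 1.0) > 1e-9:
            raise ValueError("omega_alpha + omega_beta must equal 1")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.alpha < 0 or self.gamma < 0 or self.beta0 <= 0:
            raise ValueError("alpha, gamma must be >= 0 and beta0 > 0")


@dataclass
class ComparatorConfig:
    """GA and binary-PSO settings (published values as defaults)."""

    ga_crossover: float = 0.6
    ga_mutation: float = 0.033
    pso_c1: float = 1.0
    pso_c2: float = 2.0
    pso_inertia: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.ga_crossover <= 1 and 0 <= self.ga_mutation <= 1):
            raise ValueError("GA probabilities must lie in [0, 1]")


@dataclass
class FireflyState:
    latent: np.ndarray
    mask: np.ndarray
    mcc: float = 0.0
    fitness: float = 0.0
    intensity_source: float = 0.0

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass
class SelectionResult:
    best_mask: np.ndarray
    best_fitness: float
    best_mcc: float
    trace: list[float]
    evaluations: int
    seed: int
    method: str = ""

    def __post_init__(self) -> None:
        self.best_mask = np.asarray(self.best_mask, dtype=bool)


# ---------------------------------------------------------------------------
# Primitive moves
# ---------------------------------------------------------------------------

def light_intensity(i0: float, gamma: float, r: float) -> float:
    """Light intensity at distance r: ``I0 * exp(-gamma * r^2)``."""
    if gamma < 0 or r < 0:
        raise ValueError("gamma and r must be non-negative")
    return i0 * np.exp(-gamma * r * r)


def pair_distance(mask_i: np.ndarray, mask_j: np.ndarray) -> float:
    """Euclidean distance between bit masks = sqrt(Hamming distance)."""
    mask_i = np.asarray(mask_i)
    mask_j = np.asarray(mask_j)
    if mask_i.shape != mask_j.shape:
        raise ValueError("mask length mismatch")
    return float(np.sqrt(np.sum(mask_i.astype(int) != mask_j.astype(int))))


def attract_move(
    latent_i: np.ndarray,
    mask_i: np.ndarray,
    mask_j: np.ndarray,
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move firefly i towards the brighter firefly j in latent space."""
    r2 = float(np.sum(mask_i.astype(int) != mask_j.astype(int)))
    attraction = cfg.beta0 * np.exp(-cfg.gamma * r2) * (
        mask_j.astype(float) - mask_i.astype(float)
    )
    noise = cfg.alpha * rng.standard_normal(latent_i.shape[0]) if cfg.alpha > 0 else 0.0
    return latent_i + attraction + noise


def binarize(latent: np.ndarray, rng: np.random.Generator,
             mode: str = "stochastic") -> np.ndarray:
    """Discretise a latent position into a non-empty bit mask.

    Stochastic mode sets bit k when ``sigmoid(latent_k)`` exceeds an
    independent Uniform(0,1) draw; fixed mode thresholds at 0.5.  An
    all-zero outcome is repaired by setting one uniformly chosen bit
    (the sparsity term would otherwise make the degenerate empty subset
    a strong attractor with undefined MCC).
    """
    p = 1.0 / (1.0 + np.exp(-latent))
    if mode == "stochastic":
        bits = p > rng.random(latent.shape[0])
    elif mode == "fixed":
        bits = p > 0.5
    else:
        raise ValueError(f"unknown binarize mode {mode!r}")
    if not bits.any():
        bits = bits.copy()
        bits[rng.integers(0, latent.shape[0])] = True
    return bits


def subset_fitness(mcc: float, n: int, N: int, cfg: SwarmConfig) -> float:
    """``omega_alpha * MCC + omega_beta * (1 - n/N)``."""
    if not 0 <= n <= N or N <= 0:
        raise ValueError("need 0 <= n <= N and N > 0")
    return cfg.omega_alpha * mcc + cfg.omega_beta * (1.0 - n / N)


# ---------------------------------------------------------------------------
# Memoized subset evaluation
# ---------------------------------------------------------------------------

class SubsetEvaluator:
    """Cross-validated logistic MCC of feature subsets, memoized by mask.

    Fold assignment and per-fold standardization are fixed at
    construction, so identical masks always return bit-identical values
    regardless of query order.  Standardization parameters are fitted
    on training folds only.
    """

    def __init__(self, dataset: LabeledDataset, cfg: SwarmConfig,
                 fold_seed: Optional[int] = None) -> None:
        if dataset.y is None:
            raise ValueError("dataset must be labelled")
        if len(set(dataset.y.tolist())) < 2:
            raise ValueError("dataset must contain both classes")
        self.cfg = cfg
        self.N = dataset.d
        if fold_seed is None:
            fold_seed = cfg.fitness_fold_seed
        y = dataset.y
        self._splits: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        index_pairs: list[tuple[np.ndarray, np.ndarray]] = []
        if cfg.fitness_cv_folds >= 2:
            # averaging over independent partitions damps the noise a
            # wrapper search could otherwise overfit
            for rep in range(max(1, cfg.fitness_cv_repeats)):
                skf = StratifiedKFold(n_splits=cfg.fitness_cv_folds, shuffle=True,
                                      random_state=(fold_seed + rep) % (2**32))
                index_pairs.extend(skf.split(dataset.X, y))
        else:  # resubstitution
            all_idx = np.arange(dataset.n)
            index_pairs = [(all_idx, all_idx)]
        for train_idx, test_idx in index_pairs:
            Xtr = dataset.X[train_idx]
            center = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            scale = np.where(sd > 0, sd, 1.0)
            self._splits.append(
                (
                    (Xtr - center) / scale,
                    y[train_idx],
                    (dataset.X[test_idx] - center) / scale,
                    y[test_idx],
                )
            )
        self._cache: dict[bytes, float] = {}
        self.evaluations = 0

    def evaluate(self, mask: np.ndarray) -> float:
        """Mean held-out-fold MCC of the logistic model on the subset."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return 0.0
        key = np.packbits(mask).tobytes()
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        self.evaluations += 1
        mccs = []
        for Xtr, ytr, Xte, yte in self._splits:
            model = fit_logistic(Xtr[:, mask], ytr, l2=self.cfg.l2,
                                 tol=1e-4, max_iter=self.cfg.fit_max_iter)
            probs = predict_proba(model, Xte[:, mask])
            mccs.append(metrics(confusion(yte, probs)).mcc)
        value = float(np.mean(mccs))
        self._cache[key] = value
        return value

    def fitness(self, mask: np.ndarray) -> tuple[float, float]:
        mcc = self.evaluate(mask)
        return subset_fitness(mcc, int(np.asarray(mask).sum()), self.N, self.cfg), mcc


def evaluate_subset(mask: np.ndarray, dataset: LabeledDataset, cfg: SwarmConfig,
                    evaluator: Optional[SubsetEvaluator] = None) -> float:
    """Convenience wrapper; pass an evaluator to benefit from memoization."""
    if evaluator is None:
        evaluator = SubsetEvaluator(dataset, cfg)
    return evaluator.evaluate(mask)


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

def _init_population(pop: int, N: int, rng: np.random.Generator) -> np.ndarray:
    masks = rng.integers(0, 2, size=(pop, N)).astype(bool)
    for i in range(pop):  # empty-mask repair
        if not masks[i].any():
            masks[i, rng.integers(0, N)] = True
    return masks





class _BestTracker:
    def __init__(self) -> None:
        self.fitness = -np.inf
        self.mcc = 0.0
        self.mask: Optional[np.ndarray] = None

    def update(self, fitness: float, mcc: float, mask: np.ndarray) -> None:
        if fitness > self.fitness:
            self.fitness = fitness
            self.mcc = mcc
            self.mask = mask.copy()


def run_dfa(dataset: LabeledDataset, cfg: SwarmConfig,
            evaluator: Optional[SubsetEvaluator] = None) -> SelectionResult:
    """Discrete firefly feature selection."""
    rng = np.random.default_rng(cfg.seed)
    if evaluator is None:
        evaluator = SubsetEvaluator(dataset, cfg)
    evals_before = evaluator.evaluations
    N = dataset.d
    masks = _init_population(cfg.population, N, rng)
    states = []
    best = _BestTracker()
    for i in range(cfg.population):
        fit, mcc = evaluator.fitness(masks[i])
        st = FireflyState(latent=(2.0 * masks[i] - 1.0), mask=masks[i].copy(),
                          mcc=mcc, fitness=fit, intensity_source=fit)
        states.append(st)
        best.update(fit, mcc, masks[i])

    trace: list[float] = []
    stall = 0
    for _gen in range(cfg.max_generations):
        prev_best = best.fitness
        for i, si in enumerate(states):
            moved = False
            for sj in states:
                if sj.fitness > si.fitness:
                    si.latent = attract_move(si.latent, si.mask, sj.mask, cfg, rng)
                    si.mask = binarize(si.latent, rng, cfg.binarize_mode)
                    si.fitness, si.mcc = evaluator.fitness(si.mask)
                    si.intensity_source = si.fitness
                    best.update(si.fitness, si.mcc, si.mask)
                    moved = True
            if not moved:
                # Brightest firefly: pure random walk.
                si.latent = si.latent + cfg.alpha * rng.standard_normal(N)
                si.mask = binarize(si.latent, rng, cfg.binarize_mode)
                si.fitness, si.mcc = evaluator.fitness(si.mask)
                si.intensity_source = si.fitness
                best.update(si.fitness, si.mcc, si.mask)
        trace.append(best.fitness)
        stall = stall + 1 if best.fitness <= prev_best else 0
        if cfg.stall_window is not None and stall >= cfg.stall_window:
            break
    if not trace:
        trace = [best.fitness]
    return SelectionResult(best.mask, best.fitness, best.mcc, trace,
                           evaluator.evaluations - evals_before, cfg.seed, method="dfa")


def run_ga(dataset: LabeledDataset, cfg: SwarmConfig,
           comparator: Optional[ComparatorConfig] = None,
           evaluator: Optional[SubsetEvaluator] = None) -> SelectionResult:
    """Genetic-algorithm comparator: tournament(2) selection, uniform
    crossover, per-bit mutation, elitism of one."""
    comp = comparator or ComparatorConfig()
    rng = np.random.default_rng(cfg.seed)
    if evaluator is None:
        evaluator = SubsetEvaluator(dataset, cfg)
    evals_before = evaluator.evaluations
    N = dataset.d
    pop = _init_population(cfg.population, N, rng)
    fits = np.empty(cfg.population)
    best = _BestTracker()
    for i in range(cfg.population):
        fits[i], mcc = evaluator.fitness(pop[i])
        best.update(fits[i], mcc, pop[i])

    trace: list[float] = []
    stall = 0
    for _gen in range(cfg.max_generations):
        prev_best = best.fitness
        new_pop = [best.mask.copy()]  # elitism
        while len(new_pop) < cfg.population:
            # Tournament selection of two parents.
            parents = []
            for _ in range(2):
                a, b = rng.integers(0, cfg.population, size=2)
                parents.append(pop[a] if fits[a] >= fits[b] else pop[b])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < comp.ga_crossover:
                swap = rng.random(N) < 0.5
                c1[swap], c2[swap] = parents[1][swap], parents[0][swap]
            for child in (c1, c2):
                flip = rng.random(N) < comp.ga_mutation
                child[flip] = ~child[flip]
                if not child.any():
                    child[rng.integers(0, N)] = True
                if len(new_pop) < cfg.population:
                    new_pop.append(child)
        pop = np.array(new_pop)
        for i in range(cfg.population):
            fits[i], mcc = evaluator.fitness(pop[i])
            best.update(fits[i], mcc, pop[i])
        trace.append(best.fitness)
        stall = stall + 1 if best.fitness <= prev_best else 0
        if cfg.stall_window is not None and stall >= cfg.stall_window:
            break
    if not trace:
        trace = [best.fitness]
    return SelectionResult(best.mask, best.fitness, best.mcc, trace,
                           evaluator.evaluations - evals_before, cfg.seed, method="ga")


def run_bpso(dataset: LabeledDataset, cfg: SwarmConfig,
             comparator: Optional[ComparatorConfig] = None,
             evaluator: Optional[SubsetEvaluator] = None) -> SelectionResult:
    """Binary particle-swarm comparator with sigmoid-stochastic discretisation."""
    comp = comparator or ComparatorConfig()
    rng = np.random.default_rng(cfg.seed)
    if evaluator is None:
        evaluator = SubsetEvaluator(dataset, cfg)
    evals_before = evaluator.evaluations
    N = dataset.d
    pos = _init_population(cfg.population, N, rng)
    vel = np.zeros((cfg.population, N))
    fits = np.empty(cfg.population)
    pbest = pos.copy()
    pbest_fit = np.empty(cfg.population)
    best = _BestTracker()
    for i in range(cfg.population):
        fits[i], mcc = evaluator.fitness(pos[i])
        pbest_fit[i] = fits[i]
        best.update(fits[i], mcc, pos[i])

    trace: list[float] = []
    stall = 0
    for _gen in range(cfg.max_generations):
        prev_best = best.fitness
        for i in range(cfg.population):
            r1, r2 = rng.random(N), rng.random(N)
            vel[i] = (
                comp.pso_inertia * vel[i]
                + comp.pso_c1 * r1 * (pbest[i].astype(float) - pos[i].astype(float))
                + comp.pso_c2 * r2 * (best.mask.astype(float) - pos[i].astype(float))
            )
            pos[i] = binarize(vel[i], rng, cfg.binarize_mode)
            fits[i], mcc = evaluator.fitness(pos[i])
            if fits[i] > pbest_fit[i]:
                pbest_fit[i] = fits[i]
                pbest[i] = pos[i].copy()
            best.update(fits[i], mcc, pos[i])
        trace.append(best.fitness)
        stall = stall + 1 if best.fitness <= prev_best else 0
        if cfg.stall_window is not None and stall >= cfg.stall_window:
            break
    if not trace:
        trace = [best.fitness]
    return SelectionResult(best.mask, best.fitness, best.mcc, trace,
                           evaluator.evaluations - evals_before, cfg.seed, method="bpso")


def exhaustive_search(dataset: LabeledDataset, cfg: Optional[SwarmConfig] = None,
                      max_N: int = 20,
                      evaluator: Optional[SubsetEvaluator] = None) -> SelectionResult:
    """Enumerate every non-empty mask (test oracle; N <= ``max_N``).

    Ties on fitness are broken by fewer selected features, then by the
    lexicographically smallest mask.
    """
    cfg = cfg or SwarmConfig()
    N = dataset.d
    if N > max_N:
        raise ValueError(f"N={N} exceeds exhaustive-search limit {max_N}")
    if evaluator is None:
        evaluator = SubsetEvaluator(dataset, cfg)
    evals_before = evaluator.evaluations
    best_key = None
    best_mask = None
    best_fit = -np.inf
    best_mcc = 0.0
    for code in range(1, 2**N):
        mask = np.array([(code >> k) & 1 for k in range(N)], dtype=bool)
        fit, mcc = evaluator.fitness(mask)
        key = (-fit, int(mask.sum()), tuple(mask.astype(int)))
        if best_key is None or key < best_key:
            best_key = key
            best_mask, best_fit, best_mcc = mask, fit, mcc
    return SelectionResult(best_mask, best_fit, best_mcc, [best_fit],
                           evaluator.evaluations - evals_before, cfg.seed, method="exhaustive")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_selection(result: SelectionResult, path: str | Path,
                   config: Optional[SwarmConfig] = None,
                   trace_tsv: Optional[str | Path] = None) -> None:
    doc = {
        "method": result.method,
        "best_mask": result.best_mask.astype(int).tolist(),
        "best_fitness": result.best_fitness,
        "best_mcc": result.best_mcc,
        "n_selected": int(result.best_mask.sum()),
        "trace": result.trace,
        "evaluations": result.evaluations,
        "seed": result.seed,
    }
    if config is not None:
        doc["config"] = asdict(config)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
    if trace_tsv is not None:
        with open(trace_tsv, "w") as fh:
            fh.write("generation\tbest_fitness\n")
            for g, v in enumerate(result.trace):
                fh.write(f"{g}\t{v:.17g}\n")


def load_selection(path: str | Path) -> SelectionResult:
    with open(path) as fh:
        doc = json.load(fh)
    return SelectionResult(
        best_mask=np.array(doc["best_mask"], dtype=bool),
        best_fitness=doc["best_fitness"],
        best_mcc=doc["best_mcc"],
        trace=list(doc["trace"]),
        evaluations=doc["evaluations"],
        seed=doc["seed"],
        method=doc.get("method", ""),
    )
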