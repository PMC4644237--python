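"""Learning classifier system: evolving a population of specificity masks.

Each generation: (1) every mask in the population is used to predict, leave-
family-out, the specificity profile of every profiled domain; (2) the mask's
fitness is the median Frobenius error between predicted and observed
profiles (lower is fitter — the system evolves by minimisation); (3) the
best-performing masks ("elite") are kept unchanged and the remaining slots
are refilled by single-point cross-over of elite pairs and by per-position
mutation of elite copies.  Iteration stops when the best fitness has not
improved for ``convergence_window`` generations, or at ``max_generations``.

Because elites are carried over verbatim, the best-fitness trajectory is
non-increasing by construction.  A run is a pure function of (inputs,
config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import AlignedDomainSet, SpecificityMask, SpecificityProfile, SpecMaskError, SubstitutionMatrix
from .predictor import PredictionConfig, PredictionContext, frobenius_distance

logger = logging.getLogger(__name__)

#: best-fitness improvements smaller than this do not reset the stall counter
CONVERGENCE_EPS = 1e-9


@dataclass
class EvolutionConfig:
    population_size: int = 100
    elite_fraction: float = 0.2
    mutation_rate: float = 0.02
    crossover_rate: float = 0.5
    max_generations: int = 2500
    convergence_window: int = 250
    alpha: float = 3.0
    seed: int = 0
    n_runs: int = 10

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise SpecMaskError("population_size must be >= 2")
        if not 0.0 < self.elite_fraction <= 1.0:
            raise SpecMaskError("elite_fraction must lie in (0, 1]")
        for name in ("mutation_rate", "crossover_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecMaskError(f"{name} must lie in [0, 1]")
        if self.max_generations < 1:
            raise SpecMaskError("max_generations must be >= 1")


@dataclass
class EvolutionResult:
    """Outcome of one run: per-generation best fitness and masks."""

    best_fitness_trajectory: np.ndarray  # (generations_run,)
    final_population: list[tuple[SpecificityMask, float]]
    best_mask: SpecificityMask
    generations_run: int
    seed: int
    best_mask_trajectory: np.ndarray  # (generations_run, L)


@dataclass
class DoSScoreVector:
    """Aggregated per-column determinant-of-specificity scores in [0, 1]."""

    scores: np.ndarray
    n_runs: int
    per_run_best: np.ndarray  # (n_runs, L)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.per_run_best = np.atleast_2d(np.asarray(self.per_run_best, dtype=float))
        lo = self.per_run_best.min(axis=0) - 1e-12
        hi = self.per_run_best.max(axis=0) + 1e-12
        if np.any(self.scores < lo) or np.any(self.scores > hi):
            raise SpecMaskError("aggregate scores outside per-run range")


def models_explored(population_size: int, generations: int, n_runs: int = 1) -> int:
    """Number of candidate mask models evaluated: masks/generation x
    generations x independent runs."""
    if population_size < 1 or generations < 1 or n_runs < 1:
        raise SpecMaskError("counts must be >= 1")
    return population_size * generations * n_runs


def mask_fitness(
    mask: SpecificityMask,
    aln: AlignedDomainSet,
    profiles: dict[str, SpecificityProfile],
    cfg: PredictionConfig,
    sm: SubstitutionMatrix,
    context: PredictionContext | None = None,
) -> float:
    """Median leave-family-out prediction error over all profiled domains.

    Queries without any eligible donor are skipped (warned once, at context
    construction); if no query is predictable the context raises.
    """
    ctx = context or PredictionContext(aln, profiles, cfg, sm)
    d = ctx.distances(np.asarray(mask.scores, dtype=float))
    return float(np.nanmedian(d))


def init_population(
    L: int, cfg: EvolutionConfig, rng: np.random.Generator | None = None
) -> list[SpecificityMask]:
    """population_size masks with i.i.d. uniform [0, 1] entries."""
    if L < 1:
        raise SpecMaskError("L must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return [SpecificityMask(rng.random(L)) for _ in range(cfg.population_size)]


def _elite_indices(fitnesses: np.ndarray, n_elite: int) -> np.ndarray:
    # stable sort: fitness ties broken by earlier population index
    return np.argsort(fitnesses, kind="stable")[:n_elite]


def next_generation(
    pop: list[SpecificityMask],
    fitnesses: list[float],
    cfg: EvolutionConfig,
    rng: np.random.Generator,
) -> list[SpecificityMask]:
    """Elite copy + single-point cross-over + per-position mutation.

    The ``ceil(elite_fraction * n)`` fittest masks survive unchanged; of the
    remaining slots, a ``crossover_rate`` share is filled by single-point
    cross-over of two distinct elite parents and the rest by elite copies in
    which each position is independently resampled uniform [0, 1] with
    probability ``mutation_rate``.
    """
    n = cfg.population_size
    if len(pop) != n or len(fitnesses) != n:
        raise SpecMaskError("population/fitness size mismatch with config")
    fit = np.asarray(fitnesses, dtype=float)
    n_elite = math.ceil(cfg.elite_fraction * n)
    elite_idx = _elite_indices(fit, n_elite)
    elite = [pop[i].scores for i in elite_idx]
    new: list[SpecificityMask] = [SpecificityMask(e.copy()) for e in elite]
    n_off = n - n_elite
    n_cross = round(cfg.crossover_rate * n_off) if n_elite >= 2 else 0
    L = elite[0].size
    for _ in range(n_cross):
        pa, pb = rng.choice(n_elite, size=2, replace=False)
        cut = int(rng.integers(1, L)) if L > 1 else 1
        child = np.concatenate([elite[pa][:cut], elite[pb][cut:]])
        new.append(SpecificityMask(child))
    for _ in range(n_off - n_cross):
        parent = elite[int(rng.integers(n_elite))].copy()
        hits = rng.random(L) < cfg.mutation_rate
        if hits.any():
            parent[hits] = rng.random(int(hits.sum()))
        new.append(SpecificityMask(parent))
    return new


def evolve(
    aln: AlignedDomainSet,
    profiles: dict[str, SpecificityProfile],
    cfg: EvolutionConfig,
    pcfg: PredictionConfig | None = None,
    sm: SubstitutionMatrix | None = None,
) -> EvolutionResult:
    """Run the mask-evolution loop to convergence (or the generation budget)."""
    sm = sm or SubstitutionMatrix.blosum62()
    pcfg = pcfg or PredictionConfig(alpha=cfg.alpha)
    ctx = PredictionContext(aln, profiles, pcfg, sm)
    rng = np.random.default_rng(cfg.seed)
    pop = init_population(aln.L, cfg, rng)
    cache: dict[bytes, float] = {}

    def fitness_of(mask: SpecificityMask) -> float:
        key = mask.scores.tobytes()
        val = cache.get(key)
        if val is None:
            val = float(np.nanmedian(ctx.distances(mask.scores)))
            cache[key] = val
        return val

    best_traj: list[float] = []
    best_masks: list[np.ndarray] = []
    best_so_far = np.inf
    stall = 0
    gen = 0
    while gen < cfg.max_generations:
        fits = [fitness_of(m) for m in pop]
        order = _elite_indices(np.asarray(fits), 1)
        b = int(order[0])
        best_traj.append(fits[b])
        best_masks.append(pop[b].scores.copy())
        if best_so_far - fits[b] > CONVERGENCE_EPS:
            best_so_far = fits[b]
            stall = 0
        else:
            stall += 1
        gen += 1
        if gen % 100 == 0:
            logger.info("generation %d best fitness %.6f", gen, fits[b])
        if stall >= cfg.convergence_window or gen >= cfg.max_generations:
            break
        pop = next_generation(pop, fits, cfg, rng)

    final = [(m, fitness_of(m)) for m in pop]
    best_mask = SpecificityMask(best_masks[-1].copy())
    return EvolutionResult(
        best_fitness_trajectory=np.array(best_traj),
        final_population=final,
        best_mask=best_mask,
        generations_run=gen,
        seed=cfg.seed,
        best_mask_trajectory=np.vstack(best_masks),
    )


def evolve_replicates(
    aln: AlignedDomainSet,
    profiles: dict[str, SpecificityProfile],
    cfg: EvolutionConfig,
    pcfg: PredictionConfig | None = None,
    sm: SubstitutionMatrix | None = None,
    n_runs: int | None = None,
) -> list[EvolutionResult]:
    """Independent runs with seeds cfg.seed, cfg.seed+1, ... (a thin wrapper)."""
    from dataclasses import replace

    runs = n_runs if n_runs is not None else cfg.n_runs
    return [
        evolve(aln, profiles, replace(cfg, seed=cfg.seed + i), pcfg, sm)
        for i in range(runs)
    ]


def select_alpha(
    aln: AlignedDomainSet,
    profiles: dict[str, SpecificityProfile],
    alphas: list[float],
    cfg: EvolutionConfig,
    sm: SubstitutionMatrix | None = None,
) -> tuple[float, dict[float, float]]:
    """Short-budget evolution per alpha; returns the alpha with the lowest
    converged fitness (ties go to the smallest alpha)."""
    if not alphas:
        raise SpecMaskError("alphas must be non-empty")
    sm = sm or SubstitutionMatrix.blosum62()
    curve: dict[float, float] = {}
    for a in sorted(alphas):
        pcfg = PredictionConfig(alpha=a)
        res = evolve(aln, profiles, cfg, pcfg, sm)
        curve[a] = float(res.best_fitness_trajectory[-1])
    best = min(curve, key=lambda a: (curve[a], a))
    return best, curve


def aggregate_runs(
    results: list[EvolutionResult],
) -> tuple[DoSScoreVector, np.ndarray]:
    """Aggregate independent runs into per-column DoS scores plus an
    inter-run dissimilarity trajectory.

    Scores are the per-column mean of the runs' final best masks.  The
    trajectory is, per generation, the mean pairwise Frobenius distance
    between the runs' best masks (runs of unequal length are compared up to
    the shortest run).
    """
    if not results:
        raise SpecMaskError("no results to aggregate")
    L = results[0].best_mask.scores.size
    for r in results:
        if r.best_mask.scores.size != L:
            raise SpecMaskError("mixed mask lengths across runs")
    per_run = np.vstack([r.best_mask.scores for r in results])
    scores = per_run.mean(axis=0)
    n = len(results)
    g_min = min(r.generations_run for r in results)
    dissim = np.zeros(g_min)
    if n > 1:
        trajs = [r.best_mask_trajectory[:g_min] for r in results]
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        for g in range(g_min):
            dissim[g] = float(
                np.mean(
                    [frobenius_distance(trajs[i][g], trajs[j][g]) for i, j in pairs]
                )
            )
    vec = DoSScoreVector(scores=scores, n_runs=n, per_run_best=per_run)
    return vec, dissim
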