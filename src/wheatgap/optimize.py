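"""Self-adaptive evolutionary search over the seven wheat traits.

The optimizer is a multi-start (1+lambda) evolution strategy with log-normal
step-size self-adaptation: each parent produces 16 mutant candidates per
generation; candidates failing the yield-stability filter (CV of yield above
10%) or the harvest-index ceiling (mean HI above 0.64) are removed from the
selection pool; the best surviving candidate replaces the parent only if it
improves mean yield.  Every candidate is evaluated on the same fixed weather
series (common random numbers), so selection noise comes only from mutation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .crop import (
    TRAIT_NAMES,
    CultivarParams,
    Management,
    ModelConfig,
    DEFAULT_CONFIG,
    SoilProfile,
    YieldStats,
    simulate_multi_year,
)
from .weather import WeatherSeries

__all__ = [
    "TraitRanges",
    "Candidate",
    "Evaluation",
    "OptimizationResult",
    "OptimizationError",
    "DEFAULT_TRAIT_RANGES",
    "sample_initial_parents",
    "mutate",
    "constraint_filter",
    "easa_generation",
    "easa_search",
    "optimize_ideotype",
]

logger = logging.getLogger(__name__)

#: CV-of-yield stability ceiling, percent
CV_LIMIT = 10.0
#: harvest-index biological ceiling
HI_LIMIT = 0.64
#: mean-yield improvement (t ha-1) that counts as progress for convergence
IMPROVEMENT_EPS = 1e-3
#: log-normal step-size learning rate for 7 traits
TAU = 1.0 / math.sqrt(2.0 * len(TRAIT_NAMES))


class OptimizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TraitRanges:
    """Per-trait lower/upper bounds, canonical trait order (see TRAIT_NAMES)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != (len(TRAIT_NAMES),) or hi.shape != (len(TRAIT_NAMES),):
            raise ValueError(f"bounds must have {len(TRAIT_NAMES)} values")
        if np.any(lo >= hi):
            bad = [TRAIT_NAMES[i] for i in np.nonzero(lo >= hi)[0]]
            raise ValueError(f"lower bound must be < upper bound for {bad}")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[float]]) -> "TraitRanges":
        unknown = set(d) - set(TRAIT_NAMES)
        if unknown:
            raise ValueError(
                f"unknown trait names {sorted(unknown)}; legal traits are "
                f"{list(TRAIT_NAMES)}"
            )
        missing = set(TRAIT_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing trait ranges for {sorted(missing)}")
        lo = np.array([d[t][0] for t in TRAIT_NAMES], dtype=float)
        hi = np.array([d[t][1] for t in TRAIT_NAMES], dtype=float)
        return cls(lower=lo, upper=hi)

    def to_dict(self) -> dict[str, list[float]]:
        return {
            t: [float(self.lower[i]), float(self.upper[i])]
            for i, t in enumerate(TRAIT_NAMES)
        }

    def contains(self, genome: np.ndarray) -> bool:
        g = np.asarray(genome, dtype=float)
        return bool(np.all(g >= self.lower) and np.all(g <= self.upper))

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


#: Default trait bounds: the span of genetic variation the search may use.
#: A stand-in calibration expressing plausible wheat germplasm variation.
DEFAULT_TRAIT_RANGES = TraitRanges.from_dict(
    {
        "a_max": [1.75, 7.0],   # flag-leaf LAI contribution
        "s_g": [0.0, 2.0],      # stay-green factor
        "p_h": [70.0, 140.0],   # phyllochron, degC d
        "p_p": [0.0, 1.0],      # photoperiod sensitivity
        "g_f": [400.0, 900.0],  # grain-fill duration, degC d
        "r_u": [0.02, 0.12],    # extractable soil-water fraction, day-1
        "w_ss": [1.0, 4.0],     # max senescence acceleration
    }
)


@dataclass
class Candidate:
    """A point in trait space with its self-adaptive mutation scales."""

    genome: np.ndarray
    step_sizes: np.ndarray
    stats: YieldStats | None = None
    feasible: bool | None = None
    fitness: float = -math.inf

    def copy(self) -> "Candidate":
        return Candidate(
            genome=self.genome.copy(),
            step_sizes=self.step_sizes.copy(),
            stats=self.stats,
            feasible=self.feasible,
            fitness=self.fitness,
        )


@dataclass(frozen=True)
class Evaluation:
    """Result of evaluating one genome: fitness (mean yield, t ha-1),
    feasibility under the CV/HI filters, and the underlying stats."""

    fitness: float
    feasible: bool
    stats: YieldStats | None = None


EvaluateFn = Callable[[np.ndarray], Evaluation]


@dataclass
class OptimizationResult:
    best: Candidate
    trace: pd.DataFrame
    n_starts: int
    converged: list[bool]
    accepted: list[YieldStats] = field(default_factory=list)


# ---------------------------------------------------------------------------

def sample_initial_parents(ranges: TraitRanges, n: int, cultivar: CultivarParams,
                           rng: np.random.Generator | int) -> list[Candidate]:
    """One parent at the cultivar's own trait values plus n-1 uniform draws.

    Initial step sizes are 10% of each trait's range width.
    """
    if n < 1:
        raise ValueError("need at least one initial parent")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    traits = cultivar.traits
    if not ranges.contains(traits):
        raise ValueError(
            "cultivar trait values fall outside the search ranges; the local "
            "cultivar must be representable in the parameter space"
        )
    steps = 0.1 * ranges.width
    parents = [Candidate(genome=traits.copy(), step_sizes=steps.copy())]
    for _ in range(n - 1):
        g = rng.uniform(ranges.lower, ranges.upper)
        parents.append(Candidate(genome=g, step_sizes=steps.copy()))
    return parents


def _reflect(values: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Fold values back into [lower, upper] by reflection at the bounds."""
    width = upper - lower
    shifted = np.mod(values - lower, 2.0 * width)
    folded = np.where(shifted > width, 2.0 * width - shifted, shifted)
    return lower + folded


def mutate(parent: Candidate, ranges: TraitRanges,
           rng: np.random.Generator) -> Candidate:
    """Self-adaptive Gaussian mutation with log-normal step-size control.

    Each step size is multiplied by exp(tau * N(0,1)); each trait is then
    perturbed by its own Gaussian with the new step size and reflected back
    into bounds.
    """
    if not ranges.contains(parent.genome):
        raise ValueError("parent genome outside trait ranges")
    k = len(TRAIT_NAMES)
    new_steps = parent.step_sizes * np.exp(TAU * rng.standard_normal(k))
    genome = parent.genome + new_steps * rng.standard_normal(k)
    genome = _reflect(genome, ranges.lower, ranges.upper)
    return Candidate(genome=genome, step_sizes=new_steps)


def constraint_filter(stats: YieldStats) -> bool:
    """Feasible iff yield CV <= 10% and mean harvest index <= 0.64."""
    return stats.cv <= CV_LIMIT and stats.mean_hi <= HI_LIMIT


def _evaluate_candidate(cand: Candidate, evaluate: EvaluateFn) -> None:
    try:
        ev = evaluate(cand.genome)
    except Exception:
        logger.exception("candidate evaluation failed; treating as infeasible")
        cand.fitness = -math.inf
        cand.feasible = False
        cand.stats = None
        return
    cand.fitness = ev.fitness
    cand.feasible = ev.feasible
    cand.stats = ev.stats


def easa_generation(parent: Candidate, evaluate: EvaluateFn, ranges: TraitRanges,
                    rng: np.random.Generator, n_candidates: int = 16,
                    accepted_pool: list[YieldStats] | None = None) -> Candidate:
    """One generation: mutate, evaluate, filter, select.

    Returns the feasible candidate with the highest mean yield if it strictly
    beats the parent, otherwise the parent (ties go to the parent).  An
    infeasible parent is always displaced by any feasible candidate.
    """
    if parent.feasible is None:
        _evaluate_candidate(parent, evaluate)
    best = parent
    parent_ref = -math.inf if not parent.feasible else parent.fitness
    for _ in range(n_candidates):
        cand = mutate(parent, ranges, rng)
        _evaluate_candidate(cand, evaluate)
        if not cand.feasible:
            continue
        if accepted_pool is not None and cand.stats is not None:
            accepted_pool.append(cand.stats)
        ref = parent_ref if best is parent else best.fitness
        if cand.fitness > ref:
            best = cand
    return best


def easa_search(evaluate: EvaluateFn, ranges: TraitRanges,
                initial_parents: Sequence[Candidate],
                seed: int | np.random.SeedSequence,
                n_candidates: int = 16, patience: int = 20,
                max_gen: int = 200) -> OptimizationResult:
    """Run the multi-start (1+n_candidates) evolution strategy.

    Each start iterates until ``patience`` generations pass without a mean
    yield improvement above 1e-3 t ha-1, or ``max_gen`` is reached.  The best
    final parent across starts is returned together with the full trace.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    start_seeds = ss.spawn(len(initial_parents))

    trace_rows = []
    accepted: list[YieldStats] = []
    finals: list[Candidate] = []
    converged: list[bool] = []
    infeasible_cv = 0
    infeasible_hi = 0

    def note_infeasible(stats: YieldStats | None) -> None:
        nonlocal infeasible_cv, infeasible_hi
        if stats is None:
            return
        if stats.cv > CV_LIMIT:
            infeasible_cv += 1
        if stats.mean_hi > HI_LIMIT:
            infeasible_hi += 1

    for s, (parent0, child_ss) in enumerate(zip(initial_parents, start_seeds)):
        rng = np.random.default_rng(child_ss)
        parent = parent0.copy()
        _evaluate_candidate(parent, evaluate)
        if parent.feasible and parent.stats is not None:
            accepted.append(parent.stats)
        else:
            note_infeasible(parent.stats)

        no_improve = 0
        gen = 0
        while gen < max_gen:
            gen += 1
            prev_fitness = parent.fitness if parent.feasible else -math.inf
            pool: list[YieldStats] = []
            parent = easa_generation(
                parent, evaluate, ranges, rng, n_candidates, accepted_pool=pool
            )
            accepted.extend(pool)
            trace_rows.append(
                dict(
                    start=s, generation=gen,
                    mean_yield=parent.fitness,
                    cv=parent.stats.cv if parent.stats else math.nan,
                    hi=parent.stats.mean_hi if parent.stats else math.nan,
                    feasible=bool(parent.feasible),
                    **{t: float(parent.genome[i]) for i, t in enumerate(TRAIT_NAMES)},
                )
            )
            if parent.fitness > prev_fitness + IMPROVEMENT_EPS:
                no_improve = 0
            else:
                no_improve += 1
                if no_improve >= patience:
                    break
        finals.append(parent)
        converged.append(no_improve >= patience)

    feasible_finals = [c for c in finals if c.feasible]
    if not feasible_finals:
        binding = ("yield CV > 10%" if infeasible_cv >= infeasible_hi
                   else "mean HI > 0.64")
        raise OptimizationError(
            "no feasible candidate found in any start; most frequently "
            f"binding constraint: {binding} "
            f"(cv violations: {infeasible_cv}, hi violations: {infeasible_hi})"
        )
    best = max(feasible_finals, key=lambda c: c.fitness)
    return OptimizationResult(
        best=best,
        trace=pd.DataFrame(trace_rows),
        n_starts=len(initial_parents),
        converged=converged,
        accepted=accepted,
    )


def optimize_ideotype(series: WeatherSeries, soil: SoilProfile, mgmt: Management,
                      base: CultivarParams, stress_mode: str,
                      ranges: TraitRanges = DEFAULT_TRAIT_RANGES,
                      seed: int | np.random.SeedSequence = 0,
                      n_starts: int = 25, n_candidates: int = 16,
                      patience: int = 20, max_gen: int = 200,
                      config: ModelConfig = DEFAULT_CONFIG) -> OptimizationResult:
    """Design an ideotype for one site's weather.

    All candidates carry the ``stress_mode`` (iS or iT) flowering-stress
    parameter set and the ideotype +10% light-use-efficiency multiplier; the
    seven traits are searched within ``ranges``.  Fitness is mean yield over
    every complete season of ``series`` (identical weather for all candidates
    and starts).
    """
    ideotype_base = base.as_ideotype(stress_mode)

    def evaluate(genome: np.ndarray) -> Evaluation:
        cv_params = ideotype_base.with_traits(genome)
        stats = simulate_multi_year(cv_params, series, soil, mgmt, config)
        return Evaluation(
            fitness=stats.mean_yield,
            feasible=constraint_filter(stats),
            stats=stats,
        )

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    init_ss, search_ss = ss.spawn(2)
    parents = sample_initial_parents(
        ranges, n_starts, base, np.random.default_rng(init_ss)
    )
    return easa_search(
        evaluate, ranges, parents, search_ss,
        n_candidates=n_candidates, patience=patience, max_gen=max_gen,
    )
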