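"""Variable neighborhood search (VNS) and its stagnation-aware variant QSAVNS.

Both optimizers maximize a scalar objective over a box-constrained mixed
integer/continuous :class:`~stageopt.search_space.SearchSpace`.  The
population is a set of independent VNS trajectories sharing a single elite.
Each iteration every agent shakes its genotype inside its current
neighborhood ``N_k`` (radius growing with ``k``), optionally refines the
candidate with a first-improvement local search, accepts on strict
improvement (resetting ``k`` to 1) and otherwise advances to the next
neighborhood.  Cost is measured in fitness-function evaluations (FFEs): with
local search disabled the total is exactly ``N * (T + 1)``.

QSAVNS adds two mechanisms:

* quasi-reflexive initialization — half the initial population is drawn
  uniformly, the other half is mirrored between each uniform draw and the
  box midpoint, widening early coverage;
* stagnation-aware elitist rollback — a counter ``s_count`` increments on
  every iteration without strict improvement of the global best and, on
  reaching ``s_tresh = ceil(T/3)``, all agents except the elite are
  regenerated by the initialization scheme and the counter resets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .search_space import SearchSpace, repair, sample_uniform

__all__ = [
    "Agent",
    "OptimizerConfig",
    "OptimizationResult",
    "qrl_reflect",
    "initialize_population",
    "shake",
    "local_search",
    "run_vns",
    "run_qsavns",
    "OPTIMIZERS",
]

Objective = Callable[[np.ndarray], float]


@dataclass
class Agent:
    """One candidate solution: genotype, fitness (None until evaluated), and
    its current neighborhood index."""

    genotype: np.ndarray
    fitness: Optional[float] = None
    k: int = 1


@dataclass
class OptimizerConfig:
    """Run-time knobs shared by VNS and QSAVNS.

    ``s_tresh`` defaults to ceil(T/3) so a rollback can never fire before a
    third of the run has elapsed.  ``local_search_tries = 0`` keeps the FFE
    budget at exactly N*(T+1).
    """

    population_size: int = 8
    max_iter: int = 5
    k_max: int = 3
    seed: int = 0
    s_tresh: Optional[int] = None
    local_search_tries: int = 0
    shake_radius: float = 0.3

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.max_iter < 1 or self.k_max < 1:
            raise ValueError("population_size, max_iter and k_max must be >= 1")
        if self.local_search_tries < 0:
            raise ValueError("local_search_tries must be >= 0")
        if self.s_tresh is None:
            self.s_tresh = math.ceil(self.max_iter / 3)

    def ffe_cap(self) -> int:
        return self.population_size * (
            1 + self.max_iter * (1 + self.local_search_tries)
        )


@dataclass
class OptimizationResult:
    best_genotype: np.ndarray
    best_fitness: float
    history: list[float]
    ffe_count: int
    rollback_events: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "best_genotype": [float(v) for v in self.best_genotype],
            "best_fitness": float(self.best_fitness),
            "history": [float(v) for v in self.history],
            "ffe_count": int(self.ffe_count),
            "rollback_events": list(self.rollback_events),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def qrl_reflect(
    genotype: Sequence[float], space: SearchSpace, rng: np.random.Generator
) -> np.ndarray:
    """Quasi-reflexive image of a genotype.

    Per dimension j the reflected value is a uniform draw between the box
    midpoint ``m_j = (lb_j + ub_j)/2`` and the current value ``x_j`` (the
    interval is order-normalized, degenerating to the point when they
    coincide).  Integer dimensions are repaired afterward.
    """
    x = np.asarray(genotype, dtype=float)
    m = (space.lows + space.highs) / 2.0
    lo = np.minimum(m, x)
    hi = np.maximum(m, x)
    drawn = rng.uniform(lo, hi)
    return repair(drawn, space)


def initialize_population(
    space: SearchSpace,
    n: int,
    rng: np.random.Generator,
    use_qrl: bool = True,
) -> list[Agent]:
    """Build an unevaluated population.

    With QRL on, floor(n/2) agents are uniform draws and the remaining
    ceil(n/2) are quasi-reflexive images of those draws (cycled when n is
    odd).  Without QRL all n agents are uniform.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if not use_qrl:
        return [Agent(sample_uniform(space, rng)) for _ in range(n)]
    n_uniform = max(n // 2, 1) if n > 1 else 1
    base = [sample_uniform(space, rng) for _ in range(n_uniform)]
    agents = [Agent(g.copy()) for g in base]
    for i in range(n - n_uniform):
        agents.append(Agent(qrl_reflect(base[i % n_uniform], space, rng)))
    return agents


def shake(
    genotype: Sequence[float],
    k: int,
    space: SearchSpace,
    rng: np.random.Generator,
    k_max: int = 3,
    radius: float = 0.3,
) -> np.ndarray:
    """Uniform perturbation inside neighborhood ``N_k``.

    Each dimension moves by a uniform draw in +/- (k/k_max) * radius *
    (ub_j - lb_j) around the current value, then the result is repaired.
    Larger ``k`` therefore yields stochastically larger steps.
    """
    if not 1 <= k <= k_max:
        raise ValueError(f"k={k} outside 1..{k_max}")
    x = np.asarray(genotype, dtype=float)
    width = (space.highs - space.lows) * radius * (k / k_max)
    return repair(x + rng.uniform(-width, width), space)


def local_search(
    candidate: Sequence[float],
    space: SearchSpace,
    objective: Objective,
    tries: int,
    rng: np.random.Generator,
    k_max: int = 3,
    radius: float = 0.3,
    candidate_fitness: Optional[float] = None,
) -> tuple[np.ndarray, Optional[float], int]:
    """First-improvement hill climb around ``candidate``.

    Up to ``tries`` perturbations at a tenth of the k=1 shake radius; the
    first strictly better neighbor is accepted and the search stops.  Returns
    (genotype, fitness-or-None, evaluations used).  ``candidate_fitness`` may
    be supplied to avoid re-evaluating the start point; with ``tries=0`` the
    candidate is returned untouched with zero evaluations.
    """
    if tries < 0:
        raise ValueError("tries must be >= 0")
    x = np.asarray(candidate, dtype=float)
    if tries == 0:
        return x, candidate_fitness, 0
    evals = 0
    if candidate_fitness is None:
        candidate_fitness = objective(x)
        evals += 1
    for _ in range(tries):
        if evals >= tries:
            break
        y = shake(x, 1, space, rng, k_max=k_max, radius=radius * 0.1)
        fy = objective(y)
        evals += 1
        if fy > candidate_fitness:
            return y, fy, evals
    return x, candidate_fitness, evals


def _run(
    space: SearchSpace,
    objective: Objective,
    config: OptimizerConfig,
    use_qrl: bool,
    use_rollback: bool,
) -> OptimizationResult:
    rng = np.random.default_rng(config.seed)
    n, t, k_max = config.population_size, config.max_iter, config.k_max
    agents = initialize_population(space, n, rng, use_qrl=use_qrl)

    ffe = 0

    def evaluate(g: np.ndarray) -> float:
        nonlocal ffe
        ffe += 1
        try:
            return float(objective(g))
        except Exception as exc:  # surface which genotype failed
            raise RuntimeError(
                f"objective failed at genotype {np.asarray(g).tolist()}"
            ) from exc

    for a in agents:
        a.fitness = evaluate(a.genotype)

    best_idx = int(np.argmax([a.fitness for a in agents]))
    best_g = agents[best_idx].genotype.copy()
    best_f = agents[best_idx].fitness

    history: list[float] = []
    rollbacks: list[int] = []
    s_count = 0

    for it in range(1, t + 1):
        improved_global = False
        for a in agents:
            cand = shake(
                a.genotype, a.k, space, rng,
                k_max=k_max, radius=config.shake_radius,
            )
            cf = evaluate(cand)
            if config.local_search_tries > 0:
                cand, cf, _used = local_search(
                    cand, space, evaluate, config.local_search_tries, rng,
                    k_max=k_max, radius=config.shake_radius,
                    candidate_fitness=cf,
                )
            # agents regenerated by a rollback carry no fitness yet and
            # adopt the first evaluated candidate
            if a.fitness is None or cf > a.fitness:
                a.genotype, a.fitness, a.k = cand, cf, 1
            else:
                a.k = a.k % k_max + 1
            if cf > best_f:
                best_g, best_f = cand.copy(), cf
                improved_global = True
        history.append(best_f)
        if use_rollback:
            s_count = 0 if improved_global else s_count + 1
            if s_count >= config.s_tresh:
                agents = _rollback(agents, best_g, best_f, space, rng)
                rollbacks.append(it)
                s_count = 0

    return OptimizationResult(
        best_genotype=best_g,
        best_fitness=best_f,
        history=history,
        ffe_count=ffe,
        rollback_events=rollbacks,
    )


def _rollback(
    agents: list[Agent],
    best_g: np.ndarray,
    best_f: float,
    space: SearchSpace,
    rng: np.random.Generator,
) -> list[Agent]:
    """Elitist regeneration: keep the global best verbatim, redraw the rest
    through the QRL initialization scheme (unevaluated)."""
    n = len(agents)
    elite = Agent(best_g.copy(), best_f, k=1)
    if n == 1:
        return [elite]
    fresh = initialize_population(space, n - 1, rng, use_qrl=True)
    return [elite] + fresh


def rollback(
    agents: list[Agent],
    best_g: np.ndarray,
    best_f: float,
    s_count: int,
    s_tresh: int,
    space: SearchSpace,
    rng: np.random.Generator,
) -> list[Agent]:
    """Public rollback entry point; refuses to fire before the threshold."""
    if s_count < s_tresh:
        raise ValueError(f"rollback requires s_count ({s_count}) >= s_tresh ({s_tresh})")
    return _rollback(agents, best_g, best_f, space, rng)


def run_vns(
    space: SearchSpace, objective: Objective, config: OptimizerConfig
) -> OptimizationResult:
    """Baseline population VNS: uniform initialization, no rollback."""
    return _run(space, objective, config, use_qrl=False, use_rollback=False)


def run_qsavns(
    space: SearchSpace, objective: Objective, config: OptimizerConfig
) -> OptimizationResult:
    """QSAVNS: QRL initialization plus stagnation-aware elitist rollback."""
    return _run(space, objective, config, use_qrl=True, use_rollback=True)


OPTIMIZERS: dict[str, Callable[..., OptimizationResult]] = {
    "vns": run_vns,
    "qsavns": run_qsavns,
}


def register_optimizer(name: str, fn: Callable[..., OptimizationResult]) -> None:
    """Plug-in hook: register an optimizer with the run_vns signature."""
    OPTIMIZERS[name] = fn
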