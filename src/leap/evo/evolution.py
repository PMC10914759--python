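"""Island-model evolution with pairwise tournaments and toroidal migration.

Each generation, every island's population is split into random pairs; the
fitter member of each pair survives (ties favour the shorter program, then a
seeded coin). Each survivor then either copies itself with mutation or, with
the crossover probability, recombines with another survivor to produce two
offspring; parents are retained, so the population size is invariant. After
a warm-up of ``w`` generations, every ``g`` generations the top ``p`` percent
of each island emigrate (without replacement) to the next island on a
unidirectional toroid. The run lasts ``w + g*S`` generations by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .program import Program, execute, execute_effective, random_program, mutate, crossover


@dataclass
class EvolutionConfig:
    islands: int = 8                 # S
    island_size: int = 250           # n_i, must be even
    warmup: int = 50                 # w generations before migration starts
    migration_interval: int = 10     # g
    migration_percent: float = 5.0   # p, percent of an island that emigrates
    generations: int | None = None   # default w + g*S
    mutation_rate: float = 0.08      # per-instruction point-mutation prob
    crossover_prob: float = 0.5
    insert_prob: float = 0.5
    delete_prob: float = 0.25
    const_mut_prob: float = 0.3
    min_len: int = 2
    max_len: int = 48
    init_max_len: int = 24
    n_registers: int = 3
    n_consts: int = 5
    const_sd: float = 2.0
    fitness_kind: str = "balanced"   # or "raw"
    ensemble_size: int = 51
    n_restarts: int = 2    # independent runs pooled before selection
    heterogeneous_islands: bool = True
    seed: int = 0

    @property
    def total_generations(self) -> int:
        if self.generations is not None:
            return self.generations
        return self.warmup + self.migration_interval * self.islands

    def validate(self) -> "EvolutionConfig":
        if self.islands < 2:
            raise ValueError("need at least 2 islands")
        if self.island_size % 2:
            raise ValueError("island_size must be even (pairwise tournaments)")
        if not 0 < self.migration_percent < 50:
            raise ValueError("migration_percent must be in (0, 50)")
        if not 1 <= self.min_len <= self.init_max_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= init_max_len <= max_len")
        if self.fitness_kind not in ("balanced", "raw"):
            raise ValueError("fitness_kind must be 'balanced' or 'raw'")
        return self


# Operator settings cycled across islands when ``heterogeneous_islands`` is
# on: (mutation_rate, crossover_prob, n_registers). Homogeneous runs are
# sensitive to a bad draw of early building blocks; islands exploring with
# different variation intensities fail independently, and migration spreads
# whichever regime works on the data at hand.
_ISLAND_VARIANTS = [
    (0.08, 0.50, 3),
    (0.05, 0.50, 4),
    (0.12, 0.65, 3),
    (0.08, 0.35, 4),
    (0.05, 0.65, 3),
    (0.12, 0.50, 4),
    (0.08, 0.65, 3),
    (0.05, 0.35, 4),
]


def island_configs(cfg: "EvolutionConfig") -> list:
    """Per-island operator configurations (identical when homogeneous)."""
    from dataclasses import replace

    if not cfg.heterogeneous_islands:
        return [cfg] * cfg.islands
    return [
        replace(
            cfg,
            mutation_rate=m,
            crossover_prob=x,
            n_registers=r,
        )
        for i in range(cfg.islands)
        for (m, x, r) in [_ISLAND_VARIANTS[i % len(_ISLAND_VARIANTS)]]
    ]


@dataclass
class PoolMember:
    program: Program
    fitness: float
    margin: float = 0.0  # smooth selection aid; see _evaluate


def program_fitness(program: Program, X, y, kind: str = "balanced") -> float:
    """Classification fitness on a labelled set.

    Balanced accuracy (sensitivity + specificity)/2 by default; plain
    accuracy with ``kind='raw'``.
    """
    return _evaluate(program, X, y, kind)[0]


def _evaluate(program: Program, X, y, kind: str = "balanced") -> tuple:
    """(fitness, margin) for one program.

    Fitness is the classification accuracy used for selection. The margin is
    a class-weighted mean of ``tanh(score)`` signed by the true label — a
    smooth correlate of accuracy used only to break exact fitness ties in
    tournaments, so that variants improving the decision margin without yet
    flipping any call are visible to selection (pure accuracy is a step
    function of program space and stalls the search otherwise).
    """
    y = np.asarray(y, dtype=bool)
    if y.all() or (~y).all():
        raise ValueError("fitness needs both classes present")
    scores = execute_effective(program, X)
    calls = scores > 0
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if kind == "raw":
        fit = float((calls == y).mean())
        weights = np.full(len(y), 1.0 / len(y))
    else:
        sens = float(calls[y].mean())
        spec = float((~calls[~y]).mean())
        fit = (sens + spec) / 2.0
        weights = np.where(y, 0.5 / n_pos, 0.5 / n_neg)
    margin = float((np.tanh(scores) * np.where(y, 1.0, -1.0) * weights).sum())
    return fit, margin


def _pick_winner(a: PoolMember, b: PoolMember, rng) -> PoolMember:
    if a.fitness != b.fitness:
        return a if a.fitness > b.fitness else b
    if a.margin != b.margin:
        return a if a.margin > b.margin else b
    if len(a.program) != len(b.program):
        return a if len(a.program) < len(b.program) else b
    return a if rng.integers(2) == 0 else b


def tournament_generation(
    population: list, X, y, cfg: EvolutionConfig, rng
) -> list:
    """One generation on one island; returns a population of equal size.

    n_i/2 random pairs -> n_i/2 surviving parents (retained) -> n_i/2
    offspring by copy-mutation or recombination of the survivors.
    """
    n = len(population)
    if n % 2:
        raise ValueError("population size must be even")
    order = rng.permutation(n)
    survivors = [
        _pick_winner(population[order[2 * i]], population[order[2 * i + 1]], rng)
        for i in range(n // 2)
    ]

    n_features = X.shape[1]
    queue = list(rng.permutation(len(survivors)))
    offspring: list[Program] = []
    while queue:
        if len(queue) >= 2 and rng.random() < cfg.crossover_prob:
            pa = survivors[queue.pop()].program
            pb = survivors[queue.pop()].program
            c1, c2 = crossover(pa, pb, cfg, rng)
            offspring.extend([mutate(c1, n_features, cfg, rng),
                              mutate(c2, n_features, cfg, rng)])
        else:
            pa = survivors[queue.pop()].program
            offspring.append(mutate(pa, n_features, cfg, rng))

    children = [
        PoolMember(p, *_evaluate(p, X, y, cfg.fitness_kind)) for p in offspring
    ]
    return survivors + children


def migration_due(generation: int, cfg: EvolutionConfig) -> bool:
    return (
        generation > cfg.warmup
        and (generation - cfg.warmup) % cfg.migration_interval == 0
    )


def migrate(islands: list, generation: int, cfg: EvolutionConfig) -> list:
    """Unidirectional toroidal migration of each island's top p percent.

    A no-op unless due. Every island loses its ``k = max(1, round(n_i*p/100))``
    fittest members to island ``(i+1) mod S`` simultaneously, so island sizes
    are conserved exactly.
    """
    if not migration_due(generation, cfg):
        return islands
    S = len(islands)
    k = max(1, round(len(islands[0]) * cfg.migration_percent / 100.0))
    split = []
    for pop in islands:
        order = sorted(range(len(pop)), key=lambda i: -pop[i].fitness)
        top = set(order[:k])
        migrants = [pop[i] for i in order[:k]]
        stay = [m for i, m in enumerate(pop) if i not in top]
        split.append((stay, migrants))
    return [split[i][0] + split[(i - 1) % S][1] for i in range(S)]


@dataclass
class EvolveResult:
    pool: list                      # all surviving PoolMembers, train fitness
    history: list = field(default_factory=list)  # global best per generation
    config: EvolutionConfig | None = None


def evolve(X, y, cfg: EvolutionConfig, seed: int | None = None) -> EvolveResult:
    """Run the full island-model evolution on a training set.

    Deterministic for a given seed. The returned pool is every member of
    every island after the final generation, with training fitness attached;
    ``history`` records the global best fitness at each generation (always
    non-decreasing: parents are retained and migration only moves members).
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_features = X.shape[1]
    icfgs = island_configs(cfg)

    islands = [
        [
            PoolMember(
                p := random_program(n_features, icfg, rng),
                *_evaluate(p, X, y, cfg.fitness_kind),
            )
            for _ in range(cfg.island_size)
        ]
        for icfg in icfgs
    ]
    history = [max(m.fitness for pop in islands for m in pop)]

    for gen in range(1, cfg.total_generations + 1):
        islands = [
            tournament_generation(pop, X, y, icfg, rng)
            for pop, icfg in zip(islands, icfgs)
        ]
        islands = migrate(islands, gen, cfg)
        history.append(max(m.fitness for pop in islands for m in pop))

    pool = [m for pop in islands for m in pop]
    return EvolveResult(pool, history, cfg)
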