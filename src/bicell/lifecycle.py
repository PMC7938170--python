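"""The population engine.

One cycle applies, in order, to every bicellular adult: (1) each cell splits
its current resource pool across foraging/repair/reproduction by its type's
softmax proportions; (2) both cells forage and the pooled returns are
redistributed by the signal-based shares (fixed 50/50 when sharing is not
evolvable) to form the next cycle's pools; (3) each cell draws an exponential
damage increment; (4) each cell repairs; (5) each cell reproduces with
probability 1-exp(-b*z), offspring developing immediately; (6) damage-driven
mortality per cell; (7) viability-locus mortality per cell; (8) individual
resolution — both cells dead kills the individual, a lone death is rescued by
regeneration with probability r; (9) offspring join; (10) the population is
culled uniformly at random down to n; (11) survivors' ages increment (the
cycle's newborns stay at age 0 until they complete a full cycle).

The engine is vectorised over the population.  A single numpy Generator is
consumed in a fixed documented order (damage increments, reproduction draws,
offspring mutation draws, mortality round 1, mortality round 2, regeneration
draws, cull permutation), so a run is exactly reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .errors import BicellError, ExtinctionError
from .genotype import (
    AllocationGenes,
    Genotype,
    flip_viability,
    mutate_continuous,
    mutate_viability,
    perturb_retention,
    perturb_unbounded,
    share_of_first,
    softmax_xy,
)
from .observables import CycleStats, compute_cycle_stats
from .params import ModelParams
from .physiology import (
    Cell,
    expressed_locus_index,
    foraging_return,
    intrinsic_mortality,
    repair,
    reproduction_probability,
)


@dataclass
class Individual:
    """A bicellular adult: two cells sharing one clonal genotype.

    ``viability_by_cell`` optionally carries a per-cell (2, n_loci) copy of
    the viability alleles; ``None`` means both cells carry
    ``genotype.viability`` (the default model).  The copies differ only under
    the extra-mutation-in-type-2 variant.
    """

    genotype: Genotype
    cells: tuple[Cell, Cell]
    age: int = 0
    viability_by_cell: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.cells[0].cell_type, self.cells[1].cell_type) != (1, 2):
            raise BicellError("an individual's cells must carry types 1 and 2")

    def cell_viability(self, cell_type: int) -> np.ndarray:
        if self.viability_by_cell is not None:
            return self.viability_by_cell[cell_type - 1]
        return np.array(self.genotype.viability, dtype=np.uint8)


@dataclass
class Population:
    """Array-of-individuals population state.

    All per-cell arrays have shape ``(size, 2)`` with column 0 = cell type 1;
    ``viab`` has shape ``(size, 2, n_loci)``.  Continuous genes are shared by
    the two cells of an individual but indexed by the type they apply to.
    """

    gx: np.ndarray         # foraging genes, by cell type
    gy: np.ndarray         # repair genes
    gs: np.ndarray         # resource-signal genes (unbounded; signal = exp)
    ret: np.ndarray        # damage-retention proportions
    viab: np.ndarray       # viability alleles per cell, uint8
    damage: np.ndarray
    resources: np.ndarray
    age: np.ndarray
    cycle: int = 0

    @property
    def size(self) -> int:
        return self.age.shape[0]

    @classmethod
    def initial(cls, params: ModelParams) -> "Population":
        """The symmetric founding population: ancestral genotypes, zero
        damage, the baseline resource endowment, age zero."""
        n, L = params.n, params.n_loci
        return cls(
            gx=np.zeros((n, 2)), gy=np.zeros((n, 2)), gs=np.zeros((n, 2)),
            ret=np.full((n, 2), 0.5), viab=np.zeros((n, 2, L), dtype=np.uint8),
            damage=np.zeros((n, 2)),
            resources=np.full((n, 2), params.initial_resources),
            age=np.zeros(n, dtype=np.int64),
        )

    @classmethod
    def empty(cls, n_loci: int, cycle: int = 0) -> "Population":
        return cls(
            gx=np.zeros((0, 2)), gy=np.zeros((0, 2)), gs=np.zeros((0, 2)),
            ret=np.zeros((0, 2)), viab=np.zeros((0, 2, n_loci), dtype=np.uint8),
            damage=np.zeros((0, 2)), resources=np.zeros((0, 2)),
            age=np.zeros(0, dtype=np.int64), cycle=cycle,
        )

    def subset(self, idx) -> "Population":
        return Population(
            gx=self.gx[idx], gy=self.gy[idx], gs=self.gs[idx], ret=self.ret[idx],
            viab=self.viab[idx], damage=self.damage[idx],
            resources=self.resources[idx], age=self.age[idx], cycle=self.cycle,
        )

    @staticmethod
    def concat(a: "Population", b: "Population") -> "Population":
        return Population(
            gx=np.concatenate([a.gx, b.gx]), gy=np.concatenate([a.gy, b.gy]),
            gs=np.concatenate([a.gs, b.gs]), ret=np.concatenate([a.ret, b.ret]),
            viab=np.concatenate([a.viab, b.viab]),
            damage=np.concatenate([a.damage, b.damage]),
            resources=np.concatenate([a.resources, b.resources]),
            age=np.concatenate([a.age, b.age]), cycle=a.cycle,
        )

    @classmethod
    def from_individuals(cls, individuals, n_loci: int = 16,
                         cycle: int = 0) -> "Population":
        n = len(individuals)
        pop = cls.empty(n_loci, cycle)
        if n == 0:
            return pop
        pop.gx = np.array([[i.genotype.alloc[0].x, i.genotype.alloc[1].x]
                           for i in individuals])
        pop.gy = np.array([[i.genotype.alloc[0].y, i.genotype.alloc[1].y]
                           for i in individuals])
        pop.gs = np.array([i.genotype.signal_genes for i in individuals], dtype=float)
        pop.ret = np.array([i.genotype.retention for i in individuals], dtype=float)
        pop.viab = np.array(
            [[i.cell_viability(1), i.cell_viability(2)] for i in individuals],
            dtype=np.uint8,
        )
        pop.damage = np.array([[c.damage for c in i.cells] for i in individuals])
        pop.resources = np.array([[c.resources for c in i.cells] for i in individuals])
        pop.age = np.array([i.age for i in individuals], dtype=np.int64)
        return pop

    def to_individuals(self) -> list[Individual]:
        out = []
        for i in range(self.size):
            g = Genotype(
                alloc=(AllocationGenes(float(self.gx[i, 0]), float(self.gy[i, 0])),
                       AllocationGenes(float(self.gx[i, 1]), float(self.gy[i, 1]))),
                signal_genes=(float(self.gs[i, 0]), float(self.gs[i, 1])),
                retention=(float(self.ret[i, 0]), float(self.ret[i, 1])),
                viability=tuple(int(b) for b in self.viab[i, 0]),
            )
            cells = (
                Cell(1, float(self.damage[i, 0]), float(self.resources[i, 0])),
                Cell(2, float(self.damage[i, 1]), float(self.resources[i, 1])),
            )
            out.append(Individual(genotype=g, cells=cells, age=int(self.age[i]),
                                  viability_by_cell=self.viab[i].copy()))
        return out


@dataclass
class SimulationResult:
    params: ModelParams
    trajectory: list[CycleStats]
    population: Population
    extinct: bool = False

    @property
    def completed_cycles(self) -> int:
        return len(self.trajectory)


# ---------------------------------------------------------------------------
# offspring development and regeneration
# ---------------------------------------------------------------------------

def develop_offspring(mother_cell: Cell, mother_genotype: Genotype,
                      p_z: float, rng: np.random.Generator,
                      params: ModelParams) -> Individual:
    """Produce one adult offspring from a reproducing cell.

    The propagule inherits ``(1 - retention[mother_type])`` of the mother
    cell's damage (the mother keeps the rest — ``mother_cell`` is updated in
    place) and resources proportional to the mother's proportional investment
    into reproduction (``kappa * p_z``), and develops by doubling once:
    damage and resources split equally between its type-1 and type-2 cells.  The genotype passes through continuous and
    viability mutation; under the extra-mutation variant the type-2 cell's
    viability copy undergoes one additional round.
    """
    if not mother_cell.alive:
        raise BicellError("develop_offspring called with a dead mother cell")
    t = mother_cell.cell_type - 1
    keep = mother_genotype.retention[t]
    passed = (1.0 - keep) * mother_cell.damage
    mother_cell.damage = keep * mother_cell.damage
    resources = float(_propagule_resources(p_z, params))

    g = mutate_continuous(mother_genotype, rng, params)
    if params.extra_mutation_type2:
        # extra mutation round on every gene expressed by the type-2 cell
        gx2 = perturb_unbounded(np.array([g.alloc[1].x]), params.mu, params.sigma, rng)
        gy2 = perturb_unbounded(np.array([g.alloc[1].y]), params.mu, params.sigma, rng)
        gs2 = np.array([g.signal_genes[1]])
        if params.evolvable_sharing:
            gs2 = perturb_unbounded(gs2, params.mu, params.sigma, rng)
        ret2 = np.array([g.retention[1]])
        if params.evolvable_retention and params.mu_d > 0:
            ret2 = perturb_retention(ret2, params.mu_d, params.sigma, rng)
        g = dc_replace(
            g,
            alloc=(g.alloc[0], AllocationGenes(float(gx2[0]), float(gy2[0]))),
            signal_genes=(g.signal_genes[0], float(gs2[0])),
            retention=(g.retention[0], float(ret2[0])),
        )
    g = mutate_viability(g, rng, params, rounds=1)
    v = np.array(g.viability, dtype=np.uint8)
    viab = np.stack([v, v])
    if params.extra_mutation_type2:
        viab[1] = flip_viability(viab[1], params.mu_v0, params.mu_v1, rng)

    cells = (Cell(1, passed / 2.0, resources / 2.0),
             Cell(2, passed / 2.0, resources / 2.0))
    return Individual(genotype=g, cells=cells, age=0, viability_by_cell=viab)


def regenerate(survivor: Cell, genotype: Genotype,
               params: ModelParams) -> tuple[Cell, Cell]:
    """Rebuild a bicellular adult from a lone surviving cell.

    The survivor doubles once, splitting its damage and resources equally
    between a fresh type-1 and type-2 cell; no mutation occurs and the
    individual's age is preserved by the caller.
    """
    if not survivor.alive:
        raise BicellError("regenerate called with a dead cell")
    half_d, half_r = survivor.damage / 2.0, survivor.resources / 2.0
    return (Cell(1, half_d, half_r), Cell(2, half_d, half_r))


def _propagule_resources(p_z, params: ModelParams):
    """Resources transferred to a propagule: proportional to the mother's
    reaction-norm investment into reproduction (``kappa * p_z``)."""
    return params.kappa * np.asarray(p_z)


def _spawn_offspring(pop: Population, reproduces: np.ndarray, pz: np.ndarray,
                     rng: np.random.Generator, params: ModelParams) -> Population:
    """Vectorised offspring development for all reproducing cells.

    Reduces the mothers' damage in place (retention kept) and returns the
    offspring as a new Population block, in (individual, cell-type) order.
    """
    idx, col = np.nonzero(reproduces)
    k = idx.size
    off = Population.empty(params.n_loci, pop.cycle)
    if k == 0:
        return off
    keep = pop.ret[idx, col]
    d = pop.damage[idx, col]
    pop.damage[idx, col] = keep * d
    passed = (1.0 - keep) * d
    res = _propagule_resources(pz[idx, col], params)

    gx, gy, gs, ret = pop.gx[idx], pop.gy[idx], pop.gs[idx], pop.ret[idx]
    if params.mu > 0:
        gx = perturb_unbounded(gx, params.mu, params.sigma, rng)
        gy = perturb_unbounded(gy, params.mu, params.sigma, rng)
        if params.evolvable_sharing:
            gs = perturb_unbounded(gs, params.mu, params.sigma, rng)
    if params.evolvable_retention and params.mu_d > 0:
        ret = perturb_retention(ret, params.mu_d, params.sigma, rng)
    if params.extra_mutation_type2 and k:
        # the type-2 daughter lineage undergoes one extra round of mutation
        # at development: all genes expressed by cell type 2 are hit again
        gx[:, 1] = perturb_unbounded(gx[:, 1], params.mu, params.sigma, rng)
        gy[:, 1] = perturb_unbounded(gy[:, 1], params.mu, params.sigma, rng)
        if params.evolvable_sharing:
            gs[:, 1] = perturb_unbounded(gs[:, 1], params.mu, params.sigma, rng)
        if params.evolvable_retention and params.mu_d > 0:
            ret[:, 1] = perturb_retention(ret[:, 1], params.mu_d, params.sigma, rng)
    v = flip_viability(pop.viab[idx, col], params.mu_v0, params.mu_v1, rng)
    viab = np.stack([v, v], axis=1)
    if params.extra_mutation_type2:
        viab[:, 1, :] = flip_viability(viab[:, 1, :], params.mu_v0,
                                       params.mu_v1, rng)

    off.gx, off.gy, off.gs, off.ret, off.viab = gx, gy, gs, ret, viab
    off.damage = np.column_stack([passed / 2.0, passed / 2.0])
    off.resources = np.column_stack([res / 2.0, res / 2.0])
    off.age = np.zeros(k, dtype=np.int64)
    return off


# ---------------------------------------------------------------------------
# the cycle
# ---------------------------------------------------------------------------

def run_cycle(pop: Population, params: ModelParams,
              rng: np.random.Generator) -> tuple[Population, CycleStats]:
    """Advance the population by one full cycle; returns the new population
    and the cycle's statistics.  Raises :class:`ExtinctionError` if called on
    an empty population."""
    n = pop.size
    if n == 0:
        raise ExtinctionError("run_cycle called on an extinct population")

    # (1) allocation of the current pools
    px, py, pz = softmax_xy(pop.gx, pop.gy)
    pool = pop.resources
    xa, ya, za = px * pool, py * pool, pz * pool
    mean_alloc = np.stack(
        [[px[:, t].mean(), py[:, t].mean(), pz[:, t].mean()] for t in (0, 1)]
    )

    # (2) foraging; pooled returns redistributed by the signal shares
    gains = foraging_return(xa, params)
    total = gains[:, 0] + gains[:, 1]
    if params.evolvable_sharing:
        sh1 = share_of_first(pop.gs[:, 0], pop.gs[:, 1])
    else:
        sh1 = np.full(n, 0.5)
    new_resources = np.column_stack([total * sh1, total * (1.0 - sh1)])
    mean_share = np.array([sh1.mean(), 1.0 - sh1.mean()])

    # (3) damage accumulation, (4) repair
    pop.damage = pop.damage + rng.exponential(1.0 / params.lam, (n, 2))
    pop.damage = repair(pop.damage, ya, params)

    # (5) reproduction and offspring development
    p_rep = reproduction_probability(za, params)
    reproduces = rng.random((n, 2)) < p_rep
    offspring = _spawn_offspring(pop, reproduces, pz, rng, params)

    # (6) mortality round 1: damage-dependent cellular death
    exposures_by_age = np.bincount(pop.age)
    dead = rng.random((n, 2)) < intrinsic_mortality(pop.damage, params)

    # (7) mortality round 2: expressed deleterious viability alleles
    locus = expressed_locus_index(pop.damage, params)
    carrier = np.take_along_axis(pop.viab, locus[:, :, None], axis=2)[:, :, 0] == 1
    dead |= carrier & (rng.random((n, 2)) < params.m2)

    # (8) individual-level resolution and regeneration
    n_dead = dead.sum(axis=1)
    lone = np.nonzero(n_dead == 1)[0]
    regen = np.zeros(n, dtype=bool)
    if lone.size:
        regen[lone] = rng.random(lone.size) < params.r
    dies = (n_dead == 2) | ((n_dead == 1) & ~regen)
    deaths_by_age = np.bincount(pop.age[dies], minlength=exposures_by_age.size)

    ridx = np.nonzero((n_dead == 1) & regen)[0]
    if ridx.size:
        surv = np.argmin(dead[ridx], axis=1)   # column of the living cell
        half_d = pop.damage[ridx, surv] / 2.0
        pop.damage[ridx, 0] = half_d
        pop.damage[ridx, 1] = half_d
        half_r = new_resources[ridx, surv] / 2.0
        new_resources[ridx, 0] = half_r
        new_resources[ridx, 1] = half_r
        v_surv = pop.viab[ridx, surv, :].copy()
        pop.viab[ridx, 0, :] = v_surv
        if params.extra_mutation_type2:
            # regeneration is a doubling: the variant's extra viability
            # mutation round applies to the fresh type-2 cell here as well
            v_surv = flip_viability(v_surv, params.mu_v0, params.mu_v1, rng)
        pop.viab[ridx, 1, :] = v_surv

    pop.resources = new_resources

    # (9) offspring join, (11) survivors' ages increment
    survivors = pop.subset(np.nonzero(~dies)[0])
    survivors.age = survivors.age + 1
    merged = Population.concat(survivors, offspring)

    # (10) random cull down to the population ceiling
    if merged.size > params.n:
        sel = rng.permutation(merged.size)[: params.n]
        sel.sort()
        merged = merged.subset(sel)

    merged.cycle = pop.cycle + 1
    stats = compute_cycle_stats(
        merged, params, cycle=merged.cycle, mean_alloc=mean_alloc,
        mean_share=mean_share, deaths_by_age=deaths_by_age,
        exposures_by_age=exposures_by_age,
    )
    return merged, stats


def run_simulation(params: ModelParams,
                   rng: np.random.Generator | None = None) -> SimulationResult:
    """Run ``params.cycles`` population cycles from the symmetric founding
    state.  Bitwise reproducible for a fixed seed.  If the population goes
    extinct the trajectory is truncated and flagged."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pop = Population.initial(params)
    trajectory: list[CycleStats] = []
    extinct = False
    for _ in range(params.cycles):
        pop, stats = run_cycle(pop, params, rng)
        trajectory.append(stats)
        if pop.size == 0:
            extinct = True
            break
    return SimulationResult(params=params, trajectory=trajectory,
                            population=pop, extinct=extinct)
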