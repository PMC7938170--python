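"""Population engine: development, regeneration, the cycle, whole runs."""

import numpy as np
import pytest

from bicell import (
    BicellError,
    Cell,
    Genotype,
    Individual,
    ModelParams,
    Population,
    develop_offspring,
    make_fixture,
    regenerate,
    run_cycle,
    run_simulation,
)
from bicell.errors import ExtinctionError
from bicell.observables import trajectory_frame


def no_mutation(**kw) -> ModelParams:
    base = dict(n=50, cycles=10, mu=0.0, sigma=0.0, mu_v0=0.0, mu_v1=0.0,
                mu_d=0.0, d_scale=1000.0, r=1.0, seed=0)
    base.update(kw)
    return ModelParams(**base)


class TestDevelopOffspring:
    def test_equal_partitioning_splits_damage_in_quarters(self, rng):
        # mother damage 4, retention 0.5: mother keeps 2, each offspring cell 1
        mother = Cell(1, damage=4.0, resources=3.0)
        child = develop_offspring(mother, Genotype.ancestral(), 0.75, rng,
                                  no_mutation())
        assert mother.damage == pytest.approx(2.0)
        assert child.cells[0].damage == pytest.approx(1.0)
        assert child.cells[1].damage == pytest.approx(1.0)
        assert child.age == 0

    def test_full_retention_gives_damage_free_daughters(self, rng):
        g = Genotype(alloc=Genotype.ancestral().alloc, retention=(1.0, 1.0))
        mother = Cell(1, damage=4.0, resources=1.0)
        child = develop_offspring(mother, g, 0.5, rng, no_mutation())
        assert mother.damage == pytest.approx(4.0)
        assert child.cells[0].damage == 0.0 and child.cells[1].damage == 0.0

    def test_zero_retention_rejuvenates_mother(self, rng):
        g = Genotype(alloc=Genotype.ancestral().alloc, retention=(0.0, 0.0))
        mother = Cell(1, damage=4.0, resources=1.0)
        child = develop_offspring(mother, g, 0.5, rng, no_mutation())
        assert mother.damage == 0.0
        assert child.cells[0].damage == pytest.approx(2.0)

    def test_damage_conserved_at_division(self, rng):
        g = Genotype(alloc=Genotype.ancestral().alloc, retention=(0.37, 0.5))
        mother = Cell(1, damage=1.234567, resources=1.0)
        before = mother.damage
        child = develop_offspring(mother, g, 0.6, rng, no_mutation())
        total = mother.damage + child.cells[0].damage + child.cells[1].damage
        assert total == pytest.approx(before, abs=1e-9)

    def test_endowment_proportional_to_reproductive_investment(self, rng):
        p = no_mutation()
        mother = Cell(2, damage=0.0, resources=1.0)
        child = develop_offspring(mother, Genotype.ancestral(), 0.8, rng, p)
        assert child.cells[0].resources == pytest.approx(p.kappa * 0.8 / 2)

    def test_uses_mother_types_retention(self, rng):
        g = Genotype(alloc=Genotype.ancestral().alloc, retention=(0.9, 0.1))
        mother = Cell(2, damage=2.0, resources=1.0)      # type 2 -> keeps 0.1
        develop_offspring(mother, g, 0.5, rng, no_mutation())
        assert mother.damage == pytest.approx(0.2)

    def test_dead_mother_rejected(self, rng):
        dead = Cell(1, alive=False)
        with pytest.raises(BicellError):
            develop_offspring(dead, Genotype.ancestral(), 0.5, rng, no_mutation())

    def test_extra_mutation_variant_diverges_type2_copy_only(self):
        rng = np.random.default_rng(0)
        p = no_mutation(mu_v0=0.5, extra_mutation_type2=True)
        mother = Cell(1, damage=0.0, resources=1.0)
        child = develop_offspring(mother, Genotype.ancestral(), 0.5, rng, p)
        v1, v2 = child.cell_viability(1), child.cell_viability(2)
        assert np.array_equal(v1, np.array(child.genotype.viability))
        assert not np.array_equal(v1, v2)          # extra round hit type 2


class TestRegenerate:
    def test_equal_split_and_conservation(self):
        surv = Cell(1, damage=3.0, resources=2.0)
        c1, c2 = regenerate(surv, Genotype.ancestral(), no_mutation())
        assert (c1.cell_type, c2.cell_type) == (1, 2)
        assert c1.damage == c2.damage == pytest.approx(1.5)
        assert c1.damage + c2.damage == pytest.approx(3.0, abs=1e-9)

    def test_zero_resources_survivor(self):
        surv = Cell(2, damage=0.0, resources=0.0)
        c1, c2 = regenerate(surv, Genotype.ancestral(), no_mutation())
        assert c1.resources == c2.resources == 0.0

    def test_dead_survivor_rejected(self):
        with pytest.raises(BicellError):
            regenerate(Cell(1, alive=False), Genotype.ancestral(), no_mutation())


class TestRunCycle:
    def test_population_never_exceeds_ceiling(self):
        p = ModelParams(n=40, cycles=0, d_scale=1000.0, r=1.0, seed=1)
        pop = Population.initial(p)
        rng = np.random.default_rng(1)
        for _ in range(30):
            pop, _ = run_cycle(pop, p, rng)
            assert pop.size <= p.n

    def test_static_population_ages_in_lockstep(self):
        # no damage deaths, no viability deaths, no births (b = 0)
        p = no_mutation(b=0.0, m2=0.0, d_scale=float("inf"), n=30)
        pop = Population.initial(p)
        rng = np.random.default_rng(2)
        genes_before = pop.gx.copy()
        for t in range(5):
            pop, stats = run_cycle(pop, p, rng)
            assert pop.size == 30
            assert np.all(pop.age == t + 1)
            assert stats.deaths_by_age.sum() == 0
        assert np.array_equal(pop.gx, genes_before)

    def test_no_deaths_without_damage_or_viability_mortality(self):
        # m2 = 0, D -> inf, r = 1: only culling removes individuals
        p = no_mutation(m2=0.0, d_scale=float("inf"), r=1.0, n=60)
        pop = Population.initial(p)
        rng = np.random.default_rng(3)
        for _ in range(20):
            pop, stats = run_cycle(pop, p, rng)
            assert stats.deaths_by_age.sum() == 0

    def test_extinction_raises_on_empty_population(self):
        p = no_mutation(n=4)
        empty = Population.empty(p.n_loci)
        with pytest.raises(ExtinctionError):
            run_cycle(empty, p, np.random.default_rng(0))

    def test_lethal_environment_goes_extinct(self):
        p = ModelParams(n=20, cycles=40, d_scale=1e-9, r=0.0, b=0.01, seed=5)
        res = run_simulation(p)
        assert res.extinct
        assert res.completed_cycles < 40
        assert res.population.size == 0

    def test_regeneration_preserves_age_and_total_state(self):
        # r = 1 with certain cell death for one cell is hard to isolate at the
        # population level; instead check the regenerated rows split evenly
        p = no_mutation(n=200, d_scale=0.8, r=1.0)
        pop = Population.initial(p)
        rng = np.random.default_rng(4)
        for _ in range(6):
            pop, _ = run_cycle(pop, p, rng)
        # after regeneration both cells of an individual carry equal damage
        # whenever a lone death occurred; at minimum the arrays stay valid
        assert np.all(pop.damage >= 0)
        assert np.all(pop.resources >= 0)


class TestRunSimulation:
    def test_zero_cycles_returns_initial_state(self):
        p = no_mutation(cycles=0)
        res = run_simulation(p)
        assert res.trajectory == []
        assert res.population.size == p.n
        assert not res.extinct

    def test_same_seed_gives_identical_trajectories(self):
        p = ModelParams(n=80, cycles=40, d_scale=1000.0, r=0.5, seed=42)
        a, b = run_simulation(p), run_simulation(p)
        fa, fb = trajectory_frame(a.trajectory), trajectory_frame(b.trajectory)
        assert fa.equals(fb)
        assert np.array_equal(a.population.damage, b.population.damage)
        assert np.array_equal(a.population.viab, b.population.viab)

    def test_different_seeds_differ(self):
        p = ModelParams(n=80, cycles=40, d_scale=1000.0, r=0.5, seed=42)
        a = run_simulation(p)
        b = run_simulation(p.with_overrides(seed=43))
        assert not np.array_equal(a.population.damage, b.population.damage)

    def test_no_mutation_symmetry_never_breaks(self):
        p = no_mutation(n=100, cycles=50, b=0.1, d_scale=1000.0)
        res = run_simulation(p)
        for stats in res.trajectory:
            assert np.array_equal(stats.mean_alloc[0], stats.mean_alloc[1])
            assert stats.mean_share[0] == pytest.approx(0.5, abs=1e-12)

    def test_death_rate_monotone_in_damage_scale(self):
        # weakening the damage->mortality coupling (higher D) never raises
        # the equilibrium death rate, on matched seeds.  (Median *age* is not
        # monotone in D here: at high D the random cull replaces damage
        # mortality as the dominant removal process and shortens lives more
        # than weak damage does.)
        def death_rate(d_scale, seed):
            p = ModelParams(n=400, cycles=300, d_scale=d_scale, r=0.5,
                            seed=seed)
            res = run_simulation(p)
            window = res.trajectory[-30:]
            deaths = sum(s.deaths_by_age.sum() for s in window)
            exposures = sum(s.exposures_by_age.sum() for s in window)
            return deaths / exposures

        for seed in range(5):
            r1, r2, r3 = (death_rate(d, seed) for d in (1.0, 2.0, 1000.0))
            assert r1 >= r2 >= r3


class TestPopulationContainer:
    def test_round_trip_through_individuals(self):
        pop = make_fixture("one_carrier")
        back = Population.from_individuals(pop.to_individuals())
        assert np.array_equal(pop.gx, back.gx)
        assert np.array_equal(pop.viab, back.viab)
        assert np.array_equal(pop.damage, back.damage)
        assert np.array_equal(pop.age, back.age)

    def test_subset_and_concat(self):
        pop = make_fixture("symmetric_start")
        left, right = pop.subset([0, 1]), pop.subset([2, 3])
        merged = Population.concat(left, right)
        assert merged.size == pop.size
        assert np.array_equal(merged.resources, pop.resources)

    def test_individual_requires_both_cell_types(self):
        with pytest.raises(BicellError):
            Individual(Genotype.ancestral(), (Cell(1), Cell(1)))
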