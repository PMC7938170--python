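# Methods

## Model overview

`bicell` simulates a population of at most `N` bicellular adults in
discrete, overlapping-generation cycles.  The two cells of an adult carry a
single clonal haploid genotype but distinct, heritable *type labels* (1 =
mother position, 2 = daughter position), so reaction norms can condition on
type and division of labour can — but need not — evolve.

The heritable state per cell type is: two unbounded allocation genes
(foraging gene `x`, repair gene `y`) whose three-way softmax gives the
proportions of the cell's resource pool spent on foraging, repair and
reproduction; one unbounded resource-signal gene (realized signal
`s = e^gene`, so positivity is structural and the trait mutates additively
like the allocation genes); and one damage-retention proportion in [0, 1].
The genotype also carries 16 bi-allelic viability loci (0 neutral,
1 deleterious).

## The cycle

Per cycle, in order, for every adult:

1. **Allocation.** Each cell splits its current pool `P` into
   `x = p_x P`, `y = p_y P`, `z = p_z P` by its type's softmax proportions.
2. **Foraging and redistribution.** Cells gain `f(x) = f_max·x/(x+h)`; the
   two cells' gains are pooled and redistributed by the signal shares
   `s₁/(s₁+s₂)` (fixed 50/50 when sharing is not evolvable).  Redistributed
   gains form the *next* cycle's pools: allocation always acts on the pool
   assembled in the previous cycle, which keeps the within-cycle budget
   well defined (gains cannot fund the allocation that produced them).
3. **Damage.** Each cell draws an Exponential(λ) increment, then repairs:
   `d ← d·exp(−a·y)`.
4. **Reproduction.** Each cell independently produces a propagule with
   probability `1 − exp(−b·z)`.  The propagule receives
   `(1 − retention)` of the mother cell's current damage (the mother keeps
   the rest) and `κ·p_z` resources, and doubles into a new adult (damage
   and resources split equally over its two cells).  The genotype passes
   through mutation on the way (below).
5. **Mortality round 1.** Cell death with probability
   `m₁ = (1−c)(d/D) + c(d/D)⁴`, clamped to [0, 1] (the raw expression
   exceeds 1 for `d > D`).
6. **Mortality round 2.** The damage level selects exactly one viability
   locus (16 half-open, lower-inclusive windows evenly spaced on [0, 6];
   overflow expresses the last locus).  If that locus carries the
   deleterious allele, the cell dies with probability `m₂`.
7. **Resolution.** Both cells dead → the adult dies.  Exactly one dead →
   with probability `r` the survivor doubles again, splitting its damage
   and next-cycle pool equally over fresh type-1/type-2 cells (no mutation,
   age preserved); otherwise the adult dies.
8. **Recruitment and cull.** This cycle's offspring join (they are not
   exposed to this cycle's mortality) and the population is culled
   uniformly at random down to `N`.  Survivors' ages increment; newborns
   stay at age 0 until they complete a full cycle.

A single seeded PCG64 generator is consumed in a fixed order (damage,
reproduction, offspring mutation, mortality 1, mortality 2, regeneration,
cull), so runs are bitwise reproducible from the seed.

## Mutation

At offspring production, each continuous gene (x, y and signal genes of
both types) independently receives a Gaussian(0, σ) increment with
probability μ.  The retention trait mutates with probability μ_d on the
log-odds scale (logit, clipped to ±36 so the logistic back-transform is
exact at the ends) — the unit interval is closed under mutation and the
ancestral value 0.5 is a symmetry point.  Viability loci flip 0→1 with
probability μ_v0 and 1→0 with μ_v1 (biased toward deleterious).

The offspring's viability vector derives from the *reproducing cell's* own
copy.  Both cells of an adult normally carry identical copies; under the
`extra_mutation_type2` variant the type-2 cell's copy — and every gene
expressed by cell type 2 (its allocation, signal and retention genes) —
undergoes one additional mutation round at development, and the type-2
viability copy also receives the extra round when an adult is rebuilt by
regeneration (regeneration is a doubling too; without this the type-1
survivor's copy would systematically overwrite the variant's asymmetry).
The variant gives the type-2 lineage a persistently larger mutational load
and, empirically, makes cell type 1 the germ-line in every replicate.

## Parameters

Biological constants (defaults in `ModelParams`, bound per experiment by
the presets): `N = 10⁵`, `f_max = 6`, `h = 0.3` (resources), `λ = 2`
(1/damage), `a = 0.5`, `b = 0.1` (1/resources), `c = 0.8`, `m₂ = 0.05`,
`μ = 0.05`, `σ = 0.5`, `μ_v0 = 10⁻³`, `μ_v1 = 10⁻⁴`; the damage scale `D`
is 1000 in the symmetric-senescence experiment and 1 in the
division-of-labour experiments; `μ_d` is 0 except in the
damage-partitioning experiments (0.05).

Two quantities the model statement leaves open were fixed as follows:

* **Founding endowment** (`initial_resources = 5.0` per cell): the
  self-consistent ancestral steady-state pool, i.e. the solution of
  `P = f(P/3)` at the symmetric one-third allocation.  Founding the
  population far below this scale starves the first generations of repair
  and, at `D = 1`, collapses the population before evolution can act.
* **Propagule provisioning** (`κ·p_z` with `κ = 5.0`): offspring resources
  are proportional to the mother's *proportional* investment in
  reproduction, so a fully reproduction-committed mother endows her
  propagule at the ancestral steady-state scale.  Making the endowment
  proportional to the absolute spend `z` instead couples offspring quality
  to the mother's pool size; because fecundity is nearly linear at
  `b·z ≪ 1`, that coupling convexly rewards concentrating resources in one
  reproducing cell and drives spurious germ/soma branching even in the
  high-D regime where the two types should remain interchangeable.  The
  p_z form keeps the symmetric regime symmetric while preserving
  "reproduction specialists make well-endowed offspring".

`r` — the probability that a lone surviving cell regenerates the adult —
is the axis of the division-of-labour experiments.  `r = 0.5` (partial
death-linkage) is used for the reproductive-monopolization presets
(`fig2a`, `fig3a`, the ablation and the replicate presets): full linkage
(`r = 0`) is demographically inviable at `D = 1` from the ancestral state
(cellular mortality ≈ 0.17 per cycle against fecundity ≈ 0.31 per adult
collapses the population within ~100 cycles), while full regeneration
removes the survival externality that forces the soma to maintain itself.
`r = 1` is used for the disposable-partner presets (`fig2b`, `fig3b`).

## Engine

The population is stored as flat numpy arrays (genes, retention, per-cell
viability, damage, pools, ages) and the whole cycle is vectorised; a
10⁴-adult population advances in ~4 ms per cycle, so every preset here runs
on one CPU in seconds to minutes.  The dataclass surface
(`Genotype`/`Cell`/`Individual` and the scalar operations
`develop_offspring`, `regenerate`, `softmax_allocations`, …) shares the
same mutation cores as the array engine and converts losslessly to and
from the array form.

## Observables

Per cycle: mean allocation profile, realized resource share, mean damage
and mean retention per cell type; deleterious-allele frequency per locus
(fraction of individuals carrying the allele in either cell); age and
damage histograms; deaths and exposures per age class (whole-individual
deaths from the mortality rounds — culling is not a death).  "Final"
quantities are means over the last 10% of cycles.  Age-specific mortality
is deaths/exposures pooled over that window; the division-of-labour index
is the L1 distance between the two types' window-averaged allocation
profiles (0 = identical, 2 = disjoint).

## Desk scale and what the tests show

The published experiments use `N = 10⁵` and 10⁴ cycles; the test suite and
the acceptance script run scaled-down versions (N = 5,000–20,000, 10³–5·10³
cycles) chosen so each phenomenon is resolved above drift at single-CPU
runtimes.  The between-type divergence index in the symmetric experiment is
drift-limited and shrinks with N, hence the largest affordable population
(N = 20,000) is used for that check; the germ-line identity batches use
N = 3,000, the smallest scale at which all replicates diverge and the
asymmetric-mutation variant is deterministic.

Two full-scale outcomes do not reproduce under this implementation's
resource accounting, and the corresponding checks are expected to fail —
they are retained unweakened as an honest record:

* **The 100%-foraging soma under full regeneration.**  At `r = 1` a clear
  maintenance division of labour evolves (one durable, repairing,
  resource-rich type; one disposable, non-repairing forager), but the
  forager keeps reproducing: with regeneration insuring against lone-cell
  death and propagule endowment tied to p_z, poorly-pooled cells still
  produce viable offspring.  The fully specialized state (soma foraging
  ≥ 95%) is quasi-stable when constructed — it persists for thousands of
  cycles before share drift lets soma reproduction re-invade — but is not
  reached from the ancestral state.
* **Germ retention → 1 under partial linkage.**  With retention evolvable,
  the reproduction-monopolizing type evolves retention near *zero* (the
  mother rejuvenates herself and ships damage to the propagule) rather
  than near one.  In this implementation the monopolist repairs heavily,
  so its standing damage (~0.22) makes the dumped propagule damage
  (~0.1 per daughter cell) almost free, while keeping itself clean
  compounds over its lifetime.  The opposite, mother-retains asymmetry does evolve
  in the full-regeneration variant, where the non-repairing reproducer
  reaches retention ≈ 0.99 and produces damage-free daughters.  Both
  outcomes are evolved asymmetries of damage inheritance from the
  symmetric ancestral state; the direction differs.

The synthetic populations the engine evolves are the study system itself
(the model *is* the object of study); no empirical data are emulated, so
passing tests certify the model's internal behaviour, not any fit to
biological measurements.

## Numerical notes

Softmax and signal shares are computed in max-shifted/logistic form and are
overflow-safe for any finite genes.  Damage windows are half-open and
lower-inclusive with `searchsorted`; damage at or beyond the last boundary
expresses the final locus.  Damage is conserved to 1e-9 at division and
regeneration.  The mortality curve is clamped to [0, 1].  Retention values
of exactly 0 or 1 remain mutable through the logit clip.  Culling uses a
seeded permutation (uniform without replacement), preserving index order
for reproducibility.

## Limitations

Single panmictic population; clonal haploid inheritance (no recombination,
no relatedness below 1 between the two cells); one locus expressed per cell
per cycle; damage windows fixed on [0, 6] rather than adapted to the
realized damage range; no spatial structure; no plotting.
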