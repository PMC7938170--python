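"""Experiment presets, the replicate runner, and deterministic test fixtures.

The presets bind the model's published parameter columns.  All share
N=1e5, f_max=6, h=0.3, lam=2, a=0.5, b=0.1, c=0.8, m2=0.05, mu=0.05,
sigma=0.5, mu_v0=1e-3, mu_v1=1e-4 and differ in the damage scale D, the
regeneration probability r, and the retention mutation rate mu_d:

=================  ======  =====  ======  ==============================
preset             D       r      mu_d    phenomenon
=================  ======  =====  ======  ==============================
fig1               1000    0      0       senescence without asymmetry
fig2a              1       0.5    0       germ/soma reproductive split
fig2b              1       1      0       disposable soma (regeneration)
fig3a              1       0.5    0.05    evolvable damage partitioning
fig3b              1       1      0.05    idem, with regeneration
=================  ======  =====  ======  ==============================

``r`` is the probability that a lone surviving cell regenerates the adult;
low ``r`` couples the two cells' fates (death of either tends to kill the
individual) while ``r=1`` makes the partner freely replaceable.  Partial
linkage (r=0.5, within the (0,1) range the source table lists for these
experiments) is the regime in which one type monopolizes reproduction;
full regeneration produces a disposable forager type instead.

Derived presets: ``no_share_ablation`` (fig2a without evolvable resource
sharing), ``germline_symmetry`` (fig2a scaled for replicate batches) and
``extra_mutation_type2`` (germline_symmetry with one extra round of
viability mutation in the type-2 cell lineage at development).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import BicellError
from .genotype import AllocationGenes, Genotype
from .lifecycle import Individual, Population, SimulationResult, run_simulation
from .observables import (
    empirical_mortality_by_age,
    equilibrium_summary,
    snapshot_frame,
    summary_frame,
    trajectory_frame,
)
from .params import ModelParams
from .physiology import Cell

_SHARED = dict(
    n=100_000, f_max=6.0, h=0.3, lam=2.0, a=0.5, b=0.1, c=0.8,
    m2=0.05, mu=0.05, sigma=0.5, mu_v0=1e-3, mu_v1=1e-4, cycles=10_000,
)

#: replicate-batch scale for the germ-line identity experiments: the smallest
#: desk scale at which germ/soma divergence completes in every run and the
#: deterministic effect of the asymmetric-mutation variant is resolved above
#: drift, while a 10-run batch still completes in a couple of minutes.
_REPLICATE_N = 3_000
_REPLICATE_CYCLES = 4_000

PRESETS: dict[str, ModelParams] = {
    "fig1": ModelParams(**_SHARED, d_scale=1000.0, r=0.0, mu_d=0.0),
    "fig2a": ModelParams(**_SHARED, d_scale=1.0, r=0.5, mu_d=0.0),
    "fig2b": ModelParams(**_SHARED, d_scale=1.0, r=1.0, mu_d=0.0),
    "fig3a": ModelParams(**_SHARED, d_scale=1.0, r=0.5, mu_d=0.05),
    "fig3b": ModelParams(**_SHARED, d_scale=1.0, r=1.0, mu_d=0.05),
    "no_share_ablation": ModelParams(**_SHARED, d_scale=1.0, r=0.5, mu_d=0.0,
                                     evolvable_sharing=False),
    "germline_symmetry": ModelParams(**{**_SHARED, "n": _REPLICATE_N,
                                        "cycles": _REPLICATE_CYCLES},
                                     d_scale=1.0, r=0.5, mu_d=0.0),
    "extra_mutation_type2": ModelParams(**{**_SHARED, "n": _REPLICATE_N,
                                           "cycles": _REPLICATE_CYCLES},
                                        d_scale=1.0, r=0.5, mu_d=0.0,
                                        extra_mutation_type2=True),
}


def get_preset(name: str) -> ModelParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise BicellError(
            f"unknown preset {name!r}; known presets: {', '.join(sorted(PRESETS))}"
        ) from None


def _params_hash(params: ModelParams) -> str:
    text = "\n".join(f"{k}\t{v}" for k, v in params.to_flat().items())
    return hashlib.sha256(text.encode()).hexdigest()


@dataclass
class RunOutput:
    result: SimulationResult
    out_dir: Path | None = None


def run_preset(name: str, overrides: dict | None = None, seed: int | None = None,
               scale: float = 1.0, cycles: int | None = None,
               out_dir=None) -> RunOutput:
    """Run one experiment preset, optionally scaled down and written to disk.

    ``scale`` in (0, 1] multiplies the population size N (cycle counts are
    set independently via ``cycles``).  When ``out_dir`` is given the run
    writes a config echo, the per-cycle trajectory, equilibrium and mortality
    summaries, the final population snapshot, and a manifest with the seed
    and a parameter hash sufficient to reproduce the run byte-for-byte.
    """
    if not (0.0 < scale <= 1.0):
        raise BicellError(f"scale must lie in (0, 1], got {scale}")
    params = get_preset(name)
    kwargs: dict = dict(overrides or {})
    bad = set(kwargs) - {f.name for f in params.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    if bad:
        raise BicellError(f"invalid override keys: {sorted(bad)}")
    if scale != 1.0:
        kwargs.setdefault("n", max(1, int(round(params.n * scale))))
    if cycles is not None:
        kwargs["cycles"] = cycles
    if seed is not None:
        kwargs["seed"] = seed
    params = params.with_overrides(**kwargs)

    result = run_simulation(params)

    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        params.write_config(out_path / "config.tsv")
        trajectory_frame(result.trajectory).to_csv(
            out_path / "trajectory.tsv", sep="\t", index=False)
        summary_frame(equilibrium_summary(result.trajectory)).to_csv(
            out_path / "summary.tsv", sep="\t", index=False)
        try:
            empirical_mortality_by_age(result.trajectory).to_csv(
                out_path / "mortality.tsv", sep="\t", index=False)
        except BicellError:
            pass
        snapshot_frame(result.population).to_csv(
            out_path / "snapshot.tsv", sep="\t", index=False)
        manifest = {
            "preset": name,
            "seed": params.seed,
            "scale": scale,
            "n": params.n,
            "cycles": params.cycles,
            "completed_cycles": result.completed_cycles,
            "extinct": result.extinct,
            "package_version": __version__,
            "params_hash": _params_hash(params),
        }
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return RunOutput(result=result, out_dir=out_path)


# ---------------------------------------------------------------------------
# replicate batches and germ-line identity
# ---------------------------------------------------------------------------

def germline_type(trajectory, window_frac: float = 0.1,
                  min_gap: float = 0.1) -> int | None:
    """Classify which cell type became the germ-line in one run.

    The germ-line is the type with the higher mean reproduction allocation
    over the final window; gaps smaller than ``min_gap`` are left
    unclassified (``None``) to avoid noise-driven labels.
    """
    summ = equilibrium_summary(trajectory, window_frac)
    pz = summ["mean_alloc"][:, 2]
    if abs(pz[0] - pz[1]) < min_gap:
        return None
    return 1 if pz[0] > pz[1] else 2


@dataclass
class ReplicateResult:
    table: pd.DataFrame
    tally: dict


def replicate_experiment(name: str, n_reps: int, base_seed: int,
                         overrides: dict | None = None, scale: float = 1.0,
                         cycles: int | None = None) -> ReplicateResult:
    """Run ``n_reps`` independent replicates of a preset and tally the
    germ-line identity of each.

    Replicate seeds are spawned from ``base_seed`` via a SeedSequence, so any
    replicate can be reproduced in isolation.  The tally maps cell type (1 or
    2) and ``"unclassified"`` to run counts.
    """
    if n_reps < 1:
        raise BicellError("n_reps must be >= 1")
    children = np.random.SeedSequence(base_seed).spawn(n_reps)
    rows = []
    tally = {1: 0, 2: 0, "unclassified": 0}
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2**31))
        run = run_preset(name, overrides=overrides, seed=seed, scale=scale,
                         cycles=cycles)
        summ = equilibrium_summary(run.result.trajectory)
        winner = germline_type(run.result.trajectory)
        tally[winner if winner is not None else "unclassified"] += 1
        rows.append({
            "replicate": i, "seed": seed,
            "pz_1": summ["mean_alloc"][0, 2], "pz_2": summ["mean_alloc"][1, 2],
            "px_1": summ["mean_alloc"][0, 0], "px_2": summ["mean_alloc"][1, 0],
            "dol_index": summ["dol_index"],
            "germline": 0 if winner is None else winner,
            "extinct": run.result.extinct,
        })
    return ReplicateResult(table=pd.DataFrame(rows), tally=tally)


# ---------------------------------------------------------------------------
# deterministic unit-test fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, seed: int = 0) -> Population:
    """Tiny deterministic populations for unit tests.

    ``symmetric_start``
        four identical ancestral individuals, zero damage.
    ``one_carrier``
        four ancestral individuals, exactly one deleterious allele in the
        population (locus index 6 of individual 0).
    ``specialized_pair``
        two individuals with hand-set genes: type 1 allocates essentially
        everything to reproduction, type 2 everything to foraging.
    """
    if kind == "symmetric_start":
        inds = [Individual(Genotype.ancestral(),
                           (Cell(1, 0.0, 1.0), Cell(2, 0.0, 1.0)))
                for _ in range(4)]
    elif kind == "one_carrier":
        carrier_viab = tuple(1 if j == 6 else 0 for j in range(16))
        inds = [Individual(Genotype.ancestral(),
                           (Cell(1, 0.0, 1.0), Cell(2, 0.0, 1.0)))
                for _ in range(4)]
        inds[0] = Individual(
            Genotype(alloc=(AllocationGenes(0, 0), AllocationGenes(0, 0)),
                     viability=carrier_viab),
            (Cell(1, 0.0, 1.0), Cell(2, 0.0, 1.0)),
        )
    elif kind == "specialized_pair":
        germ = AllocationGenes(-12.0, -12.0)      # p_z ~ 1
        soma = AllocationGenes(12.0, -12.0)       # p_x ~ 1
        g = Genotype(alloc=(germ, soma))
        inds = [Individual(g, (Cell(1, 0.0, 1.0), Cell(2, 0.0, 1.0)))
                for _ in range(2)]
    else:
        raise BicellError(f"unknown fixture kind {kind!r}")
    return Population.from_individuals(inds)
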