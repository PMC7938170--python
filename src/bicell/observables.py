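"""Per-cycle and end-of-run population summaries.

These reproduce the quantitative content of the model's standard read-outs:
allocation trajectories per cell type, resource/damage partitioning between
types, deleterious-allele frequencies per damage window, age and damage
distributions, and empirical (binned, unsmoothed) age-specific mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .params import ModelParams


@dataclass
class CycleStats:
    """Summary of one completed population cycle.

    ``mean_alloc`` has shape (2, 3): rows are cell types 1 and 2, columns the
    mean proportional allocation to foraging, repair and reproduction of the
    individuals alive at the start of the cycle.  ``deaths_by_age`` and
    ``exposures_by_age`` count whole-individual deaths (mortality rounds, not
    culling) and individuals at risk, indexed by age in cycles.  End-of-cycle
    state (damage, ages, allele frequencies) describes the population after
    culling; NaN/empty when the population went extinct during the cycle.
    """

    cycle: int
    pop_size: int
    mean_alloc: np.ndarray
    mean_share: np.ndarray
    mean_damage: np.ndarray
    mean_retention: np.ndarray
    allele_freq: np.ndarray
    age_hist: np.ndarray
    damage_hist: np.ndarray
    deaths_by_age: np.ndarray
    exposures_by_age: np.ndarray


def allele_frequencies_by_locus(pop) -> np.ndarray:
    """Per-locus fraction of individuals carrying the deleterious allele.

    The denominator is individuals (clonal haploid genotypes); an individual
    counts as a carrier if either of its cells carries the allele (the two
    copies differ only under the extra-mutation variant).
    """
    if pop.size == 0:
        raise UndefinedStatisticError("allele frequencies of an empty population")
    return (pop.viab.any(axis=1)).mean(axis=0)


def division_of_labour_index(stats: CycleStats) -> float:
    """L1 distance between the two cell types' mean allocation profiles.

    Ranges over [0, 2]; 0 iff the types allocate identically, 2 for fully
    disjoint specialization.
    """
    return float(np.abs(stats.mean_alloc[0] - stats.mean_alloc[1]).sum())


def dol_from_profiles(profile_1, profile_2) -> float:
    """L1 divergence of two allocation profiles given directly as length-3
    arrays ``(p_x, p_y, p_z)``."""
    return float(np.abs(np.asarray(profile_1, float) - np.asarray(profile_2, float)).sum())


def damage_by_age_summary(pop) -> pd.DataFrame:
    """Median and 10%/90% quantiles of per-individual mean damage, by age."""
    if pop.size == 0:
        raise UndefinedStatisticError("damage-by-age summary of an empty population")
    mean_damage = pop.damage.mean(axis=1)
    df = pd.DataFrame({"age": pop.age, "damage": mean_damage})
    out = (
        df.groupby("age")["damage"]
        .agg(n="size", q10=lambda s: s.quantile(0.10), median="median",
             q90=lambda s: s.quantile(0.90))
        .reset_index()
    )
    return out


def _pool_age_arrays(arrays: list[np.ndarray]) -> np.ndarray:
    width = max((a.size for a in arrays), default=0)
    out = np.zeros(width, dtype=float)
    for a in arrays:
        out[: a.size] += a
    return out


def empirical_mortality_by_age(trajectory, window_frac: float = 0.1) -> pd.DataFrame:
    """Binned age-specific mortality, pooled over the final window of cycles.

    For each age class ``a``, the death probability is deaths(a)/exposures(a)
    with deaths and exposures summed over the last ``window_frac`` of the
    trajectory; age classes with zero exposure are omitted.
    """
    if not trajectory:
        raise UndefinedStatisticError("mortality of an empty trajectory")
    k = max(1, int(round(window_frac * len(trajectory))))
    window = trajectory[-k:]
    deaths = _pool_age_arrays([s.deaths_by_age for s in window])
    exposures = _pool_age_arrays([s.exposures_by_age for s in window])
    if exposures.sum() == 0:
        raise UndefinedStatisticError("no exposures recorded in the pooling window")
    keep = exposures > 0
    ages = np.nonzero(keep)[0]
    return pd.DataFrame(
        {
            "age": ages,
            "deaths": deaths[keep],
            "exposures": exposures[keep],
            "mortality": deaths[keep] / exposures[keep],
        }
    )


def equilibrium_summary(trajectory, window_frac: float = 0.1) -> dict:
    """Means of the per-cycle summaries over the final window of cycles.

    Returns a dict with per-type arrays: ``mean_alloc`` (2, 3),
    ``mean_share`` (2,), ``mean_damage`` (2,), ``mean_retention`` (2,),
    ``allele_freq`` (n_loci,), and the scalar ``dol_index`` computed from the
    window-averaged allocation profiles.
    """
    if not trajectory:
        raise UndefinedStatisticError("equilibrium summary of an empty trajectory")
    k = max(1, int(round(window_frac * len(trajectory))))
    window = trajectory[-k:]
    alloc = np.mean([s.mean_alloc for s in window], axis=0)
    out = {
        "cycles_pooled": k,
        "mean_alloc": alloc,
        "mean_share": np.mean([s.mean_share for s in window], axis=0),
        "mean_damage": np.mean([s.mean_damage for s in window], axis=0),
        "mean_retention": np.mean([s.mean_retention for s in window], axis=0),
        "allele_freq": np.mean([s.allele_freq for s in window], axis=0),
        "dol_index": dol_from_profiles(alloc[0], alloc[1]),
    }
    return out


# ---------------------------------------------------------------------------
# construction (called by the engine once per cycle)
# ---------------------------------------------------------------------------

def compute_cycle_stats(pop, params: ModelParams, cycle: int,
                        mean_alloc: np.ndarray, mean_share: np.ndarray,
                        deaths_by_age: np.ndarray,
                        exposures_by_age: np.ndarray) -> CycleStats:
    """Assemble a :class:`CycleStats` from the end-of-cycle population and
    the within-cycle tallies the engine recorded."""
    L = params.n_loci
    if pop.size == 0:
        return CycleStats(
            cycle=cycle, pop_size=0, mean_alloc=mean_alloc, mean_share=mean_share,
            mean_damage=np.full(2, np.nan), mean_retention=np.full(2, np.nan),
            allele_freq=np.full(L, np.nan), age_hist=np.zeros(0, dtype=np.int64),
            damage_hist=np.zeros(L, dtype=np.int64),
            deaths_by_age=deaths_by_age, exposures_by_age=exposures_by_age,
        )
    locus = np.searchsorted(params.interior_bounds, pop.damage, side="right")
    return CycleStats(
        cycle=cycle,
        pop_size=pop.size,
        mean_alloc=mean_alloc,
        mean_share=mean_share,
        mean_damage=pop.damage.mean(axis=0),
        mean_retention=pop.ret.mean(axis=0),
        allele_freq=allele_frequencies_by_locus(pop),
        age_hist=np.bincount(pop.age),
        damage_hist=np.bincount(locus.ravel(), minlength=L),
        deaths_by_age=deaths_by_age,
        exposures_by_age=exposures_by_age,
    )


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def trajectory_frame(trajectory) -> pd.DataFrame:
    """One row per cycle with the scalar per-type summaries and the per-locus
    deleterious-allele frequencies."""
    rows = []
    for s in trajectory:
        row = {"cycle": s.cycle, "pop_size": s.pop_size}
        for t in (0, 1):
            row[f"px_{t + 1}"] = s.mean_alloc[t, 0]
            row[f"py_{t + 1}"] = s.mean_alloc[t, 1]
            row[f"pz_{t + 1}"] = s.mean_alloc[t, 2]
            row[f"share_{t + 1}"] = s.mean_share[t]
            row[f"damage_{t + 1}"] = s.mean_damage[t]
            row[f"retention_{t + 1}"] = s.mean_retention[t]
        row["dol_index"] = division_of_labour_index(s)
        row["deaths"] = int(s.deaths_by_age.sum())
        row["exposures"] = int(s.exposures_by_age.sum())
        for k, f in enumerate(s.allele_freq, start=1):
            row[f"freq_locus_{k:02d}"] = f
        rows.append(row)
    return pd.DataFrame(rows)


def snapshot_frame(pop) -> pd.DataFrame:
    """One row per individual: age, per-type state, continuous genes, and the
    viability alleles as 16-character strings (one per cell)."""
    def _bits(col):
        return ["".join(map(str, row)) for row in pop.viab[:, col, :]]

    return pd.DataFrame(
        {
            "id": np.arange(pop.size),
            "age": pop.age,
            "damage_1": pop.damage[:, 0], "damage_2": pop.damage[:, 1],
            "resources_1": pop.resources[:, 0], "resources_2": pop.resources[:, 1],
            "x_1": pop.gx[:, 0], "x_2": pop.gx[:, 1],
            "y_1": pop.gy[:, 0], "y_2": pop.gy[:, 1],
            "signal_gene_1": pop.gs[:, 0], "signal_gene_2": pop.gs[:, 1],
            "retention_1": pop.ret[:, 0], "retention_2": pop.ret[:, 1],
            "viability_1": _bits(0), "viability_2": _bits(1),
        }
    )


def summary_frame(summary: dict) -> pd.DataFrame:
    """Long-format table of an equilibrium summary (metric, cell_type, value)."""
    rows = []
    names = ("px", "py", "pz")
    for t in (0, 1):
        for j, nm in enumerate(names):
            rows.append({"metric": nm, "cell_type": t + 1,
                         "value": summary["mean_alloc"][t, j]})
        rows.append({"metric": "share", "cell_type": t + 1,
                     "value": summary["mean_share"][t]})
        rows.append({"metric": "damage", "cell_type": t + 1,
                     "value": summary["mean_damage"][t]})
        rows.append({"metric": "retention", "cell_type": t + 1,
                     "value": summary["mean_retention"][t]})
    rows.append({"metric": "dol_index", "cell_type": 0, "value": summary["dol_index"]})
    for k, f in enumerate(summary["allele_freq"], start=1):
        rows.append({"metric": f"freq_locus_{k:02d}", "cell_type": 0, "value": f})
    return pd.DataFrame(rows)
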