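"""Heritable state, the genotype->phenotype transform, and mutation operators.

A genotype carries, for each of the two cell types:

* two unbounded allocation genes ``x`` (foraging) and ``y`` (repair) whose
  three-way softmax yields the proportions of the cell's resource pool spent
  on foraging, repair and reproduction;
* one unbounded resource-signal gene; the realized signal is its exponential,
  so signals are strictly positive and the signalling trait mutates on the
  same additive Gaussian scale as the allocation genes;
* one damage-retention proportion in [0, 1] (the fraction of her own damage a
  mother cell keeps at division), mutated on the log-odds scale so the unit
  interval is closed under mutation and 0.5 is a symmetric ancestral state;

plus 16 bi-allelic viability loci (0 = neutral, 1 = deleterious) with biased
flip mutation (neutral->deleterious more likely than the reverse).

The array functions at the bottom are the single implementation of every
mutation operator; both the scalar dataclass API and the vectorised population
engine call them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .errors import InvalidGenotypeError
from .params import ModelParams

#: retention log-odds are clipped to this magnitude before perturbation so the
#: logistic back-transform never overflows and retention values of exactly 0
#: or 1 remain mutable.
LOGIT_BOUND = 36.0


@dataclass(frozen=True)
class AllocationGenes:
    """Unbounded foraging (x) and repair (y) genes of one cell type."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidGenotypeError(
                f"allocation genes must be finite, got x={self.x}, y={self.y}"
            )


@dataclass(frozen=True)
class AllocationProfile:
    """Proportional allocation to foraging (p_x), repair (p_y), reproduction (p_z)."""

    p_x: float
    p_y: float
    p_z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_x, self.p_y, self.p_z])


@dataclass(frozen=True)
class Genotype:
    """Clonal haploid genotype shared by the two cells of an individual.

    ``alloc``, ``signal_genes`` and ``retention`` are indexed by cell type
    (entry 0 -> type 1, entry 1 -> type 2).  ``viability`` holds the 16
    bi-allelic loci of the lineage (the reproducing cell's copy).
    """

    alloc: tuple[AllocationGenes, AllocationGenes]
    signal_genes: tuple[float, float] = (0.0, 0.0)
    retention: tuple[float, float] = (0.5, 0.5)
    viability: tuple[int, ...] = (0,) * 16

    def __post_init__(self) -> None:
        if len(self.alloc) != 2:
            raise InvalidGenotypeError("alloc must have one entry per cell type")
        for g in self.signal_genes:
            if not math.isfinite(g):
                raise InvalidGenotypeError(f"signal gene must be finite, got {g}")
        for rho in self.retention:
            if not (0.0 <= rho <= 1.0):
                raise InvalidGenotypeError(f"retention must lie in [0, 1], got {rho}")
        if any(v not in (0, 1) for v in self.viability):
            raise InvalidGenotypeError("viability alleles must be 0 or 1")

    @property
    def signals(self) -> tuple[float, float]:
        """Strictly positive realized resource-need signals (exp of the genes)."""
        return (math.exp(self.signal_genes[0]), math.exp(self.signal_genes[1]))

    @classmethod
    def ancestral(cls, n_loci: int = 16) -> "Genotype":
        """The symmetric founding genotype: equal thirds allocation, equal
        signals, equal damage partitioning, no deleterious alleles."""
        return cls(
            alloc=(AllocationGenes(0.0, 0.0), AllocationGenes(0.0, 0.0)),
            signal_genes=(0.0, 0.0),
            retention=(0.5, 0.5),
            viability=(0,) * n_loci,
        )


# ---------------------------------------------------------------------------
# genotype -> phenotype
# ---------------------------------------------------------------------------

def softmax_xy(x, y):
    """Three-way softmax of the allocation genes, with an implicit third
    category at logit 0 (reproduction).

    Works elementwise on arrays.  Numerically stable for any finite inputs:
    returns ``(p_x, p_y, p_z)`` with ``p_x = e^x / (1 + e^x + e^y)`` etc. and
    ``p_z = 1 - p_x - p_y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.maximum(0.0, np.maximum(x, y))
    ex = np.exp(x - m)
    ey = np.exp(y - m)
    e0 = np.exp(-m)
    total = e0 + ex + ey
    return ex / total, ey / total, e0 / total


def softmax_allocations(genes: AllocationGenes) -> AllocationProfile:
    """Transform one cell type's allocation genes to proportions."""
    if not (math.isfinite(genes.x) and math.isfinite(genes.y)):
        raise InvalidGenotypeError("allocation genes must be finite")
    p_x, p_y, p_z = softmax_xy(genes.x, genes.y)
    return AllocationProfile(float(p_x), float(p_y), float(p_z))


def resource_shares(s1: float, s2: float) -> tuple[float, float]:
    """Split the pooled foraging returns by the two cells' signals.

    Cell 1 receives ``s1 / (s1 + s2)`` and cell 2 the rest; invariant under
    common rescaling of the signals.
    """
    if not (s1 > 0 and s2 > 0) or not (math.isfinite(s1) and math.isfinite(s2)):
        raise InvalidGenotypeError(f"signals must be positive finite, got {s1}, {s2}")
    total = s1 + s2
    return (s1 / total, s2 / total)


def share_of_first(g1, g2):
    """Share of cell 1 directly from the unbounded signal genes.

    ``exp(g1) / (exp(g1) + exp(g2))`` computed as a logistic of the gene
    difference, so it is stable for any finite genes.  Elementwise.
    """
    return expit(np.asarray(g1, dtype=float) - np.asarray(g2, dtype=float))


# ---------------------------------------------------------------------------
# mutation cores (arrays; in a fixed draw order for reproducibility)
# ---------------------------------------------------------------------------

def perturb_unbounded(values: np.ndarray, rate: float, sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Each entry independently receives a Gaussian(0, sigma) increment with
    probability ``rate``.  Returns a new array."""
    values = np.asarray(values, dtype=float)
    hit = rng.random(values.shape) < rate
    eps = rng.normal(0.0, sigma, values.shape)
    return np.where(hit, values + eps, values)


def perturb_retention(values: np.ndarray, rate: float, sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Logit-scale Gaussian perturbation of retention proportions.

    Each entry independently, with probability ``rate``, has its log-odds
    (clipped to +-LOGIT_BOUND) incremented by Gaussian(0, sigma) and is mapped
    back through the logistic function, so results stay in [0, 1].
    """
    values = np.asarray(values, dtype=float)
    hit = rng.random(values.shape) < rate
    eps = rng.normal(0.0, sigma, values.shape)
    with np.errstate(divide="ignore"):
        lo = np.clip(logit(values), -LOGIT_BOUND, LOGIT_BOUND)
    return np.where(hit, expit(lo + eps), values)


def flip_viability(viab: np.ndarray, mu_v0: float, mu_v1: float,
                   rng: np.random.Generator, rounds: int = 1) -> np.ndarray:
    """Biased bit-flip mutation of viability loci.

    Per round, each locus flips 0->1 with probability ``mu_v0`` and 1->0 with
    probability ``mu_v1``, independently.  Returns a new uint8 array.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    v = np.asarray(viab, dtype=np.uint8).copy()
    for _ in range(rounds):
        u = rng.random(v.shape)
        p = np.where(v == 1, mu_v1, mu_v0)
        v = np.where(u < p, 1 - v, v).astype(np.uint8)
    return v


# ---------------------------------------------------------------------------
# scalar mutation operators (thin wrappers over the array cores)
# ---------------------------------------------------------------------------

def mutate_continuous(genotype: Genotype, rng: np.random.Generator,
                      params: ModelParams) -> Genotype:
    """Mutate the continuous reaction-norm genes of a genotype.

    The six unbounded genes (x and y of both types, both signal genes) each
    mutate with probability ``mu`` by a Gaussian(0, sigma) increment; the two
    retention values each mutate with probability ``mu_d`` on the logit scale.
    The input genotype is unmodified.  Draw order matches the population
    engine: x genes, y genes, signal genes, retention.
    """
    gx = np.array([genotype.alloc[0].x, genotype.alloc[1].x])
    gy = np.array([genotype.alloc[0].y, genotype.alloc[1].y])
    gs = np.array(genotype.signal_genes, dtype=float)
    ret = np.array(genotype.retention, dtype=float)
    if params.mu > 0:
        gx = perturb_unbounded(gx, params.mu, params.sigma, rng)
        gy = perturb_unbounded(gy, params.mu, params.sigma, rng)
        if params.evolvable_sharing:
            gs = perturb_unbounded(gs, params.mu, params.sigma, rng)
    if params.evolvable_retention and params.mu_d > 0:
        ret = perturb_retention(ret, params.mu_d, params.sigma, rng)
    return replace(
        genotype,
        alloc=(AllocationGenes(float(gx[0]), float(gy[0])),
               AllocationGenes(float(gx[1]), float(gy[1]))),
        signal_genes=(float(gs[0]), float(gs[1])),
        retention=(float(ret[0]), float(ret[1])),
    )


def mutate_viability(genotype: Genotype, rng: np.random.Generator,
                     params: ModelParams, rounds: int = 1) -> Genotype:
    """Apply ``rounds`` rounds of biased viability-locus mutation; returns a
    new genotype, input unmodified."""
    v = flip_viability(np.array(genotype.viability, dtype=np.uint8),
                       params.mu_v0, params.mu_v1, rng, rounds=rounds)
    return replace(genotype, viability=tuple(int(b) for b in v))
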