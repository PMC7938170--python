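"""Model parameters.

``ModelParams`` collects every biological constant of the bicellular
life-history model together with the engine settings (cycle count, seed,
experiment flags).  Defaults correspond to the shared column of the model's
parameter table with the high-extrinsic-mortality damage scale (``d_scale=1``);
the experiment presets in :mod:`bicell.experiments` bind complete columns.

Parameter glossary
------------------
n
    population ceiling: number of bicellular adults after culling.
f_max, h
    maximal foraging return (resources) and half-saturation constant of the
    Monod-type foraging curve ``f(x) = f_max * x / (x + h)``.
lam
    rate of the exponential distribution of per-cycle damage increments
    (mean increment ``1/lam``).
a
    repair efficiency (1/resources): damage after repair is ``d * exp(-a*y)``.
b
    fecundity return rate (1/resources): reproduction probability is
    ``1 - exp(-b*z)``.
c
    convexity of the damage->mortality curve, from linear (0) to quartic (1).
d_scale
    damage scale of the intrinsic mortality curve (the model's D, "inverse
    extrinsic mortality"); small values make damage strongly lethal.
m2
    per-locus death probability when an expressed viability locus carries the
    deleterious allele.
r
    regeneration probability: when exactly one cell of an adult dies, the
    survivor doubles and rebuilds the adult with probability ``r``; otherwise
    the individual dies.
mu, sigma
    per-gene mutation probability and Gaussian effect size of the continuous
    reaction-norm genes (allocation and resource-signal genes).
mu_v0, mu_v1
    per-locus viability mutation probabilities, neutral->deleterious and
    deleterious->neutral (biased: mu_v0 > mu_v1).
mu_d
    mutation probability of the damage-retention locus (per cell type).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Iterator

import numpy as np

_BOOL_FIELDS = ("extra_mutation_type2", "evolvable_sharing", "evolvable_retention")
_INT_FIELDS = ("n", "n_loci", "cycles", "seed")


@dataclass(frozen=True)
class ModelParams:
    n: int = 100_000
    f_max: float = 6.0
    h: float = 0.3
    lam: float = 2.0
    a: float = 0.5
    b: float = 0.1
    c: float = 0.8
    d_scale: float = 1.0
    m2: float = 0.05
    r: float = 1.0
    mu: float = 0.05
    sigma: float = 0.5
    mu_v0: float = 1e-3
    mu_v1: float = 1e-4
    mu_d: float = 0.0
    # engine settings
    n_loci: int = 16
    damage_max: float = 6.0        # upper edge of the evenly spaced expression windows
    kappa: float = 5.0             # propagule resources = kappa * mother's p_z
    initial_resources: float = 5.0 # per-cell endowment of the founding generation
    cycles: int = 10_000
    seed: int = 0
    extra_mutation_type2: bool = False
    evolvable_sharing: bool = True
    evolvable_retention: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size n must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        for name in ("f_max", "a", "b", "kappa", "initial_resources"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("h", "lam", "d_scale", "damage_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("c", "m2", "r", "mu", "mu_v0", "mu_v1", "mu_d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.sigma >= 0:
            raise ValueError("sigma must be >= 0")

    @property
    def interior_bounds(self) -> np.ndarray:
        """The ``n_loci - 1`` interior damage-window boundaries.

        Windows are half-open and lower-inclusive: locus ``k`` (0-based) is
        expressed for damage in ``[edges[k], edges[k+1])``; damage at or
        beyond ``damage_max`` expresses the final locus.
        """
        return np.linspace(0.0, self.damage_max, self.n_loci + 1)[1:-1]

    @property
    def window_edges(self) -> np.ndarray:
        """All ``n_loci + 1`` window edges from 0 to ``damage_max``."""
        return np.linspace(0.0, self.damage_max, self.n_loci + 1)

    # -- flat key/value config format -------------------------------------

    def to_flat(self) -> dict[str, str]:
        """Serialize to a flat, order-stable mapping of strings."""
        out: dict[str, str] = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in _BOOL_FIELDS:
                out[f.name] = "true" if v else "false"
            elif f.name in _INT_FIELDS:
                out[f.name] = str(int(v))
            else:
                out[f.name] = repr(float(v))
        return out

    @classmethod
    def from_flat(cls, mapping: dict[str, str]) -> "ModelParams":
        kwargs: dict[str, object] = {}
        valid = {f.name for f in fields(cls)}
        for key, raw in mapping.items():
            if key not in valid:
                raise KeyError(f"unknown parameter {key!r}")
            if key in _BOOL_FIELDS:
                if raw.strip().lower() not in ("true", "false"):
                    raise ValueError(f"{key} must be 'true' or 'false'")
                kwargs[key] = raw.strip().lower() == "true"
            elif key in _INT_FIELDS:
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)  # type: ignore[arg-type]

    def write_config(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in self.to_flat().items():
                fh.write(f"{key}\t{val}\n")

    @classmethod
    def read_config(cls, path) -> "ModelParams":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("\t")
                mapping[key] = val
        return cls.from_flat(mapping)

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def parse_override(text: str) -> tuple[str, str]:
    """Parse a ``key=value`` override string."""
    key, sep, val = text.partition("=")
    if not sep or not key:
        raise ValueError(f"override must have the form key=value, got {text!r}")
    return key.strip(), val.strip()
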