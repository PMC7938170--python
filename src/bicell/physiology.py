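"""Per-cycle physiology of a single cell: the model's five response curves
and the damage-window expression rule.

All functions are pure and work elementwise on scalars or arrays, so the
vectorised population engine calls exactly the same code the scalar API does.
Damage is a non-negative per-cell quantity that accrues stochastically
(exponential increments), is reduced multiplicatively by repair, gates which
viability locus is expressed, and raises intrinsic mortality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams


@dataclass
class Cell:
    """One of the two cells of an adult.

    ``cell_type`` is 1 (mother lineage position) or 2 (daughter position);
    ``damage`` and ``resources`` are non-negative; ``alive`` flags survival
    through the current cycle's mortality rounds.
    """

    cell_type: int
    damage: float = 0.0
    resources: float = 0.0
    alive: bool = True

    def __post_init__(self) -> None:
        if self.cell_type not in (1, 2):
            raise ValueError(f"cell_type must be 1 or 2, got {self.cell_type}")
        if self.damage < 0 or self.resources < 0:
            raise ValueError("damage and resources must be non-negative")


def _check_nonneg(value, name: str):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def foraging_return(x_alloc, params: ModelParams):
    """Resources gained by investing ``x_alloc`` into foraging.

    Saturating (Monod) returns ``f_max * x / (x + h)``: concave increasing,
    bounded above by ``f_max``, half-maximal at ``x = h``.
    """
    x = _check_nonneg(x_alloc, "foraging allocation")
    out = params.f_max * x / (x + params.h)
    return out if out.ndim else float(out)


def damage_increment(rng: np.random.Generator, params: ModelParams, size=None):
    """One (or ``size``) exponential damage increment(s) with mean ``1/lam``."""
    draw = rng.exponential(1.0 / params.lam, size)
    return draw if size is not None else float(draw)


def repair(d, y_alloc, params: ModelParams):
    """Damage left after investing ``y_alloc`` into repair: ``d * exp(-a*y)``.

    Never increases damage; monotone decreasing in the repair allocation.
    """
    d = _check_nonneg(d, "damage")
    y = _check_nonneg(y_alloc, "repair allocation")
    out = d * np.exp(-params.a * y)
    return out if out.ndim else float(out)


def reproduction_probability(z_alloc, params: ModelParams):
    """Probability of producing a daughter cell: ``1 - exp(-b*z)``.

    Zero at zero investment, concave increasing, saturating below 1.
    """
    z = _check_nonneg(z_alloc, "reproduction allocation")
    out = -np.expm1(-params.b * z)
    return out if out.ndim else float(out)


def intrinsic_mortality(d, params: ModelParams):
    """Damage-dependent death probability of the first mortality round.

    ``(1-c)*(d/D) + c*(d/D)^4`` clamped to [0, 1]: linear for ``c = 0``,
    strongly convex for ``c`` near 1; reaches 1 at ``d = D`` (the damage
    scale ``d_scale``).
    """
    d = _check_nonneg(d, "damage")
    q = d / params.d_scale
    out = np.clip((1.0 - params.c) * q + params.c * q**4, 0.0, 1.0)
    return out if out.ndim else float(out)


def expressed_locus_index(d, params: ModelParams):
    """0-based index of the viability locus expressed at damage ``d``.

    The ``n_loci`` windows are half-open and lower-inclusive, evenly spaced
    on ``[0, damage_max]``; damage at or beyond the last interior boundary
    expresses the final locus.
    """
    d = _check_nonneg(d, "damage")
    idx = np.searchsorted(params.interior_bounds, d, side="right")
    return idx if np.ndim(idx) else int(idx)


def viability_death(cell: Cell, viability, rng: np.random.Generator,
                    params: ModelParams) -> bool:
    """Second mortality round for one cell.

    If the cell's viability vector carries the deleterious allele at the
    locus expressed at its damage level, the cell dies with probability
    ``m2``; otherwise it survives this round.
    """
    if not cell.alive:
        raise ValueError("viability_death called on a dead cell")
    k = expressed_locus_index(cell.damage, params)
    if int(viability[k]) == 1:
        return bool(rng.random() < params.m2)
    return False
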