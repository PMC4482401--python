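"""Spine-count estimation and placement.

The number of putative spines on a dendrite follows the optimal-wiring
scaling law L = c · n^{2/3} · V^{1/3} relating total dendritic length L (μm),
synapse count n and dendrite volume V (μm³); inverting it gives

    n = round( ρ · (L / (c · V^{1/3}))^{3/2} )

with ρ a density multiplier (1 = the law's density). Spines are then
apportioned to branches proportionally to branch length, placed along each
branch either equidistantly or uniformly at random, and flagged with AMPA
and/or NMDA receptors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .morphology import Branch

__all__ = [
    "CuntzParams",
    "SpineBranch",
    "SpineMap",
    "cuntz_spine_count",
    "allocate_spines",
    "place_spines",
    "assign_receptors",
    "count_combinations",
    "build_spine_map",
    "DEFAULT_C",
]

#: Wiring-law proportionality constant, calibrated once so the packaged
#: mouse-like fixture suite has a mean spine density of 1.54 per μm.
DEFAULT_C = 0.8389


@dataclass(frozen=True)
class CuntzParams:
    """Wiring-law constant ``c`` and the density multiplier ρ."""

    c: float = DEFAULT_C
    density_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.density_multiplier <= 0:
            raise ValueError("density_multiplier must be > 0")


@dataclass(frozen=True)
class SpineBranch:
    """Spines of one branch: arc-length positions (μm) and receptor flags."""

    branch_index: int
    n: int
    positions: tuple[float, ...]
    ampa_flags: tuple[bool, ...]
    nmda_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.ampa_flags) == len(self.nmda_flags) == self.n):
            raise ValueError("positions and flag lists must all have length n")


@dataclass(frozen=True)
class SpineMap:
    entries: tuple[SpineBranch, ...]

    @property
    def n_total(self) -> int:
        return sum(e.n for e in self.entries)


def cuntz_spine_count(L: float, V: float, params: CuntzParams = CuntzParams()) -> int:
    """Total spine count implied by the wiring law for a dendrite of length
    ``L`` (μm) and volume ``V`` (μm³)."""
    if L < 0:
        raise ValueError("L must be >= 0")
    if L == 0:
        return 0
    if V <= 0:
        raise ValueError("V must be > 0 when L > 0")
    n = params.density_multiplier * (L / (params.c * V ** (1.0 / 3.0))) ** 1.5
    return int(round(n))


def allocate_spines(n_total: int, branches: list[Branch]) -> list[int]:
    """Distribute ``n_total`` spines over branches proportionally to branch
    length, conserving the total exactly (largest-remainder rounding, ties
    broken by branch index)."""
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    if not branches:
        if n_total > 0:
            raise ValueError("cannot allocate spines to an empty branch list")
        return []
    lengths = np.array([b.length for b in branches], dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("total branch length must be > 0")
    quota = n_total * lengths / total
    counts = np.floor(quota).astype(int)
    remainder = n_total - int(counts.sum())
    if remainder > 0:
        frac = quota - np.floor(quota)
        # largest remainders first; ties resolved by branch order
        order = np.lexsort((np.arange(len(frac)), -frac))
        counts[order[:remainder]] += 1
    return [int(c) for c in counts]


def place_spines(l_b: float, n_i: int, mode: str = "linspace", seed: int = 0) -> np.ndarray:
    """Arc-length spine positions on a branch of length ``l_b``.

    ``linspace`` places spines at the midpoints (j − ½)·l_b/n_i, giving a
    constant spacing of l_b/n_i without endpoint collisions; ``uniform``
    draws i.i.d. positions on [0, l_b] and sorts them.
    """
    if n_i < 0:
        raise ValueError("n_i must be >= 0")
    if n_i == 0:
        return np.empty(0)
    if mode == "linspace":
        j = np.arange(1, n_i + 1, dtype=float)
        return (j - 0.5) * l_b / n_i
    if mode == "uniform":
        rng = np.random.default_rng(seed)
        return np.sort(rng.uniform(0.0, l_b, size=n_i))
    raise ValueError(f"unknown placement mode {mode!r}")


def assign_receptors(n_i: int, fraction: float, seed: int = 0) -> np.ndarray:
    """Boolean receptor flags: exactly floor(fraction·n_i) spines flagged.

    fraction = 1 flags every spine deterministically; otherwise the flagged
    subset is chosen uniformly at random (seeded).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    k = math.floor(fraction * n_i)
    flags = np.zeros(n_i, dtype=bool)
    if k >= n_i:
        flags[:] = True
        return flags
    if k > 0:
        rng = np.random.default_rng(seed)
        flags[rng.choice(n_i, size=k, replace=False)] = True
    return flags


def count_combinations(n: int, k: int) -> int:
    """Exact binomial coefficient C(n, k): the number of distinct patterns of
    ``k`` co-activated spines among ``n``."""
    if k < 0 or n < 0:
        raise ValueError("n and k must be >= 0")
    if k > n:
        raise ValueError("k must not exceed n")
    return math.comb(n, k)


def build_spine_map(
    branches: list[Branch],
    n_total: int,
    spatial_mode: str = "linspace",
    ampa_fraction: float = 1.0,
    nmda_fraction: float = 0.5,
    seed: int = 0,
) -> SpineMap:
    """Allocate, place and receptor-flag spines over a whole dendrite."""
    counts = allocate_spines(n_total, branches)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(3 * max(len(branches), 1)) % (2**31 - 1)
    entries = []
    for i, (b, n_i) in enumerate(zip(branches, counts)):
        pos = place_spines(b.length, n_i, mode=spatial_mode, seed=int(child_seeds[3 * i]))
        ampa = assign_receptors(n_i, ampa_fraction, seed=int(child_seeds[3 * i + 1]))
        nmda = assign_receptors(n_i, nmda_fraction, seed=int(child_seeds[3 * i + 2]))
        entries.append(
            SpineBranch(
                branch_index=b.branch_index,
                n=n_i,
                positions=tuple(float(p) for p in pos),
                ampa_flags=tuple(bool(a) for a in ampa),
                nmda_flags=tuple(bool(x) for x in nmda),
            )
        )
    return SpineMap(entries=tuple(entries))
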