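"""Genetic-algorithm tuning of the five biophysical parameters.

The objective M is expensive, so candidates are cached by parameter tuple.
Each generation evaluates the pool, crosses over the best two candidates
(uniform coordinate swap), mutates each coordinate of the two offspring with
a small probability, and replaces the two worst pool members; the pool size
stays constant and the best candidate ever evaluated is tracked separately,
so the returned optimum never degrades.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .estimation import EstimationConfig, estimate_neuron_M
from .morphology import Morphology
from .params import BiophysParams, SurrogateKernels

__all__ = ["GAConfig", "ParameterSpace", "ga_optimize", "optimize_neuron", "BiophysParams"]


@dataclass(frozen=True)
class GAConfig:
    pool_size: int = 100
    iterations: int = 500
    mutation_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 4:
            raise ValueError("pool_size must be >= 4 (best-2 and worst-2 selection)")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class ParameterSpace:
    """Finite grids of the 5-dimensional search space.

    Defaults extend the observed optimum bands modestly: resting potentials
    −85…−75 mV in 1 mV steps, both spine placement schemes, density
    multipliers {0.5, 1, 2} of the wiring-law density, and AMPA/NMDA
    fractions {0.25, 0.5, 0.75, 1}.
    """

    v_rest: tuple[float, ...] = tuple(float(v) for v in range(-85, -74))
    spatial_mode: tuple[str, ...] = ("linspace", "uniform")
    density_setting: tuple[float, ...] = (0.5, 1.0, 2.0)
    ampa_fraction: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    nmda_fraction: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)

    def __post_init__(self) -> None:
        for name in ("v_rest", "spatial_mode", "density_setting", "ampa_fraction", "nmda_fraction"):
            if not getattr(self, name):
                raise ValueError(f"grid {name} must be nonempty")

    def grids(self) -> tuple[tuple, ...]:
        return (
            self.v_rest,
            self.spatial_mode,
            self.density_setting,
            self.ampa_fraction,
            self.nmda_fraction,
        )

    @property
    def size(self) -> int:
        return int(np.prod([len(g) for g in self.grids()]))

    def all_points(self):
        """Iterate every parameter tuple in the grid (for exhaustive search)."""
        return itertools.product(*self.grids())

    def sample(self, rng: np.random.Generator) -> tuple:
        return tuple(g[int(rng.integers(len(g)))] for g in self.grids())

    @staticmethod
    def to_params(point: tuple) -> BiophysParams:
        return BiophysParams(
            v_rest=point[0],
            spatial_mode=point[1],
            density_setting=point[2],
            ampa_fraction=point[3],
            nmda_fraction=point[4],
        )


def ga_optimize(
    objective: Callable[[BiophysParams], float],
    space: ParameterSpace = ParameterSpace(),
    cfg: GAConfig = GAConfig(),
) -> tuple[BiophysParams, float, list[dict]]:
    """Maximise ``objective`` over the finite parameter grid.

    Returns the best parameters ever evaluated, their objective value, and a
    per-iteration history of the pool's best and the running global best.
    Deterministic for a fixed seed; objective values are cached per tuple.
    """
    rng = np.random.default_rng(cfg.seed)
    cache: dict[tuple, float] = {}

    def evaluate(point: tuple) -> float:
        if point not in cache:
            cache[point] = float(objective(ParameterSpace.to_params(point)))
        return cache[point]

    pool = [space.sample(rng) for _ in range(cfg.pool_size)]
    best_point = None
    best_value = -np.inf
    history: list[dict] = []

    for it in range(cfg.iterations):
        values = [evaluate(pt) for pt in pool]
        order = np.argsort(values)  # ascending
        for idx in order:
            if values[idx] > best_value:
                best_value = values[idx]
                best_point = pool[idx]
        p1, p2 = pool[order[-1]], pool[order[-2]]

        # uniform crossover: swap each coordinate with probability 1/2
        c1, c2 = list(p1), list(p2)
        for k in range(5):
            if rng.random() < 0.5:
                c1[k], c2[k] = c2[k], c1[k]
        # per-coordinate mutation: re-draw from the grid
        for child in (c1, c2):
            for k, grid in enumerate(space.grids()):
                if rng.random() < cfg.mutation_prob:
                    child[k] = grid[int(rng.integers(len(grid)))]
        offspring = [tuple(c1), tuple(c2)]

        # offspring replace the two worst, unconditionally
        worst = list(order[:2])
        for w, child in zip(worst, offspring):
            pool[w] = child
        for child in offspring:
            v = evaluate(child)
            if v > best_value:
                best_value = v
                best_point = child
        history.append(
            {
                "iteration": it,
                "pool_best": float(max(values)),
                "global_best": float(best_value),
                "evaluations": len(cache),
            }
        )
    assert best_point is not None
    return ParameterSpace.to_params(best_point), float(best_value), history


def optimize_neuron(
    m: Morphology,
    space: ParameterSpace = ParameterSpace(),
    cfg: GAConfig = GAConfig(),
    est_cfg: EstimationConfig = EstimationConfig(),
    kernels: SurrogateKernels = SurrogateKernels(),
    cell_name: str = "cell",
) -> dict:
    """Select the parameters maximising a neuron's M; one summary record.

    The record mirrors the per-cell summary layout: cell name, resting
    potential, spatial mode (LS/UN), density multiplier, AMPA/NMDA fractions
    and the maximised M.
    """

    def objective(p: BiophysParams) -> float:
        total, _ = estimate_neuron_M(m, p=p, cfg=est_cfg, kernels=kernels)
        return float(total)

    best, best_value, history = ga_optimize(objective, space, cfg)
    return {
        "cell": cell_name,
        "v_rest": best.v_rest,
        "SP": "LS" if best.spatial_mode == "linspace" else "UN",
        "rho": best.density_setting,
        "AMPA": best.ampa_fraction,
        "NMDA": best.nmda_fraction,
        "M": int(round(best_value)),
        "history": history,
    }
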