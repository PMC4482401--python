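"""Stochastic estimation of the discriminable-pattern count M and its law.

The exhaustive pattern space of a branch with n spines and k co-active sites
is C(n, k) and intractable even for tens of spines, so M is estimated by a
plateau search: sample activation patterns in cumulative batches (10, 20,
30, … by default), recount the discriminable waveforms after each batch,
and stop as soon as the discrete derivative of the count is no longer
positive. Across branches M follows the law

    M(neuron) = Σ_i  a · n_i · ln n_i + b

over spiny branches, whose constants (a, b) are fitted by least squares and
compared with linear and quadratic alternatives via adjusted R².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .morphology import Morphology, dissect_branches, morpho_stats
from .params import BiophysParams, SurrogateKernels
from .spines import CuntzParams, build_spine_map, cuntz_spine_count
from .waveforms import ActivationPattern, quantize, surrogate_simulate

__all__ = [
    "EstimationConfig",
    "MLawFit",
    "estimate_branch_M",
    "estimate_neuron_M",
    "mlaw_predict",
    "fit_mlaw",
]


@dataclass(frozen=True)
class EstimationConfig:
    """Plateau-search schedule.

    batch_increment   patterns added per round (cumulative batches)
    k_active          co-active spines per random pattern; None → min(7, n),
                      "uniform-random" → k drawn uniformly in 1..n per pattern
    max_rounds        safeguard against non-terminating growth
    seed              RNG seed for pattern sampling
    d                 discriminability sample threshold
    """

    batch_increment: int = 10
    k_active: int | str | None = None
    max_rounds: int = 100
    seed: int = 0
    d: int = 400

    def __post_init__(self) -> None:
        if self.batch_increment < 1:
            raise ValueError("batch_increment must be >= 1")
        if self.max_rounds < 2:
            raise ValueError("max_rounds must be >= 2 (a derivative needs two rounds)")


class _GrowingDisjointSet:
    """Union-find over an index set that grows one element at a time."""

    def __init__(self) -> None:
        self.parent: list[int] = []
        self.size: list[int] = []
        self.n_components = 0

    def add(self) -> int:
        idx = len(self.parent)
        self.parent.append(idx)
        self.size.append(1)
        self.n_components += 1
        return idx

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.n_components -= 1


def _draw_pattern(rng: np.random.Generator, n_spines: int, k_active) -> tuple[int, ...]:
    if k_active == "uniform-random":
        k = int(rng.integers(1, n_spines + 1))
    elif k_active is None:
        k = min(7, n_spines)
    else:
        k = min(int(k_active), n_spines)
    return tuple(sorted(int(i) for i in rng.choice(n_spines, size=k, replace=False)))


def estimate_branch_M(
    simulator: Callable[[tuple[int, ...]], np.ndarray],
    n_spines: int,
    cfg: EstimationConfig = EstimationConfig(),
) -> tuple[int, list[int]]:
    """Plateau-search estimate of a branch's discriminable-pattern count.

    ``simulator`` maps a tuple of active spine indices to a somatic voltage
    trace. Patterns accumulate across rounds, so the per-round count trace
    is non-decreasing; the search stops once a round adds no new
    discriminable waveform (discrete derivative <= 0) or at ``max_rounds``.
    Returns the maximum observed count and the per-round trace.
    """
    if n_spines < 1:
        raise ValueError("n_spines must be >= 1")
    rng = np.random.default_rng(cfg.seed)

    # Patterns only accumulate, so pairwise dissimilarities never change:
    # each new waveform is compared once against all earlier ones and the
    # union-find structure grows incrementally round by round.
    buf: np.ndarray | None = None  # capacity-doubling store of quantized rows
    n_rows = 0
    dsu = _GrowingDisjointSet()
    trace: list[int] = []
    prev_m: int | None = None
    for _ in range(cfg.max_rounds):
        for _ in range(cfg.batch_increment):
            pat = _draw_pattern(rng, n_spines, cfg.k_active)
            q = quantize(np.asarray(simulator(pat), dtype=float))
            if buf is None:
                buf = np.empty((4 * cfg.batch_increment, q.shape[0]))
            elif n_rows == buf.shape[0]:
                buf = np.concatenate([buf, np.empty_like(buf)], axis=0)
            idx = dsu.add()
            if n_rows:
                diffs = np.count_nonzero(buf[:n_rows] != q, axis=1)
                for j in np.nonzero(diffs < cfg.d)[0]:
                    dsu.union(idx, int(j))
            buf[n_rows] = q
            n_rows += 1
        m = dsu.n_components
        trace.append(m)
        if prev_m is not None and m - prev_m <= 0:
            break
        prev_m = m
    return max(trace), trace


def estimate_neuron_M(
    m: Morphology,
    p: BiophysParams = BiophysParams(),
    cfg: EstimationConfig = EstimationConfig(),
    cuntz: CuntzParams | None = None,
    kernels: SurrogateKernels = SurrogateKernels(),
    max_branches: int | None = None,
    progress: Callable[[int, int, int], None] | None = None,
) -> tuple[int, list[dict]]:
    """Whole-neuron M: the sum of per-branch plateau estimates.

    Spine counts follow the wiring law under ``p.density_setting``; spines
    are placed per ``p.spatial_mode`` and receptor-flagged per the AMPA/NMDA
    fractions. Branches without spines contribute 0. Every branch uses the
    same estimation seed, so identical branches yield identical estimates.
    Returns (M_total, per-branch records with branch_index, n_i, M).
    """
    if cuntz is None:
        cuntz = CuntzParams(density_multiplier=p.density_setting)
    else:
        cuntz = CuntzParams(c=cuntz.c, density_multiplier=p.density_setting)
    branches = dissect_branches(m)
    stats = morpho_stats(m)
    n_total = cuntz_spine_count(stats.total_length, stats.total_volume, cuntz)
    smap = build_spine_map(
        branches,
        n_total,
        spatial_mode=p.spatial_mode,
        ampa_fraction=p.ampa_fraction,
        nmda_fraction=p.nmda_fraction,
        seed=cfg.seed,
    )
    by_index = {b.branch_index: b for b in branches}
    per_branch: list[dict] = []
    total = 0
    entries = smap.entries if max_branches is None else smap.entries[:max_branches]
    for entry in entries:
        if entry.n == 0:
            per_branch.append({"branch_index": entry.branch_index, "n_i": 0, "M": 0})
            continue
        branch = by_index[entry.branch_index]

        def simulator(pattern: tuple[int, ...]) -> np.ndarray:
            return surrogate_simulate(
                branch,
                entry,
                ActivationPattern(branch_index=entry.branch_index, active_spines=pattern),
                p=p,
                kernels=kernels,
            )

        m_b, _ = estimate_branch_M(simulator, entry.n, cfg)
        per_branch.append({"branch_index": entry.branch_index, "n_i": entry.n, "M": m_b})
        total += m_b
        if progress is not None:
            progress(entry.branch_index, entry.n, m_b)
    return total, per_branch


@dataclass(frozen=True)
class MLawFit:
    """Fitted constants of a per-branch M law and its adjusted R²."""

    a: float
    b: float
    adj_r2: float
    model_tag: str
    coefficients: tuple[float, ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model_tag,
                "a": self.a,
                "b": self.b,
                "adj_r2": self.adj_r2,
                "coefficients": list(self.coefficients),
            }
        )


def mlaw_predict(spine_counts: Sequence[float], a: float, b: float) -> float:
    """Σ_i (a·n_i·ln n_i + b) over branches, with n_i = 0 contributing 0.

    A spineless branch cannot discriminate any pattern, so it adds nothing
    (not even the intercept b).
    """
    total = 0.0
    for n in spine_counts:
        if n < 0:
            raise ValueError("spine counts must be >= 0")
        if n == 0:
            continue
        total += a * n * np.log(n) + b
    return float(total)


def _design(n: np.ndarray, model_tag: str) -> np.ndarray:
    if model_tag == "nlogn":
        return np.column_stack([n * np.log(n), np.ones_like(n)])
    if model_tag == "linear":
        return np.column_stack([n, np.ones_like(n)])
    if model_tag == "quadratic":
        return np.column_stack([n**2, n, np.ones_like(n)])
    raise ValueError(f"unknown model_tag {model_tag!r}")


def fit_mlaw(samples: Sequence[tuple[float, float]], model_tag: str = "nlogn") -> MLawFit:
    """Least-squares fit of a per-branch law M(n) and its adjusted R².

    Supported models: ``nlogn`` (a·n·ln n + b), ``linear`` (a·n + b) and
    ``quadratic`` (a·n² + b·n + c). Adjusted R² = 1 − (1−R²)(N−1)/(N−p−1)
    with p the number of coefficients excluding the intercept.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (n, M) samples")
    n, M = arr[:, 0], arr[:, 1]
    if (n < 1).any():
        raise ValueError("spine counts must be >= 1 for fitting")
    if np.allclose(n, n[0]):
        raise ValueError("degenerate design: all spine counts equal")
    X = _design(n, model_tag)
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    resid = M - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((M - M.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n_obs = len(M)
    p = X.shape[1] - 1
    adj_r2 = 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - p - 1)
    if model_tag == "quadratic":
        a, b = float(coef[0]), float(coef[2])
    else:
        a, b = float(coef[0]), float(coef[1])
    return MLawFit(
        a=a, b=b, adj_r2=float(adj_r2), model_tag=model_tag, coefficients=tuple(float(c) for c in coef)
    )
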