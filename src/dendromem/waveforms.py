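"""Somatic waveform generation, quantization and discriminability counting.

Two equal-length quantized voltage traces are *discriminable* when they
differ in at least ``d`` sample points. The number of discriminable
waveforms in a set is the number of connected components of the similarity
graph whose edges join NON-discriminable pairs; components are found with a
disjoint-set (union-find) structure using the union-by-size heuristic.

Defaults match a 200 ms recording at dt = 25 μs (8000 samples), a 10 μV
quantization (truncation to two decimal digits of mV) and d = 400 samples
(a 10 ms window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .params import BiophysParams, SurrogateKernels
from .spines import SpineBranch

__all__ = [
    "WaveformSet",
    "DiscriminabilityConfig",
    "ActivationPattern",
    "quantize",
    "n_differing",
    "is_discriminable",
    "count_discriminable",
    "surrogate_simulate",
    "gen_waveform_templates",
    "write_waveforms_csv",
    "read_waveforms_csv",
    "DEFAULT_DT_MS",
    "DEFAULT_DURATION_MS",
]

log = logging.getLogger(__name__)

DEFAULT_DT_MS = 0.025  # 25 μs
DEFAULT_DURATION_MS = 200.0
DEFAULT_RELEASE_MS = 50.0
QUANTIZATION_STEP_MV = 0.01  # 10 μV


@dataclass
class WaveformSet:
    """Matrix of somatic voltage traces (mV), one waveform per row."""

    values: np.ndarray
    dt: float = DEFAULT_DT_MS
    duration: float = DEFAULT_DURATION_MS

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n_expected = int(round(self.duration / self.dt))
        if self.values.size and self.values.shape[1] != n_expected:
            raise ValueError(
                f"waveform length {self.values.shape[1]} != duration/dt = {n_expected}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_waveforms(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DiscriminabilityConfig:
    """Sample-count threshold d: pairs differing in >= d samples are
    discriminable. d = 400 is a 10 ms window at dt = 25 μs."""

    d: int = 400

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")


@dataclass(frozen=True)
class ActivationPattern:
    """A coincident activation of a subset of one branch's spines."""

    branch_index: int
    active_spines: tuple[int, ...]
    release_time: float = DEFAULT_RELEASE_MS


def quantize(w: np.ndarray) -> np.ndarray:
    """Truncate voltages (toward zero) to two decimal digits of mV.

    This models a 10 μV recording-noise floor. Values already on the 0.01 mV
    grid but stored with binary representation error are snapped to the grid
    first so that e.g. 8.06 does not truncate to 8.05.
    """
    w = np.asarray(w, dtype=float)
    scaled = w * 100.0
    nearest = np.round(scaled)
    scaled = np.where(np.abs(scaled - nearest) < 1e-6, nearest, scaled)
    return np.trunc(scaled) / 100.0


def n_differing(w: np.ndarray, z: np.ndarray) -> int:
    """Number of sample points where two quantized waveforms differ."""
    w = np.asarray(w)
    z = np.asarray(z)
    if w.shape != z.shape:
        raise ValueError(f"length mismatch: {w.shape} vs {z.shape}")
    return int(np.count_nonzero(w != z))


def is_discriminable(
    w: np.ndarray, z: np.ndarray, cfg: DiscriminabilityConfig = DiscriminabilityConfig()
) -> bool:
    """True iff the quantized traces differ in at least ``cfg.d`` samples."""
    return n_differing(w, z) >= cfg.d


class _DisjointSet:
    """Union-find with union by size and path compression."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n

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


def _pairwise_differing(values: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise differing-sample counts."""
    n = values.shape[0]
    diff = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        counts = np.count_nonzero(values[i + 1 :] != values[i], axis=1)
        diff[i, i + 1 :] = counts
        diff[i + 1 :, i] = counts
    return diff


def count_discriminable(
    ws: WaveformSet, cfg: DiscriminabilityConfig = DiscriminabilityConfig()
) -> tuple[int, np.ndarray]:
    """Number of discriminable waveforms M and per-waveform component labels.

    Builds the similarity graph (edge ⇔ the pair is NOT discriminable) over
    the quantized traces and counts its connected components with a
    disjoint-set structure. Labels are component ids ordered by each
    component's lowest waveform index. If a component is not a clique —
    i.e. some intra-component pairs are discriminable, so the similarity
    relation was not transitive — a warning reports the offending pair
    fraction.
    """
    if ws.n_waveforms == 0:
        return 0, np.empty(0, dtype=int)
    q = quantize(ws.values)
    n = q.shape[0]
    diff = _pairwise_differing(q)
    similar = diff < cfg.d

    dsu = _DisjointSet(n)
    ii, jj = np.nonzero(np.triu(similar, k=1))
    for i, j in zip(ii, jj):
        dsu.union(int(i), int(j))

    roots = [dsu.find(i) for i in range(n)]
    # component id ordered by lowest member index (the representative)
    rep_order: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in rep_order:
            rep_order[r] = len(rep_order)
    labels = np.array([rep_order[r] for r in roots], dtype=int)
    m = len(rep_order)

    # non-transitivity diagnostic: components need not be cliques
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    intra_mask = (labels[:, None] == labels[None, :]) & upper
    intra = int(np.count_nonzero(intra_mask))
    intra_discr = int(np.count_nonzero(intra_mask & ~similar))
    if intra_discr:
        log.warning(
            "similarity is not transitive: %d/%d intra-component pairs are discriminable",
            intra_discr,
            intra,
        )
    return m, labels


def _dexp_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak double-exponential kernel, zero for t < 0."""
    g = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay) - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return g / peak


def surrogate_simulate(
    branch,
    spines: SpineBranch,
    pattern: ActivationPattern,
    p: BiophysParams = BiophysParams(),
    kernels: SurrogateKernels = SurrogateKernels(),
    dt: float = DEFAULT_DT_MS,
    duration: float = DEFAULT_DURATION_MS,
) -> np.ndarray:
    """Deterministic somatic-EPSP surrogate for one activation pattern.

    The trace sits at ``p.v_rest`` before ``pattern.release_time``; each
    active spine then contributes an AMPA and/or NMDA double-exponential
    kernel attenuated by exp(−x_s/λ) for its arc-length distance x_s from
    the branch root. The NMDA amplitude is multiplied by a sigmoid of the
    number of co-active NMDA spines within ``kernels.cluster_window`` μm
    (the supralinear clustering effect) and by a voltage gain that is
    bell-shaped in the resting potential: hyperpolarising a cell from −75 mV
    raises the NMDA gain up to its peak near ``kernels.v_opt``, so
    moderately hyperpolarised cells discriminate more patterns.

    The summed AMPA and NMDA drives reach the soma in steps of
    ``kernels.drive_resolution`` mV, reflecting the stereotyped, near
    all-or-none character of dendritic output: a branch therefore has a
    finite somatic-waveform repertoire, which is what makes its
    discriminable-pattern count a well-defined finite quantity.
    """
    n_samples = int(round(duration / dt))
    if pattern.release_time >= duration:
        raise ValueError("release_time must precede the end of the recording")
    for idx in pattern.active_spines:
        if idx < 0 or idx >= spines.n:
            raise ValueError(f"spine index {idx} outside branch with {spines.n} spines")

    t = np.arange(n_samples) * dt - pattern.release_time
    v = np.full(n_samples, float(p.v_rest))
    if not pattern.active_spines:
        return v

    active = sorted(set(pattern.active_spines))
    pos = np.array([spines.positions[i] for i in active])
    nmda_active = np.array([spines.nmda_flags[i] for i in active])
    nmda_pos = pos[nmda_active]

    v_gain = 1.0 + kernels.hyper_gain * float(
        np.exp(-(((p.v_rest - kernels.v_opt) / kernels.v_sigma) ** 2))
    )

    drive_ampa = 0.0
    drive_nmda = 0.0
    for i, x_s in zip(active, pos):
        atten = float(np.exp(-x_s / kernels.lambda_atten))
        if spines.ampa_flags[i]:
            drive_ampa += kernels.amp_ampa * atten
        if spines.nmda_flags[i]:
            k_local = int(np.count_nonzero(np.abs(nmda_pos - x_s) <= kernels.cluster_window))
            sig = 1.0 / (
                1.0 + np.exp(-(k_local - kernels.cluster_threshold) / kernels.cluster_slope)
            )
            boost = 1.0 + kernels.cluster_boost * sig
            drive_nmda += kernels.amp_nmda * atten * v_gain * boost

    step = kernels.drive_resolution
    if step > 0:
        drive_ampa = round(drive_ampa / step) * step
        drive_nmda = round(drive_nmda / step) * step
    if drive_ampa:
        v += drive_ampa * _dexp_kernel(t, kernels.tau_rise_ampa, kernels.tau_decay_ampa)
    if drive_nmda:
        v += drive_nmda * _dexp_kernel(t, kernels.tau_rise_nmda, kernels.tau_decay_nmda)
    return v


def gen_waveform_templates(
    n_templates: int,
    n_per_template: int,
    separation: int = 4000,
    noise_amplitude: float = 0.004,
    seed: int = 0,
    d: int = 400,
    dt: float = DEFAULT_DT_MS,
    duration: float = DEFAULT_DURATION_MS,
) -> WaveformSet:
    """Synthetic waveform set with a known discriminable-count ground truth.

    Builds ``n_templates`` EPSP-shaped template traces that pairwise differ
    in at least ``separation`` samples, then emits ``n_per_template`` noisy
    copies of each. Template values sit at quantization-cell centres and the
    noise stays below half a cell (10 μV cells), so copies of one template
    are identical after quantization while distinct templates remain
    discriminable: the set's discriminable count equals ``n_templates``.
    """
    if separation < d:
        raise ValueError("separation must be >= d")
    if not 0.0 <= noise_amplitude < QUANTIZATION_STEP_MV / 2:
        raise ValueError("noise_amplitude must stay below half a quantization cell")
    if n_templates < 1 or n_per_template < 1:
        raise ValueError("need at least one template and one copy")

    rng = np.random.default_rng(seed)
    n_samples = int(round(duration / dt))
    t = np.arange(n_samples) * dt - DEFAULT_RELEASE_MS
    base = _dexp_kernel(t, 3.0, 60.0)

    templates = []
    for j in range(n_templates):
        amp = 2.0 + 1.5 * j  # mV; well-separated peak amplitudes
        tr = -80.0 + amp * base
        # snap to quantization-cell centres: k*0.01 + 0.005
        tr = np.trunc(tr * 100.0) / 100.0 + 0.005
        templates.append(tr)
    for a in range(n_templates):
        for b in range(a + 1, n_templates):
            sep = n_differing(quantize(templates[a]), quantize(templates[b]))
            if sep < separation:
                raise ValueError(
                    f"templates {a},{b} differ in only {sep} samples (< {separation}); "
                    "reduce separation or n_templates"
                )
    rows = []
    for tr in templates:
        for _ in range(n_per_template):
            rows.append(tr + rng.uniform(-noise_amplitude, noise_amplitude, size=n_samples))
    return WaveformSet(values=np.array(rows), dt=dt, duration=duration)


def write_waveforms_csv(ws: WaveformSet, path) -> None:
    """One waveform per row; header records dt and duration (ms)."""
    with open(path, "w") as fh:
        fh.write(f"# dt_ms={ws.dt} duration_ms={ws.duration}\n")
        np.savetxt(fh, ws.values, fmt="%.6f", delimiter=",")


def read_waveforms_csv(path) -> WaveformSet:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        values = np.loadtxt(fh, delimiter=",", ndmin=2)
    return WaveformSet(
        values=values, dt=float(meta["dt_ms"]), duration=float(meta["duration_ms"])
    )
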