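"""SWC morphology handling: parsing, branch dissection, morphometry, synthesis.

The unit conventions follow the SWC standard: coordinates and radii in
micrometres. Dendritic accounting (total length L, total volume V, branch
counts) excludes soma (structure code 1) and axon (structure code 2)
compartments; the scaling law that sets spine counts operates on dendritic
wiring only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Morphology",
    "Branch",
    "MorphoStats",
    "SWCError",
    "read_swc",
    "write_swc",
    "dissect_branches",
    "morpho_stats",
    "gen_synthetic_morphology",
    "gen_mouse_like_cells",
    "export_neuron_bundle",
]

#: SWC structure codes excluded from dendritic length/volume accounting.
NON_DENDRITIC_CODES = frozenset({1, 2})

SWC_COLUMNS = ["id", "structure", "x", "y", "z", "radius", "parent"]


class SWCError(ValueError):
    """Raised for malformed or structurally invalid SWC content."""


@dataclass
class Morphology:
    """A rooted neuronal reconstruction.

    ``nodes`` is a DataFrame with the seven SWC columns; ``parent`` is -1 for
    the root. Exactly one root is allowed, ids are unique, radii positive and
    the parent relation is acyclic (guaranteed by the validating constructors).
    """

    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_nodes(self.nodes)
        self.nodes = self.nodes.reset_index(drop=True)

    @property
    def root_id(self) -> int:
        return int(self.nodes.loc[self.nodes["parent"] == -1, "id"].iloc[0])

    def children_map(self) -> dict[int, list[int]]:
        """Map node id -> list of child ids, in file order."""
        cm: dict[int, list[int]] = {int(i): [] for i in self.nodes["id"]}
        for nid, pid in zip(self.nodes["id"], self.nodes["parent"]):
            if pid != -1:
                cm[int(pid)].append(int(nid))
        return cm

    def node_lookup(self) -> dict[int, tuple[float, float, float, float, int]]:
        """Map node id -> (x, y, z, radius, structure)."""
        return {
            int(r.id): (float(r.x), float(r.y), float(r.z), float(r.radius), int(r.structure))
            for r in self.nodes.itertuples()
        }


@dataclass(frozen=True)
class Branch:
    """A maximal unbranched path between root / branch points / terminals.

    ``node_path`` runs from the upstream endpoint (root or branch point) to
    the downstream endpoint (branch point or terminal). ``length`` and
    ``volume`` sum only dendritic edges (child node not soma/axon).
    """

    node_path: tuple[int, ...]
    length: float
    volume: float
    branch_index: int


@dataclass(frozen=True)
class MorphoStats:
    total_length: float  # μm, dendritic
    total_volume: float  # μm³, dendritic
    n_branches: int
    n_branch_points: int


def _validate_nodes(nodes: pd.DataFrame) -> None:
    if list(nodes.columns) != SWC_COLUMNS:
        raise SWCError(f"expected columns {SWC_COLUMNS}, got {list(nodes.columns)}")
    if nodes.empty:
        raise SWCError("empty morphology")
    ids = nodes["id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise SWCError("duplicate node ids")
    roots = nodes.loc[nodes["parent"] == -1]
    if len(roots) != 1:
        raise SWCError(f"expected exactly one root, found {len(roots)}")
    idset = set(int(i) for i in ids)
    for nid, pid in zip(nodes["id"], nodes["parent"]):
        if pid != -1 and int(pid) not in idset:
            raise SWCError(f"node {int(nid)} references missing parent {int(pid)}")
    if (nodes["radius"] <= 0).any():
        raise SWCError("non-positive radius")
    _check_acyclic(nodes)


def _check_acyclic(nodes: pd.DataFrame) -> None:
    parent = {int(i): int(p) for i, p in zip(nodes["id"], nodes["parent"])}
    seen_ok: set[int] = set()
    for start in parent:
        path = []
        cur = start
        while cur != -1 and cur not in seen_ok:
            path.append(cur)
            cur = parent[cur]
            if cur in path:
                raise SWCError(f"cycle detected through node {cur}")
        seen_ok.update(path)


def read_swc(path: str | Path) -> Morphology:
    """Parse a 7-column SWC file (``#`` comment lines allowed).

    Raises :class:`SWCError` with the offending line number for malformed
    rows, and for structural problems (dangling parents, multiple roots,
    cycles, non-positive radii).
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 7:
                raise SWCError(f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                rows.append(
                    (
                        int(parts[0]),
                        int(parts[1]),
                        float(parts[2]),
                        float(parts[3]),
                        float(parts[4]),
                        float(parts[5]),
                        int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SWCError(f"{path.name}:{lineno}: {exc}") from exc
    if not rows:
        raise SWCError(f"{path.name}: no data lines")
    nodes = pd.DataFrame(rows, columns=SWC_COLUMNS)
    return Morphology(nodes)


def write_swc(m: Morphology, path: str | Path, header: str | None = None) -> None:
    """Write ``m`` as standard SWC with 6-decimal coordinates and radii."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for r in m.nodes.itertuples():
            fh.write(
                f"{int(r.id)} {int(r.structure)} {r.x:.6f} {r.y:.6f} {r.z:.6f} "
                f"{r.radius:.6f} {int(r.parent)}\n"
            )


def _edge_metrics(
    lut: dict[int, tuple[float, float, float, float, int]], parent_id: int, child_id: int
) -> tuple[float, float, bool]:
    """Length, frustum volume and dendritic flag of the edge parent->child.

    An edge is dendritic when its child node is neither soma nor axon, so a
    stem edge leaving the soma counts towards the dendrite.
    """
    x1, y1, z1, r1, _ = lut[parent_id]
    x2, y2, z2, r2, s2 = lut[child_id]
    h = math.dist((x1, y1, z1), (x2, y2, z2))
    vol = math.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
    return h, vol, s2 not in NON_DENDRITIC_CODES


def dissect_branches(m: Morphology) -> list[Branch]:
    """Split the tree into maximal unbranched paths.

    Endpoints are the root, nodes with two or more (non-axon) children, and
    terminals. Axon subtrees are pruned before dissection; branches whose
    edges are all somatic (e.g. multi-point soma stubs) are dropped. Every
    dendritic edge belongs to exactly one returned branch.
    """
    lut = m.node_lookup()
    cm_full = m.children_map()
    # prune axon subtrees
    cm: dict[int, list[int]] = {}
    keep: set[int] = set()
    stack = [m.root_id]
    while stack:
        nid = stack.pop()
        keep.add(nid)
        kids = [c for c in cm_full[nid] if lut[c][4] != 2]
        cm[nid] = kids
        stack.extend(kids)

    root = m.root_id
    endpoints = {root}
    for nid in keep:
        if len(cm[nid]) >= 2:
            endpoints.add(nid)
        elif len(cm[nid]) == 0:
            endpoints.add(nid)

    branches: list[Branch] = []
    # walk down from every endpoint through single-child runs
    order = sorted(endpoints)
    for start in order:
        for child in cm[start]:
            path = [start, child]
            while child not in endpoints:
                child = cm[child][0]
                path.append(child)
            length = 0.0
            volume = 0.0
            dendritic = False
            for a, b in zip(path[:-1], path[1:]):
                h, v, is_dend = _edge_metrics(lut, a, b)
                if is_dend:
                    length += h
                    volume += v
                    dendritic = True
            if dendritic:
                branches.append(
                    Branch(
                        node_path=tuple(path),
                        length=length,
                        volume=volume,
                        branch_index=len(branches),
                    )
                )
    return branches


def morpho_stats(m: Morphology) -> MorphoStats:
    """Dendritic total length, total volume and branch counts.

    Lengths are Euclidean parent–child distances; volumes are conical
    frustums π·h·(r₁² + r₁r₂ + r₂²)/3 per edge. Soma and axon edges are
    excluded throughout.
    """
    branches = dissect_branches(m)
    total_length = sum(b.length for b in branches)
    total_volume = sum(b.volume for b in branches)
    starts = [b.node_path[0] for b in branches]
    n_branch_points = sum(1 for nid in set(starts) if starts.count(nid) >= 2)
    return MorphoStats(
        total_length=total_length,
        total_volume=total_volume,
        n_branches=len(branches),
        n_branch_points=n_branch_points,
    )


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def gen_synthetic_morphology(
    n_branch_points: int,
    mean_branch_length: float = 60.0,
    radius_range: tuple[float, float] = (0.3, 1.0),
    seed: int = 0,
    nodes_per_branch: int = 5,
) -> Morphology:
    """Random binary dendritic tree with exactly ``n_branch_points`` bifurcations.

    The tree has a single soma root (structure code 1) and 2·p+1 dendritic
    branches for p bifurcations. Branch lengths are drawn from a normal
    distribution around ``mean_branch_length`` (σ = 25 % of the mean, clipped
    at 20 % of the mean); radii taper geometrically with branch depth from
    ``radius_range[1]`` down to ``radius_range[0]``. Deterministic for a
    fixed seed, and writable as valid SWC.
    """
    if n_branch_points < 0:
        raise ValueError("n_branch_points must be >= 0")
    if mean_branch_length <= 0:
        raise ValueError("mean_branch_length must be > 0")
    r_min, r_max = radius_range
    if not (0 < r_min <= r_max):
        raise ValueError("radius_range must satisfy 0 < min <= max")
    rng = np.random.default_rng(seed)

    rows: list[tuple[int, int, float, float, float, float, int]] = []
    soma_radius = max(5.0, 2 * r_max)
    rows.append((1, 1, 0.0, 0.0, 0.0, soma_radius, -1))
    next_id = 2

    def branch_radius(depth: int) -> float:
        return max(r_min, r_max * 0.8**depth)

    def grow_branch(parent_id: int, origin: np.ndarray, direction: np.ndarray, depth: int):
        nonlocal next_id
        length = float(
            np.clip(
                rng.normal(mean_branch_length, 0.25 * mean_branch_length),
                0.2 * mean_branch_length,
                None,
            )
        )
        seg = length / nodes_per_branch
        pos = origin.copy()
        d = direction.copy()
        rad = branch_radius(depth)
        pid = parent_id
        for _ in range(nodes_per_branch):
            d = _unit(d + rng.normal(scale=0.15, size=3))
            pos = pos + seg * d
            rows.append((next_id, 3, float(pos[0]), float(pos[1]), float(pos[2]), rad, pid))
            pid = next_id
            next_id += 1
        return pid, pos, d

    # stem
    stem_dir = _unit(rng.normal(size=3))
    tip_id, tip_pos, tip_dir = grow_branch(1, np.zeros(3), stem_dir, depth=0)
    tips = [(tip_id, tip_pos, tip_dir, 0)]

    for _ in range(n_branch_points):
        idx = int(rng.integers(len(tips)))
        pid, pos, d, depth = tips.pop(idx)
        for sign in (+1.0, -1.0):
            perp = _unit(np.cross(d, rng.normal(size=3)))
            child_dir = _unit(d + 0.8 * sign * perp)
            cid, cpos, cdir = grow_branch(pid, pos, child_dir, depth + 1)
            tips.append((cid, cpos, cdir, depth + 1))

    nodes = pd.DataFrame(rows, columns=SWC_COLUMNS)
    return Morphology(nodes)


def gen_mouse_like_cells(n_cells: int = 12, seed: int = 20150623) -> list[Morphology]:
    """Packaged mouse-cortical-like synthetic fixture suite.

    Emulates the gross morphometry of mouse cortical pyramidal/stellate
    dendrites: 15–40 bifurcations, mean branch lengths 40–90 μm (total
    dendritic length a few millimetres) and dendritic radii 0.4–0.8 μm.
    Used to calibrate the scaling-law constant to a plausible mean spine
    density.
    """
    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(n_cells):
        p = int(rng.integers(15, 41))
        mean_len = float(rng.uniform(40.0, 90.0))
        cells.append(
            gen_synthetic_morphology(
                n_branch_points=p,
                mean_branch_length=mean_len,
                radius_range=(0.4, 0.8),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return cells


def export_neuron_bundle(m: Morphology, spine_map, params, out_dir: str | Path) -> list[Path]:
    """Write the NEURON input-file bundle for an external biophysical run.

    Produces ``neuron_reconstruction.hoc`` (geometry), ``biophysical_model.hoc``
    (passive membrane + resting potential), ``synapses_specs.hoc`` (receptor
    kinetics) and ``synapses_locs.dat`` (one synapse per line: branch index,
    arc-length position normalised to branch length, AMPA flag, NMDA flag).
    Returns the list of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    branches = dissect_branches(m)
    by_index = {b.branch_index: b for b in branches}
    lut = m.node_lookup()

    geo = out_dir / "neuron_reconstruction.hoc"
    with open(geo, "w") as fh:
        fh.write("// neuron geometry exported from SWC\n")
        fh.write(f"create soma, dend[{max(len(branches), 1)}]\n")
        fh.write("soma { pt3dclear() pt3dadd(0, 0, 0, 1) }\n")
        for b in branches:
            fh.write(f"dend[{b.branch_index}] {{ pt3dclear()\n")
            for nid in b.node_path:
                x, y, z, r, _ = lut[nid]
                fh.write(f"  pt3dadd({x:.6f}, {y:.6f}, {z:.6f}, {2 * r:.6f})\n")
            fh.write("}\n")

    bio = out_dir / "biophysical_model.hoc"
    with open(bio, "w") as fh:
        fh.write("// passive membrane and resting potential\n")
        v_rest = getattr(params, "v_rest", -80.0)
        fh.write(f"v_init = {v_rest:.1f}\n")
        fh.write("forall { insert pas  g_pas = 1e-4  e_pas = v_init  cm = 1  Ra = 150 }\n")

    specs = out_dir / "synapses_specs.hoc"
    with open(specs, "w") as fh:
        fh.write("// synaptic receptor kinetics (AMPA fast, NMDA slow)\n")
        fh.write("ampa_tau_rise = 0.5\nampa_tau_decay = 5.0\n")
        fh.write("nmda_tau_rise = 3.0\nnmda_tau_decay = 60.0\n")

    locs = out_dir / "synapses_locs.dat"
    with open(locs, "w") as fh:
        for entry in getattr(spine_map, "entries", []):
            b = by_index[entry.branch_index]
            for pos, a, n in zip(entry.positions, entry.ampa_flags, entry.nmda_flags):
                frac = pos / b.length if b.length > 0 else 0.0
                fh.write(f"{entry.branch_index} {frac:.6f} {int(a)} {int(n)}\n")

    return [geo, bio, specs, locs]
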