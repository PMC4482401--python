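import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

from dendromem.morphology import (
    Morphology,
    dissect_branches,
    gen_synthetic_morphology,
)


@pytest.fixture
def chain_swc(tmp_path):
    """Minimal 3-node SWC: soma root -> dendrite -> dendrite."""
    path = tmp_path / "chain.swc"
    path.write_text(
        "# minimal chain\n"
        "1 1 0 0 0 5 -1\n"
        "2 3 0 0 10 1 1\n"
        "3 3 0 0 20 1 2\n"
    )
    return path


@pytest.fixture
def bifurcation_swc(tmp_path):
    """Soma, stem of 2 nodes, then a bifurcation into two 2-node daughters."""
    path = tmp_path / "bif.swc"
    path.write_text(
        "1 1 0 0 0 5 -1\n"
        "2 3 0 0 10 1 1\n"
        "3 3 0 0 20 1 2\n"
        "4 3 5 0 25 1 3\n"
        "5 3 10 0 30 1 4\n"
        "6 3 -5 0 25 1 3\n"
        "7 3 -10 0 30 1 6\n"
    )
    return path


@pytest.fixture
def small_neuron():
    """A 2-bifurcation (5-branch) synthetic neuron for pipeline tests."""
    return gen_synthetic_morphology(2, mean_branch_length=40.0, seed=11)


def bfs_grouping_oracle(values: np.ndarray, d: int) -> int:
    """Independent brute-force grouping: BFS over the similarity graph.

    Similarity = fewer than d differing samples, counted with a plain
    python loop; no shared code with the union-find implementation.
    """
    n = len(values)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            ndiff = sum(1 for a, b in zip(values[i], values[j]) if a != b)
            if ndiff < d:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    components = 0
    for start in range(n):
        if seen[start]:
            continue
        components += 1
        queue = [start]
        seen[start] = True
        while queue:
            node = queue.pop()
            for nb in adj[node]:
                if not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
    return components
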