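"""Spine counts from the optimal-wiring scaling law.

The law L = c·n^{2/3}·V^{1/3} links total dendritic length, synapse count
and volume; inverting it predicts how many spines a dendrite should carry.
Spines are then split over branches proportionally to branch length and
placed equidistantly.
"""

from dendromem import (
    CuntzParams,
    allocate_spines,
    cuntz_spine_count,
    dissect_branches,
    gen_synthetic_morphology,
    morpho_stats,
    place_spines,
)

m = gen_synthetic_morphology(n_branch_points=5, seed=1)
branches = dissect_branches(m)
s = morpho_stats(m)

n = cuntz_spine_count(s.total_length, s.total_volume, CuntzParams())
print(f"L = {s.total_length:.0f} um, V = {s.total_volume:.0f} um^3")
print(f"predicted spine count n = {n}  (density {n / s.total_length:.2f} /um)")
# mouse cortical densities are reported between 0.5 and 2.1 spines/um

counts = allocate_spines(n, branches)
print(f"per-branch allocation (sums to {sum(counts)}):")
for b, n_i in zip(branches[:3], counts[:3]):
    pos = place_spines(b.length, n_i, mode="linspace")
    spacing = pos[1] - pos[0] if n_i > 1 else float("nan")
    print(f"  branch {b.branch_index}: l_b = {b.length:5.1f} um, "
          f"n_i = {n_i:3d}, equidistant spacing {spacing:.2f} um")
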