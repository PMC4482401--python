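"""Genetic-algorithm selection of the five biophysical parameters.

The GA searches resting potential, spine placement scheme, density
multiplier and AMPA/NMDA fractions for the combination that maximises a
neuron's discriminable-pattern count, here on a deliberately small grid so
the run finishes in seconds.
"""

import logging

from dendromem import (
    EstimationConfig,
    GAConfig,
    ParameterSpace,
    gen_synthetic_morphology,
    optimize_neuron,
)

logging.getLogger("dendromem.waveforms").setLevel(logging.ERROR)

m = gen_synthetic_morphology(n_branch_points=1, mean_branch_length=30.0, seed=2)
space = ParameterSpace(
    v_rest=(-82.0, -80.0, -78.0),
    spatial_mode=("linspace",),
    density_setting=(0.5, 1.0),
    ampa_fraction=(1.0,),
    nmda_fraction=(0.5, 1.0),
)
record = optimize_neuron(
    m,
    space,
    GAConfig(pool_size=6, iterations=8, seed=0),
    EstimationConfig(seed=0, max_rounds=10),
    cell_name="synthetic-1",
)
record.pop("history")
print("best parameter row (cell, v_rest, SP, rho, AMPA, NMDA, M):")
print(record)
# LS = equidistant spine placement, rho = density multiplier of the wiring
# law; M is the maximised discriminable-pattern count.
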