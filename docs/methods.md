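# Methods

## Scope and model

`dendromem` estimates the number of coincident synaptic input patterns (M)
a neuron can discriminate through its somatic voltage waveforms, using only
an SWC reconstruction plus five tunable biophysical parameters. The model
assumes (i) branches act as independent discriminating subunits, so the
neuron's M is the sum of per-branch M; (ii) spine counts follow the
optimal-wiring scaling law `L = c·n^(2/3)·V^(1/3)`; (iii) discrimination
operates on quantized somatic traces compared sample-by-sample.

## Morphology

SWC files are parsed with strict validation (unique ids, a single root,
resolvable parents, acyclicity, positive radii; parse errors carry line
numbers). Dendritic accounting excludes soma (code 1) and axon (code 2):
an edge counts as dendritic when its *child* node is neither, so the stem
edge leaving the soma is included. Branches are maximal unbranched paths
between the root, branch points and terminals; the root-to-first-branch-
point stem counts as a branch, and multi-point-soma stubs are dropped.
Edge lengths are Euclidean; edge volumes are conical frustums
`π·h·(r₁² + r₁r₂ + r₂²)/3`. Multi-root files are rejected — single-cell
repository files have one root. Basal and apical dendrites are pooled (all
dendritic structure codes), since per-compartment separation is not needed
by anything downstream.

The synthetic-morphology generator grows random binary trees: branch
lengths are normal around the requested mean (σ = 25 %, clipped at 20 % of
the mean), directions follow a jittered random walk, and radii taper
geometrically with bifurcation depth. Exactly p bifurcations give 2p+1
branches. The "mouse-like" fixture suite (12 cells, 15–40 bifurcations,
mean branch lengths 40–90 μm, radii 0.4–0.8 μm) emulates the gross
morphometry of mouse cortical dendrites: total lengths of a few mm and
realistic L/V ratios. It does **not** emulate real arborisation statistics
(no apical trunk, no Sholl profile, no tortuosity matching), so passing
tests demonstrate correctness of the machinery on plausible geometry, not
agreement with any particular real cell class.

## Spines

The wiring-law constant defaults to `c = 0.8389`, calibrated once (root
finding on the fixture suite) so the suite's mean spine density is
1.54 per μm — the midpoint value reported for mouse cortex, inside the
0.5–2.1/μm literature range. The density multiplier ρ rescales the law's
prediction (0.5, 1, 2 are the grid the optimizer explores). Allocation to
branches is proportional to length with largest-remainder rounding (exact
conservation; ties broken by branch index). Equidistant placement uses
midpoints `(j − ½)·l_b/n_i`, keeping the constant spacing `l_b/n_i` while
avoiding endpoint collisions with branch points. Receptor assignment flags
`floor(fraction·n_i)` spines (never exceeding the spine count); fraction 1
is deterministic, otherwise the subset is drawn uniformly with a seed.

## Waveforms and discriminability

Traces are 200 ms at dt = 25 μs (N = 8000). Quantization truncates toward
zero to two decimals of mV (10 μV), the stated motivation being recording
noise; truncation of negatives is toward zero (string-truncation
semantics), not floor. Values stored with binary representation error but
lying on the 0.01 mV grid are snapped to the grid before truncation
(tolerance 10⁻⁶ of a cell) so that e.g. 8.06 never truncates to 8.05.
Quantization happens *before* differencing.

Two quantized traces are discriminable iff they differ in ≥ d samples
(default d = 400 ≙ 10 ms). The discriminable count of a set is the number
of connected components of the graph whose edges join non-discriminable
pairs, found by union-find with union-by-size and path compression.
Components need not be cliques on real data (the similarity relation is
not transitive); when they are not, a warning logs the fraction of
intra-component pairs that are discriminable, and the component count is
used regardless. Labels are returned alongside M, numbered by each
component's lowest waveform index.

## The somatic-EPSP surrogate

The surrogate replaces an external compartmental simulation. For a
pattern of co-active spines it sums per-spine contributions: AMPA-flagged
spines add `amp_ampa·exp(−x_s/λ)`, NMDA-flagged spines add
`amp_nmda·exp(−x_s/λ)·g(V_rest)·(1 + boost·σ(k_local))`, where `x_s` is
arc-length to the branch root, `k_local` the number of co-active NMDA
spines within the 10 μm cluster window, and σ a sigmoid (midpoint 15
spines, slope 3) — the supralinear clustering effect. The two summed
drives are then resolved in steps of `drive_resolution` (default 0.1 mV)
and shaped by unit-peak double-exponential kernels (AMPA 0.5/5 ms, NMDA
3/60 ms) from the 50 ms release time onward.

Three surrogate choices deserve justification:

- **Discrete drive steps.** At 10 μV quantization a sustained amplitude
  difference of only ~2 μV already flips ≥400 samples, so a continuous
  noiseless sum would make *every* distinct pattern discriminable and the
  plateau search would never terminate. The step models the near
  all-or-none, stereotyped character of dendritic output and gives each
  branch a finite waveform repertoire — the same lossiness that lets ~200
  activation patterns collapse into a handful of somatic shapes.
- **Bell-shaped NMDA voltage gain** (peak −81 mV, width 4 mV, amplitude
  0.8): moderate hyperpolarisation increases the NMDA contribution while
  deep hyperpolarisation suppresses it (Mg²⁺ block vs driving-force
  trade-off), so cells rest-polarised near −80 mV discriminate most, and
  hyperpolarising from −75 mV helps.
- **Cluster-sigmoid midpoint at the wiring-law density**: with ~15 NMDA
  spines per 20 μm window at that density, the sigmoid is maximally
  sensitive exactly there; half density under-drives it and double density
  saturates it, making the law's density the discrimination optimum among
  {0.5, 1, 2}·CL.

All kernel constants are surrogate parameters collected in
`SurrogateKernels`; they are modelling choices of this package, not
measured quantities.

## Plateau estimation

Patterns activate k spines drawn uniformly without replacement; k defaults
to min(7, n_i) — the worked toy's activation count — because the original
production value is unstated; `k_active="uniform-random"` draws k
uniformly per pattern instead. Batches are cumulative (10, 20, 30, …), so
pairwise dissimilarities never change and the union-find structure grows
incrementally: each new waveform is compared once against all previous
ones. The search stops when the discrete derivative of the count is ≤ 0,
or after `max_rounds` (default 100; the safeguard exists because a backend
producing fresh waveforms forever would otherwise never halt). The maximum
observed count is returned. With a non-transitive similarity relation a
round can *merge* existing components, so the raw trace may dip — that dip
is precisely the stop signal; on transitive (template-like) backends the
trace is non-decreasing and the estimator is bounded by the backend's true
repertoire size.

Per-branch estimation derives each branch's spine layout from one seed, so
geometrically identical branches receive identical estimates, and
spineless branches contribute 0.

## The M law

`mlaw_predict` evaluates `Σ_i a·n_i·ln n_i + b` with the convention that
`n_i = 0` contributes nothing (an inactive branch cannot discriminate, so
it must not add the intercept). Natural log is a convention; a and b
absorb base changes. Fits use ordinary least squares on the design
`[n·ln n, 1]` (or `[n, 1]`, `[n², n, 1]`); adjusted
R² = 1 − (1−R²)(N−1)/(N−p−1) with p the coefficient count excluding the
intercept. Fitting requires ≥3 samples, n ≥ 1 and a non-degenerate design.
Under 5 % multiplicative noise the slope a is sharply identified (within a
few %), while the intercept b has a sampling SD of several units — an
intrinsic property of that noise model, since residual noise at large n
dwarfs b.

On the built-in surrogate the per-branch repertoire grows roughly linearly
over the desk-scale n range with k fixed at 7, so the n·log n and linear
fits of pipeline data are near-tied; the sharp superiority of n·log n
reported for full-scale biophysical simulations is reproduced here only on
law-generated data. This is a known limitation of the surrogate, not of
the fitting machinery.

## Genetic algorithm

Candidates are 5-tuples on finite grids (defaults: V_rest −85…−75 mV step
1; {linspace, uniform}; ρ ∈ {0.5, 1, 2}; AMPA/NMDA fractions
{0.25, 0.5, 0.75, 1}). Each iteration evaluates the pool (cached by
tuple — M estimation is the cost centre and tuples recur), selects the two
best, applies uniform crossover (each coordinate swapped with probability
½ — the standard unbiased choice for unordered tuples), mutates each
offspring coordinate with probability 0.1 by re-drawing from its grid, and
replaces the two worst unconditionally; the pool size stays constant. The
global best over all evaluations is tracked separately so the returned
optimum never degrades; the initial pool is uniform random over the grids.

## Statistics

The permutation correlation test offers two modes: `standard` (two-sided:
fraction of shuffles with |R| ≥ |R_observed|; the default, with calibrated
type-I error) and `as_printed` (fraction of shuffles with signed R > 0.05,
rejecting when that fraction < 0.05 — kept verbatim for fidelity, but it
degenerates for long vectors where a shuffled R rarely exceeds 0.05).
Group comparisons default to the unpaired Wilcoxon rank-sum (the
comparisons performed are unpaired; Kruskal–Wallis for k groups), with
α = 0.05 decisions reported alongside raw p-values and no
multiple-testing correction. M* is min–max feature scaling; percent
differences are against the grand mean of all included cells; species
totals weight mean M by whole-CNS neuron counts.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: fixture
neurons of 1–8 bifurcations, plateau searches capped at 40–100 rounds,
3-cell pipelines (~40 branches) for the law fit, and 288/500-point GA
grids — sizes chosen so each stage still exercises its full code path.
Largest-remainder rounding, floor-based receptor counts, branch-index tie
breaks and single-seed expansion (`numpy.random.SeedSequence`) make every
run reproducible from one integer seed. Degenerate inputs fail loudly:
empty morphologies, constant vectors in correlation or scaling, all-equal
spine counts in fitting, and zero-volume dendrites with positive length
all raise errors rather than returning conventions.

## Known limitations

- The surrogate is a phenomenological stand-in: it captures attenuation,
  clustering supralinearity, voltage-dependent NMDA gain and repertoire
  finiteness, but no active conductances, no within-branch interaction
  between AMPA and NMDA kinetics, and no interior optimum for the NMDA
  fraction. Conclusions about real cells require re-running the exported
  NEURON bundle with a full biophysical model.
- M is a point estimate; no confidence intervals are computed.
- Comparative statistics operate on whatever metadata table is supplied;
  the package ships no repository download tooling.
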