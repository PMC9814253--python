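# Methods

`chemloop` reproduces, in software, the decision-making machinery of an
autonomous batch reaction-optimization platform: a kernel-density Bayesian
optimizer over a mixed categorical/continuous space, a hierarchical
multi-objective scalarizer, a process-constrained batch planner, a
descriptor-clustering ligand-space designer, and a closed-loop orchestrator.
A synthetic Suzuki-coupling emulator supplies measurements so the entire
loop runs without hardware.

## Parameter space and executable dispenses

The search space couples one categorical parameter (the phosphine ligand,
12–23 options) with continuous process parameters: phosphine-to-palladium
ratio (0.5–4.0), palladium loading (1.0–5.0 mol%), reaction temperature
(10–40 °C), and optionally arylboronic-acid equivalents (1.0–2.0).
Continuous values normalize affinely to the unit interval; categorical
values are handled as option indices internally but exposed as stable
string identifiers.

Parameters dispensed from stock solutions carry a dispense rule
(stock concentration, 1 µL volume quantum, 3–100 µL dispensable window, and
an amount-per-unit conversion from parameter value to µmol). Suggested
points are *snapped*: the implied volume is rounded to the nearest quantum
— ties away from zero, a convention we fix because half-microliter ties are
otherwise platform-dependent — and the executed amount is recomputed from
the rounded volume. Only executed points enter the observation log. A
rounded volume outside the dispensable window is an error, never a clamp,
so the log never contains unexecutable conditions. The 3 µL minimum is a
default, not a verified instrument limit. In the default space the
ligand-volume conversion is referenced to a 0.2 µmol nominal palladium
charge so that the ratio range's endpoints land on whole microliters.

## Hierarchical scalarization

Objectives are prioritized: maximize E-product assay yield, then minimize
Z-product yield, then minimize Pd loading, then (12-ligand configuration
only) minimize arylboronic-acid equivalents, each with a 10% relative
tolerance. After orienting all levels to minimization, thresholds are
computed over nested regions: with R₁ = all observations,

    threshold_j = min_{R_j} f_j + t_j (max_{R_j} f_j − min_{R_j} f_j),
    R_{j+1} = { i ∈ R_j : f_j(i) ≤ threshold_j }.

The span is taken on the surviving region R_j, not the full set, because a
tolerance is only meaningful among observations that already achieved all
higher-priority thresholds. The tolerance is interpreted relative to the
observed span (not an absolute 10 mol%); that reading follows from treating
the tolerance as a property of the optimization landscape rather than the
assay. Thresholds are recomputed from scratch from all observations before
every batch.

The merit is an *operational reconstruction* of the soft-stacking Chimera
scalarizer, not the original construction: with d(i) the first level whose
threshold observation i fails (J+1 if none) and c = min(d(i), J),

    merit(i) = (J + 1 − d(i)) + f̂_c(i),

where f̂_c is the min–max normalization of level c over all observations
(zero span → 0). Lower is better. The integer offset enforces the
hierarchy's dominance semantics exactly — an observation satisfying
strictly more levels always outranks one satisfying fewer (the offset gap
exceeds the unit width of the normalized term; the boundary case would
require a failing observation to sit at the global level minimum, which
contradicts failing) — and the formulation is exactly testable by hand,
which the original soft stacking is not.

## Kernel-density surrogate and sample bias

The acquisition is a kernel-weighted average of normalized merits blended
with a uniform prior:

    α_λ(x) = ( Σ_n m̂_n k_n(x) + λ_int w₀ p₀ ) / ( Σ_n k_n(x) + w₀ p₀ ),

with p₀ the uniform density of the normalized space (1 per unit cube × 1/K
per categorical axis) and w₀ = 1. The sample bias λ is exposed on the
instrument scale ±0.000104 and mapped to λ_int ∈ [−1, 1]; far from all
data α → λ_int, so negative bias makes unexplored regions attractive
(explorative) and positive bias repels them (exploitative). α is a weighted
mean, hence bounded between min(m̂, λ_int) and max(m̂, λ_int) and monotone
nondecreasing in λ.

Kernels are fixed rather than learned (the original Phoenics/Gryffin
parameterize them with Bayesian neural networks): Gaussians on normalized
continuous axes, a smoothed indicator on categorical axes ((1−s) for the
same option, s/(K−1) otherwise, s = 0.1), or — in descriptor mode — a
Gaussian on standardized descriptor vectors, with bandwidth σ_c = σ·√p for
p descriptor dimensions so a typical descriptor displacement weighs like
one continuous axis. The continuous bandwidth follows Scott's rule on
normalized axes, **including the data-spread factor**:
σ_d = max(0.05, max(sd_d, 0.05)·n^(−1/(d+4))) per dimension. The
spread-free variant n^(−1/(d+4)) alone gives σ ≈ 0.5 at n ≈ 200 on the
unit cube; at that bandwidth the surrogate cannot resolve the
preferred-ratio ridge of the emulator (width ≈ 0.23 normalized), and
campaigns plateaued around three-quarters of the attainable optimum. The
0.05 floor keeps the kernel from collapsing onto single observations late
in a campaign.

Proposals minimize α by uniform random search (2 000 candidates, fixed
parameters clamped) followed by three rounds of coordinate-wise
golden-section refinement on the free continuous dimensions of the best
candidate. A winner within 1e−6 (normalized) of an existing observation
with the same categorical values is discarded for the next-best candidate.
All randomness is seeded; each proposal slot derives its seed from
(campaign seed, loop id, slot index).

## Process-constrained batches

Reactions run in loops of eight sharing one reactor-block temperature
(basic process-constrained batch optimization). Slots carry eight evenly
spaced sample biases from +λ_max down to −λ_max. One slot per loop is
proposed unconstrained and its temperature becomes the loop's shared value.
Which slot anchors is consequential: the exploitative acquisition never
extrapolates (its far-field is repellent), so an always-exploitative anchor
freezes the temperature at whatever the first random loop found — in stress
tests such campaigns stalled below 15% of the attainable optimum when the
first loop landed cold. A rotating anchor solves this: three loops
anchored by the most exploitative slot (refining temperature where
predicted merit is best), every fourth by the most explorative (probing
fresh temperatures). Within a batch, a proposal landing within 0.05
normalized Chebyshev distance of an already-planned slot with the same
ligand is re-proposed with a shifted sub-seed (up to six attempts), so
exploitative slots form a small cloud around the incumbent — cheap local
exploration of the ratio and loading — instead of eight near-replicates.
Every suggestion is snapped to executable volumes before entering the plan.

## Ligand-space design

Candidate ligands arrive as a table of computed molecular descriptors
(several hundred rows, tens of heterogeneous numeric columns). Columns are
z-scored (population sd; zero-variance columns dropped with a log entry) —
descriptors carry incommensurable units, so correlation-scale PCA is the
defensible default. The table is projected onto the first four principal
components (sign convention: each loading's largest-magnitude entry is
positive), then k-means with k = 24 partitions the scores: k-means++
seeding, Lloyd iterations with inertia asserted nonincreasing, best of 20
restarts, fully seeded. One representative per cluster is the non-excluded
member nearest its centroid in PC space, ties broken by lexicographically
smallest ligand id; exclusions (availability, price, stability — judgments
outside the data) are caller-supplied ligand or cluster ids, and a wholly
excluded cluster yields none, giving the 23-ligand panel used in the larger
campaign.

The synthetic descriptor generator plants 24 cluster centers in a 4-D
latent space (center scale 4.0, within-cluster scale 0.35), lifts them to
30 observed descriptors through a random linear map with log-normal
per-column scales and offsets, and adds 15% relative noise. It reproduces
the scale and blocked correlation structure of a real descriptor library
and returns ground-truth labels for recovery tests. It does not emulate
heavy-tailed descriptor distributions, missing values, or clusters of very
unequal density, so clustering-recovery results certify the pipeline's
correctness, not its robustness on a real library.

## Reaction emulator

The emulator's mean surface is an invented, qualitatively faithful shape —
a fixture for exercising the optimizer, not a kinetic claim:

    conversion = 100 · logistic((T − 30)/5) · Pd/(Pd + 2)
                     · exp(−(r − r_L)²/(2·0.8²)) · a_L,

so conversion improves toward the top of the temperature range, saturates
in palladium loading (half-saturation 2 mol%), and peaks at a per-ligand
preferred ratio r_L. Stereochemistry splits conversion by a per-ligand
selectivity: E = conv·s_L, Z = conv·(1−s_L), echoing the
retention/inversion dichotomy. Ligand latents are drawn per seed:
s_L ~ Beta(1.2, 2.5) so most ligands favor inversion and only a thin tail
is strongly E-selective (matching the observed prevalence of
stereoinversion), r_L ~ U(1.2, 3.2) (optima near the center of the ratio
range), activity a_L ~ U(0.55, 1.0). With descriptors supplied, s_L becomes
a logistic-linear function of the standardized descriptor vector so
descriptor-aware optimization has signal. Measurement noise is independent
Gaussian (sd 1.5 mol%, within the 1–2 mol% replicate reproducibility band)
on E and Z, truncated at 0 and rescaled if E+Z would exceed 100; reported
conversion is max(E+Z, mean conversion) capped at 100 so E + Z ≤
conversion ≤ 100 always holds. `true_optimum` grid-searches the noiseless
surface (21 points per continuous dimension × all ligands) and is the
oracle all campaign performance is judged against.

## Orchestration, scheduling, assay yields

A campaign of L loops × 8 plans each batch from all observations to date,
executes it (emulator, or robot-CSV exchange: a plan CSV with experiment
id, well in row-major order, loop id, λ, integer-µL volumes and executed
parameters; a results CSV in long peak-area or wide response form), appends
observations with executed parameters, and re-scalarizes. Standard
(test-reaction) wells — 16 per 96-well block at a fixed reference condition
— are logged separately and never enter the optimizer. Campaigns are
replay-deterministic given the seed and config.

Assay yields from HPLC records: yield% = (A_species/A_IS)·(1/RF)·
(n_IS/n_limiting)·100 with predetermined response factors and an internal
standard. Makespans: sequential campaigns take n·age; staggered loops take
⌈n/8⌉·(8·stagger + age) — with 15-min staggering and a 120-min age, 192
reactions take 96 h instead of 16 days, and 120 take 60 h.

## Problem sizes and determinism

Default study conditions are 23 ligands, 24 loops × 8 = 192 iterations,
noise 1.5 mol%. The test suite checks optimizer performance as a median
over 20 campaign seeds; `scripts/acceptance.py` reports the same quantity
over 8 seeds derived from its `--seed`, a size chosen to keep a full
from-scratch reproduction under a minute while the median remains stable.
Every stochastic component (candidate sampling, emulator noise, descriptor
synthesis, k-means restarts) is seeded; reruns are bit-identical.

## Known limitations

- The scalarizer and surrogate are reconstructions: hierarchy semantics
  and acquisition limits match the originals, exact merit values and
  proposal trajectories do not.
- Exploration is novelty-driven and merit-blind (a property of the α
  formula's far-field); discovery of a dominant ligand hiding in a narrow
  ratio window is therefore luck-limited at 192 iterations, and individual
  seeds can finish well below the oracle even though the median clears 90%.
- The emulator omits chemistry the platform would see: no side products,
  no catalyst decomposition, no temporal drift, no well-position effects.
- pc-BO variants beyond the basic shared-value scheme (e.g. nested
  optimization of the constrained variable) are out of scope, as are
  instrument drivers and chromatogram integration.
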