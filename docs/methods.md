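# Methods

## Channel model and rate family

Channels follow the Hodgkin–Huxley formalism: the current density is
`I = gbar · Πᵢ xᵢ^pᵢ · (V − E_rev)` (mA/cm² with `gbar` in S/cm² and
voltages in mV), each gating variable relaxing as
`dx/dt = (x∞(V) − x)/τ(V)`.  Rather than accepting arbitrary code for the
rate functions, the package fixes a declarative closed-form family that
covers classical channel descriptions and serializes cleanly to YAML:

- `alpha_beta` gates: α and β are each a constant, exponential
  `A·exp((V−Vh)/k)`, sigmoid `A/(1+exp((V−Vh)/k))` or linoid
  `A·(V−Vh)/(exp((V−Vh)/k)−1)` term, with `x∞ = α/(α+β)`, `τ = 1/(α+β)`;
- `inf_tau` gates: Boltzmann `x∞ = 1/(1+exp(−(V−Vh)/k))` (negative `k`
  gives inactivation) with a constant or bell-shaped
  `τ = base + amp/(exp((V−Vh)/k₁)+exp(−(V−Vh)/k₂))`;
- calcium-dependent gates (KCa only): Hill activation
  `x∞ = ca^h/(ca^h + Kd^h)` with a constant or bell τ.

The linoid form has a removable singularity at `V = Vh`; it is evaluated
by its analytic limit `A·k` within `|V−Vh| < 10⁻⁶ mV` to avoid
catastrophic cancellation.  Gate invariants (`x∞ ∈ [0,1]`, `τ > 0`) are
enforced on `V ∈ [−150, 70] mV`.  Rates are taken as already valid at the
simulation temperature of 37 °C; a `q10_factor` (default 1) is available
for rescaling.

Reversal potentials are fixed (`Ih`: −45 mV) or computed by the Nernst
equation `E = (RT/zF)·ln([out]/[in])` with
`R = 8.314462618 J mol⁻¹ K⁻¹`, `F = 96485.33212 C mol⁻¹`,
`T(K) = °C + 273.15`.  The bundled per-class concentrations reproduce the
class reversal potentials (Kv/KCa −86.7, Nav 50.0, Cav 135.0 mV) to within
0.1 mV at 37 °C.

The template library provides nine documented phenotypes spanning the five
ion classes (HH squid K, A-type, delayed rectifier, m-type, D-type, Nav
m³h, T-type Cav, SK-like KCa, HCN-like Ih).  Their parameters are
representative textbook values for each phenotype, chosen so the
phenotypes are kinetically well separated; they are starting points for
synthetic ensembles, not fits to specific published models.

## Protocols

The five per-class clamp protocols (activation, inactivation,
deactivation, ramp, action potential) are defined by the versioned table
`src/ionclamp/data/protocols.yaml`: holding levels, graded step ranges
(inclusive of both endpoints), segment durations and the analysis window
`[TA, TB]` per (ion class, protocol).  Segments are
left-closed/right-open: the sample at a boundary belongs to the new
segment.  The ramp protocol holds at `V0`, then runs eight alternating
linear ramps between `V0` and `V1` with durations `T2…T9`, starting
upward — four up/down pairs of differing slope.  Whether the first ramp
ascends, and whether every ramp spans the full range, are choices the
table file makes explicit and a user can override.

The action-potential protocol uses a bundled *synthetic* regular-spiking
waveform (resting −65 mV, stereotyped spikes to +30 mV with a −72 mV
afterhyperpolarization recovering with τ = 15 ms, default 10 Hz with ±2 ms
seeded jitter).  It is deterministic for a fixed seed; a user-supplied
recorded waveform of matching duration can replace it.

## Clamp simulation

Gates are advanced by exponential Euler,
`x ← x∞ + (x − x∞)·exp(−dt/τ)`, at `dt = 0.05 ms`.  This update is exact
for constant voltage, so hold segments are advanced in closed form (the
fixed-step trajectory is reproduced sample for sample); ramp and AP
waveforms are scanned per sample with rates evaluated at each update
interval's midpoint voltage, which preserves exactness on constant
stretches and is second-order accurate on ramps (halving `dt` changes
ramp currents by ~10⁻⁴ relative RMS for the fastest template gates).
Gates start at steady state for the holding potential, removing onset
transients.  Only the channel's own current is recorded: under ideal
clamp a passive leak is a voltage-determined additive term carrying no
kinetic information, and the downstream normalization would largely cancel
it.  Single-compartment geometry is irrelevant for current densities under
ideal clamp and is not modeled.  `gbar` is applied as the final
multiplication so that rescaling the conductance rescales every sample
exactly.

## Featureization

Per protocol and channel: (1) if the trace set's absolute minimum exceeds
its absolute maximum the whole set is flipped (set-level flipping
preserves the relative structure across steps); (2) the set is divided by
its maximum value after flipping — set-wide, not per trace, since
per-trace division would erase the activation curve across steps; an
all-zero set is returned as a flagged zero vector; (3) each trace is
restricted to `[TA, TB]` and subsampled by uniform index selection to
exactly 512 points, endpoints included, without anti-alias filtering
(traces are smooth); (4) traces are concatenated over steps in ascending
voltage order, and for KCa over the seven calcium levels in descending
concentration (outermost).  Kv activation thus yields 512·16 = 8192
values and KCa activation 512·16·7 = 57344.

Scoring fits, per protocol, a Z-scoring (population standard deviation;
zero-variance columns map to 0) followed by PCA retaining the smallest
dimensionality with ≥ 99 % cumulative explained variance; each protocol's
score block is divided by the standard deviation of all its entries; the
five normalized condition-score blocks are concatenated and reduced by a
final PCA (same criterion, re-centered) to the total scores.  Principal
axes are oriented so each axis's largest-magnitude loading is positive,
making results reproducible across linear-algebra backends.  The variance
threshold and Z-score ddof are constructor parameters of
`TwoStagePCAScorer`.  Conductance invariance of the whole pipeline is
exact up to the final rounding of the normalization division (observed
≤ 10⁻¹⁵ in total-score coordinates); tests assert it at 10⁻⁹.

A degenerate ensemble with no variance (identical channels) yields a
single zero component and zero scores rather than an error.

## Clustering

Ward linkage and tree cutting use `scipy.cluster.hierarchy` (`linkage`,
`cut_tree`); cuts at decreasing k are nested refinements, and labels are
renumbered by order of first appearance.  Merge ties are resolved by the
library's internal order; for continuous scores ties occur with
probability zero, and the test suite verifies agreement with a brute-force
greedy agglomeration oracle on small random point sets.  Silhouette,
Davies–Bouldin and Calinski–Harabasz come from `sklearn.metrics`; the Dunn
index (min inter-cluster distance over max intra-cluster diameter) is
implemented here.  The inner distance is computed on the raw preprocessed
feature vectors (not Z-scored), with the norm the mean absolute value over
all entries of the appended vector; for KCa the normalizing length
includes the calcium dimension (512·c·7), the natural extension of the
per-protocol definition.  No k is selected automatically: `scan_k`
tabulates all measures and the user applies the usual knee/extremum
heuristics.  Reference models minimize the Euclidean distance to their
cluster's mean score, ties broken by lexicographic id; clusters are named
by the subtype labels contributing at least 30 % of members, else
"mixed".

## Genealogy

Ancestor–descendant edges form a directed graph; *families* are connected
components of its undirected skeleton, numbered by decreasing size then
lexicographically smallest member.  Metadata are free text; crosstab
matching lowercases and trims labels.

## Synthetic ensembles

The generator emulates a corpus of refitted model variants: each member
perturbs its template's half-voltages additively
(`N(0, (jitter_fraction·20 mV)²)`) and its rates, slopes, time constants
and calcium parameters log-normally (`σ = jitter_fraction`), then
revalidates the gate invariants with bounded resampling.  A single
`jitter_fraction` therefore controls both scales; at the default 1 % the
within-template spread is small against the between-phenotype separation,
which is what makes ground-truth recovery a meaningful check.  What the
generator does **not** emulate: measurement noise, protocol artifacts
(series resistance, leak subtraction), non-HH kinetics (Markov schemes),
or the uneven phenotype composition of real corpora.  Passing recovery
tests therefore demonstrate the pipeline's internal consistency and
discriminative power on clean HH-style kinetics, not performance on noisy
experimental data.

## Problem sizes and defaults

The standard synthetic corpus used throughout the tests and the
acceptance script is 5 Kv templates × 10 members at 1 % jitter
(50 channels, all five protocols at `dt = 0.05 ms`, ≈ 160 k time samples
per channel), chosen as the smallest ensemble that exercises every
pipeline stage with realistic within/between-group structure; it
simulates and scores in a few seconds.  The Ward oracle comparison uses
50 random sets of 3–8 points.  Index scans run over k = 2…10.

## Known limitations

- Only HH-style (product-of-gates) kinetics are expressible; Markov-state,
  ligand- or light-gated schemes are out of scope.
- The AP waveform is synthetic; scores under the AP protocol are only
  comparable between channels run on the same waveform (the waveform is
  part of the fitted score space's identity).
- Scores are fitted per ion class and are not comparable across classes
  (protocols differ by class).
- The two-stage PCA is linear by design; strongly nonlinear kinetic
  differences may fold onto nearby scores.
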