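# Methods

This note records the models, conventions and numerical choices behind
`stochtrace`, in the spirit of the methods documentation of simulation
packages: what is computed, under which assumptions, and where a design was
genuinely open, why it was fixed the way it was.

## Stochastic simulation

The simulator implements the exact SSA (direct method) for well-stirred
mass-action kinetics of reactant order 0–2. Propensities are

- order 0: *a = c*
- order 1 (reactant S): *a = c·x_S*
- order 2, distinct reactants: *a = c·x₁·x₂*
- order 2, homodimer 2S: *a = c·x(x−1)/2* (number of unordered pairs)

Waiting times are exponential with rate *a₀ = Σ_j a_j*; the firing channel
is drawn with probability *a_j/a₀*, independently of the waiting time, by
inverse-CDF over the cumulative propensities. Simulation stops at *t_max*,
when *a₀ = 0* (exhaustion), or after an optional `max_steps` firings (used
by benchmarks that need traces of a fixed length). The state is recorded at
*t = 0* and after **every** firing — no thinning — so traces are exactly
piecewise constant and unevenly sampled.

Species come in three kinds. `entity` and `complex` carry integer copy
numbers; `variable` carries a real-valued scalar measurement. Variables
evolve only through explicit reactions here; no rate/assignment rules are
modelled, because nothing in the supported model format defines continuous
dynamics for them.

**Seeding.** Replica *i* of an ensemble uses the sub-seed
`(base_seed + i · 0x9E3779B9) mod 2⁶³` fed to numpy's PCG64. The
golden-ratio stride guarantees pairwise-distinct seeds for any realistic
ensemble size, and PCG64's seeding mixes them thoroughly; the scheme is
deterministic, so `(model, t_max, n, base_seed)` reproduces an ensemble
bit-for-bit. Cross-correlation between replicas is avoided by seed
distinctness, not by any streaming discipline.

**tstart.** Per species, the first time its amount is strictly positive: 0
if initially present, +∞ if it never appears. This drives the
temporal-circuit layout and is preserved through boxing.

## Fixture models

Three built-in models generate all test data; their defaults are the study
conditions used throughout the test suite and the acceptance script.

- `birth_death` — ∅→S at rate λ=10, S→∅ at rate μ=0.1 per molecule, S
  initially absent. Stationary mean λ/μ = 100 with Poisson dispersion;
  event rate ≈ 2λ at equilibrium, so trace lengths are easy to control.
- `dimerisation` — 2A ⇌ C (association 0.01, dissociation 0.1, 100 A
  initially): exercises homodimer combinatorics.
- `oscillator` — a three-species negative-feedback loop (A activates B, B
  activates C, C catalyses A's removal); C is absent at *t = 0* and enters
  only through synthesis, which exercises tstart bookkeeping and gives the
  temporal-circuit layout a non-trivial column structure.

What the fixtures do **not** emulate: real case-study networks with dozens
of species, rare-event regimes, stiff rate separations, or experimentally
calibrated kinetics. Passing tests show the machinery is correct on
small-to-medium mass-action systems, not that any biological conclusion
follows.

## Stream codec

The semantic compressor rewrites a number stream as
`value,persistence` tuples followed by sign-prefixed increments, separated
by `;`. Conventions fixed here:

- **Increments are successive differences** (*d_k = s_k − s_{k−1}*),
  decoded by cumulative sum. The alternative (differences from the tuple's
  base value) would grow increment magnitudes along a drifting trace;
  successive deltas keep them at the size of single reaction stoichiometries,
  which is what makes SSA traces compress well.
- **A tuple opens at the first element of each maximal constant run of
  length ≥ 2**; trailing non-repeating samples stay as increments of the
  open tuple. Runs of length 1 do not open tuples.
- **Decimal streams use exact decimal arithmetic** on shortest round-trip
  serialisations, inside a 800-digit context (double differences never need
  more): binary floating addition does not guarantee *v + (w − v) = w*, and
  losslessness is a hard contract here. Negative zero is normalised so sign
  prefixes stay unambiguous.
- Structural stage: gzip at default level, then standard padded Base64
  without line wrapping.

Integrity: payloads carry sample count and first/last values; Base64/gzip
corruption, count mismatches and first/last mismatches all raise a
dedicated integrity error. A flipped character can only go undetected if it
does not change the decoded bytes at all (Base64 padding slack).

## Boxed XML

One document couples the model section (species with kinds, amounts and
MIRIAM-style annotations; reactions with type tags, integer stoichiometries
and rate constants) with a trace section: a shared uniform grid
`(tFirst, tLast, nPoints)` and, per replica and species, one compressed
stream with its own count/first/last metadata and the species' tstart.
Element and attribute names are fixed by the XSD shipped under
`src/stochtrace/schemas/`; `unbox` validates against it and reports the
offending element path on violation.

Choices: **all replicas live in one document** (they share the grid, and
cross-replica analysis is the point of the format); **resampling is
zero-order hold** because SSA traces are piecewise constant, so holding the
last value is exact rather than an approximation; entity/complex streams
are encoded as integers, variable streams as decimals. The grid spans
`[max over replicas of first time, max over replicas of last time]` —
replicas that terminate early (absorption) are correct under ZOH extension,
while a grid preceding a replica's first record would have no defined
value. The `structure` attribute is carried as an opaque string.

Boxing is lossy exactly once — the resampling onto the grid; on gridded
trace sets `box`/`unbox` are mutually inverse, and that is the round-trip
contract the tests enforce.

## Binning alignment

Windows are half-open `[anchor + k·w, anchor + (k+1)·w)`, anchored at the
trace start (single-trace binning) or at the replica-set minimum start time
(alignment), so all replicas share one window grid. Aggregates: sum, mean
(default), max, min. Representative time: the **lower median** (index
⌊(k−1)/2⌋ of the sorted member times) by default — it is always an actual
sample time and needs no tie rule — or the time of the maximum member value
(first maximum on ties). Empty windows produce no bin; for cross-replica
alignment, windows empty in *any* replica are dropped for all
(intersection), which keeps every reported grid point defined in every
replica. The shared time vector reports window midpoints.

## Analyzers

All cross-replica evaluation uses zero-order hold; grid times before a
replica's first record clamp to its first value (relevant only for
synthetic inputs — SSA replicas all start at *t = 0*).

- *series*: grid = sorted union of all replica timestamps.
- *pointwise*: regular grid from the ensemble start, both endpoints always
  included (a final partial step is closed at *t_max*).
- *first-hitting*: per run, the first timestamp where the condition holds;
  values are pooled for statistics, times reported separately, and the
  aggregate is plotted at the mean hitting time. Non-hitting runs are
  excluded and counted, not an error.
- *steady-state*: one uniformly random timestamp with *t* > transient per
  run, drawn from a generator seeded by the caller; runs that never pass
  the transient are excluded with a warning.
- *cumulative*: condition-true spans of the ZOH signal; per span max, min
  and the exact integral divided by the span length; a span still open at
  the end of a trace closes at the last timestamp.
- *time*: `between_ascending` (oscillation periods), `true_intervals`
  (ascending to next descending front), `time_sum` (total time true).
- *raw*: pass-through.

Statistic conventions: variance, standard deviation and standard error use
the unbiased (n−1) denominator; skew and kurtosis use population (1/n)
central moments with kurtosis reported as excess; geometric and harmonic
means require strictly positive values. Domain violations (a single
replica for variance, a zero for the harmonic mean) are reported per point
by omission of that point, and named in the error when a scalar statistic
is requested directly.

Front convention: the first timestamp never emits a front — there is no
pre-history to flip from. An opt-in flag counts an initially-true condition
as an ascending front at *t₀* for workflows that need it. With suppressed
boundary fronts, a condition that is true everywhere yields no fronts, no
periods and no true-intervals, but `time_sum` still reports the full span,
because it integrates the truth signal rather than pairing fronts.

## Reaction graphs and layouts

A model maps to a directed multigraph: one node per species; per reaction,
an edge from every distinct reactant to every distinct product tagged with
the reaction id and type. Synthesis/degradation reactions attach to a
per-reaction `env:<id>` pseudo-node so zero-reactant/zero-product reactions
stay visible. Degree centrality is `deg(v)/(n−1)` (parallel edges count
with multiplicity; in/out/total modes), with dense ranks; coloring maps
ranks onto a lightness ladder in [0.2, 0.85] — darker = more central — so
even the most central node remains legible on both light and dark
backgrounds.

Layouts are deterministic under a fixed seed and always land inside the
canvas (1000×1000 abstract units by default, 50-unit margin):

- *Circle*: static even spacing; a greedy neighbor-following order keeps
  graph-adjacent nodes adjacent on the ring where possible.
- *Spring*: a weighted embedder (edges pull proportionally to weight, all
  pairs repel, displacement capped by a cooling schedule).
- *Fruchterman–Reingold* and *Kamada–Kawai* delegate to networkx and are
  rescaled into the canvas; disconnected graphs under KK are laid out per
  component and packed into horizontal slots, since graph-theoretic
  distances are undefined across components.
- *ISOM*: self-organizing-map iteration — pick a random canvas point, move
  the closest vertex and its graph neighbors toward it with exponentially
  damped strength; both the neighborhood radius (3 edge steps initially)
  and the adaption factor (0.8 → 0.05, geometric) decay over epochs.
- *Temporal-Circuit* requires traces by construction: the column of a
  species is the rank of its pooled first-appearance time (minimum over
  replicas) among the sorted distinct tstart values; initially-present
  species and environment pseudo-nodes sit in column 0; species that never
  appear occupy one extra rightmost column. Within a column, nodes stack
  in identifier order (a total, stable tie-break); each edge carries a
  `source_column` annotation equal to the maximum column over its
  reaction's source species. Calling it without traces is an error, not a
  fallback — the layout *is* the simulation information.

The color-blindness filter is specified by its contract rather than a
perceptual model: output lightness preserves the input ordering, separates
every pair by a configurable δ (default 0.08) and keeps 2δ away from the
background lightness; hues in the red band ([0°, 40°], pushed toward
yellow) and green band ([90°, 150°], pushed toward blue) are compressed
proportionally to their distance from the band edge, leaving blues, yellows
and hueless grays untouched. A palette larger than the achievable lightness
ladder is rejected with a suggestion to lower δ.

## Problem sizes

The test suite and acceptance script run at the scales they report: 2000
fuzzed codec streams of up to 10⁴ samples; 10-replica birth-death ensembles
of 10³/10⁴/10⁵ steps for the compression benchmark; 2000 pure-death
replicas and 10⁴ inter-event gaps for simulator validity; 50 fuzzed replica
sets for analyzer/oracle equivalence; 100 random multigraphs (n ≤ 50) for
centrality. These sizes make every statistical check decisive (3-standard-
error bands, α = 0.01 tests) while a full run stays around a minute.

## Known limitations

- Mass-action orders 0–2 only; no tau-leaping, ODE/hybrid integration,
  delays or compartment volumes.
- The SBML reader covers a minimal subset (species, reactions, one rate
  constant per kinetic law) and rejects rules, events, function
  definitions, constraints and initial assignments by name.
- The compression benchmark mirrors the qualitative behaviour (better with
  longer traces, best on integer streams with long constant runs); absolute
  ratios depend on the simulated system.
- Layout quality is judged by contract (determinism, canvas containment,
  clustering tendencies), not by aesthetic criteria.
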