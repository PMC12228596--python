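# Methods

## Model and assumptions

`qdock` operates on the lattice interaction-space abstraction of
protein–ligand binding. A molecule is an ordered chain of interaction
sites; each site carries two bounded continuous properties, the hydrophobic
interaction strength `h` and the hydrogen-bonding strength `hb` (the two
most frequent protein–ligand interaction types). The model deliberately
ignores solvent effects, 3-D pocket geometry, and all other interaction
types, and it treats `h`/`hb` as abstract reals: no physical units or
canonical ranges exist for them in the lattice picture, so ranges are
user-supplied (the generators default to `[0, 1]`). The site encoding is
localized so that adding a third interaction qubit per site is a contained
change.

A docking site is a contiguous run of ligand-many protein sites whose
profile matches the ligand's — first at the coarse binary-label level
(search), then by continuous-value similarity (ranking).

## The two encodings

**Binary.** Each property is thresholded at the midpoint of its range; the
midpoint itself maps up (`[min, mid) → 0`, `[mid, max] → 1`). Two bits per
site, hydrophobic bit first, chains concatenated big-endian (first site
leftmost). Out-of-range values raise rather than clamp: a clamped value
would silently change the label the search relies on.

**Amplitude.** Each property becomes one qubit `α|0⟩ + β|1⟩` with
`α ∝ (max − v)`, `β ∝ (v − min)`, normalized; a site is the tensor product
of its two property qubits and a chain the tensor product of its sites. All
amplitudes are real and non-negative; β is strictly monotone in the value,
and the dominant amplitude branch agrees with the binary bit everywhere
except exactly at the midpoint, where the binary closed-upper rule decides.

## Search

The protein label is segmented into consecutive non-overlapping windows of
`2L` bits (`L` = ligand sites); a trailing remainder shorter than one window
is dropped and recorded in the trace. Duplicate window labels add nothing
to a presence question, so only each label's **last** occurrence enters the
uniform superposition `|s⟩` over `N` distinct labels — a subspace of the
full register Hilbert space, which is why fewer than `√N` iterations
suffice.

One Grover iteration applies the oracle reflection `I − 2|t⟩⟨t|` and the
diffusion reflection `2|s⟩⟨s| − I`. The iteration count is
`k = max(1, ⌊(π/4)√N⌋)`, the standard optimum for one marked state
(configurable override). For a present target the exact probability is
`sin²((2k+1)·arcsin(1/√N))`; for an absent target both reflections fix the
state and the probability is exactly 0.

**Presence threshold.** The target is declared present iff its measured
probability reaches `1/N`. The rule comes from the two-state extreme: with
`N = 2` a present target measures at exactly 1/2 for every iteration count
(the Grover rotation is stationary there) while an absent one measures 0,
so the boundary must be inclusive — implemented as
`p ≥ 1/N − 1e−9`, the tolerance absorbing float roundoff in the simulated
probability. With the exact backend the decision is therefore error-free
for every `N`. With the sampling backend the `N = 2` case sits exactly on
the threshold and the decision becomes a coin flip at any shot count; exact
is the default backend for decisions for precisely this reason, and
sampling must be requested explicitly with a shot count and seed.

**Controller.** For each shift offset `0 … L−1` the leading sites are
dropped, the remainder windowed, and the window range searched recursively:
a range whose distinct-label count is 1 is compared to the ligand label
directly (the threshold `1/N = 1` is meaningless and the comparison is
deterministic); otherwise the Grover presence test runs. A present
multi-window range is bisected on a window boundary (ceiling-left) and
**both** halves are explored — a present parent does not say which half
holds the match, and there may be several. Absent ranges are pruned.
Across the `L` shift passes every contiguous `L`-site run at offsets
`0 … P−L` appears as a window exactly once, so the controller's output
equals a classical substring scan on the exact backend; offset `L` would
regenerate the shift-0 windows, so shifting stops at `L−1`. Candidate
positions are reported as 0-based site offsets into the original protein.
Every decision (shift, window offsets, `N`, path, `k`, probability,
threshold, verdict) is recorded in a trace attached to the result.

## Evaluation

Candidates and the ligand are amplitude-encoded (unit-norm states, so
`Z = |A|² + |B|² = 2` in the pipeline, though the operations accept
arbitrary norms). The SWAP test prepares
`|ψ⟩ = (|A⟩|0⟩ + |B⟩|1⟩)/√2` and `|φ⟩ = (|A||0⟩ − |B||1⟩)/√Z`, Hadamards a
control qubit around a controlled-SWAP of `|φ⟩` with ψ's ancilla, and
measures the control. The circuit is simulated literally; its outcome
satisfies the identity `P₀ = ½ + ½‖⟨φ|ψ⟩‖²` with the bra contracting only
the ancilla, which makes `D = √(4Z(P₀ − ½))` equal the classical Euclidean
distance `|A − B|` exactly on the statevector backend (verified to 1e−9 in
tests). A sampled `P₀` marginally below ½ gives a negative radicand; it is
clamped to distance 0 and flagged, never raised. Ranking sorts ascending by
distance with ties broken by start offset, so permuting candidate input
order can never change the result.

## Backends and determinism

The exact backend tracks the full real statevector and returns squared
amplitudes; registers here are at most ~10 qubits, so dense vectors and
operators are used throughout. The sampling backend draws a seeded
multinomial (register measurement) or binomial (control qubit) from the
exact distribution — equivalent to measuring the simulated circuit shot by
shot, at far lower cost. Exact runs are pure functions of their inputs;
sampling runs are bit-reproducible per seed (the controller derives one
child seed per Grover call from the run seed).

Two diffusion implementations exist because NISQ-oriented circuit
constructions differ: the explicit dense unitary of `2|s⟩⟨s| − I`, and the
amplitude-amplification form `A(I − 2|0⟩⟨0|)A†` with `A` the state-preparation
unitary for `|s⟩` (a Householder reflection) and the zero reflection
implemented by phase kickback on an extra ancilla held in `|−⟩`. The ancilla
path accumulates a physically irrelevant global phase of −1 per iteration;
its register marginal matches the matrix path to 1e−10 on every test
instance.

## Synthetic data

The generator emulates the study's inputs: chains whose `(h, hb)` values
are i.i.d. uniform within their ranges (the model gives no other
distribution), proteins with a ligand copy planted at a chosen offset —
`exact-continuous` (identical values, distance 0) or `exact-binary` (values
redrawn inside the same midpoint half-intervals: identical label, nonzero
distance; a `jitter` bound keeps redraws near the ligand's values and
errors out rather than crossing a label boundary) — rejection-sampled
negative proteins with no matching window, continuous realizations of the
two reference bitstring instances, and the three benchmark problem shapes
(4/1, 10/2 and 27/3 sites, random values). Uniform values make accidental
extra matches possible
and the tests compare against a classical substring scan rather than the
planted offset alone. What passing tests show is correctness of the
search and ranking machinery on lattice abstractions — not predictive power
on real protein structures, which the lattice model does not attempt.

Default problem sizes in tests and the acceptance script (proteins ≤ 27
sites, ligands 1–3 sites, 100-instance recovery sweeps, 4096–10000 shots)
match the scales of the reference worked examples; they run in seconds on
one CPU.

## Known limitations

* The midpoint rule makes the binary label discontinuous in the values; a
  value infinitesimally below the midpoint is invisible to the search even
  though its amplitude state is nearly balanced.
* The sampling backend cannot decide the `N = 2` boundary case reliably
  (see above); use the exact backend for decisions.
* The `1/N` threshold presumes a single marked basis state, which the
  unique-latest deduplication guarantees; the closed-form probability is
  stated for one marked state only.
* No transpilation to hardware gate sets, no noise models, no error
  mitigation: the package targets exact and shot-sampled simulation only.
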