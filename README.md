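# qdock

Quantum identification and ranking of protein–ligand docking sites on the
lattice interaction-space model.

In the interaction-space picture, a protein and a ligand are each an ordered
chain of *interaction sites*, every site carrying two bounded continuous
properties: a hydrophobic interaction strength `h ∈ [h_min, h_max]` and a
hydrogen-bonding strength `hb ∈ [hb_min, hb_max]`. A docking site is a
contiguous run of ligand-many protein sites whose interaction profile matches
the ligand's. `qdock` finds and ranks such runs with a quantum algorithm,
simulated exactly (statevector) or with seeded finite-shot sampling:

1. **Binary (search) encoding.** Each property is thresholded at the midpoint
   of its range (midpoint inclusive upward), two bits per site, hydrophobic
   bit first; a chain becomes a bitstring such as `|110110⟩`.
2. **Subspace Grover search.** The protein label is chopped into ligand-sized
   windows; the *distinct* window labels (keeping each label's last
   occurrence) form a uniform superposition `|s⟩ = (1/√N) Σ|x⟩` over a Hilbert
   subspace. One Grover iteration pairs the oracle `O = I − 2|t⟩⟨t|` (`|t⟩` the
   ligand label) with the diffusion `G = 2|s⟩⟨s| − I`; after
   `k = max(1, ⌊(π/4)√N⌋)` iterations (always fewer than `√N`) the ligand
   label is declared present iff its measured probability reaches the
   threshold `1/N`. A present multi-window range is bisected and both halves
   searched recursively; shifting the protein by 0…L−1 sites makes every
   window alignment visible. Two interchangeable diffusion implementations
   (explicit unitary; ancilla amplitude amplification) are provided and
   equivalence-tested.
3. **Amplitude (evaluation) encoding + SWAP test.** Candidate windows are
   re-encoded with endpoint-interpolating amplitudes
   `a = (h_max − h)/√((h_max − h)² + (h − h_min)²)` (and likewise `b, c, d`),
   and each candidate is ranked by the quantum Euclidean distance
   `D = √(4Z(P₀ − ½))` obtained from a SWAP test on the states
   `|ψ⟩ = (|A⟩|0⟩ + |B⟩|1⟩)/√2` and `|φ⟩ = (|A||0⟩ − |B||1⟩)/√Z`, with
   `Z = |A|² + |B|²`. On the exact backend `D` equals the classical Euclidean
   distance `|A − B|` to numerical precision; the smallest distance is the
   best docking site.

The package is for people studying quantum algorithms for computer-aided
drug design at lattice-model scale: it runs entirely on a classical
simulator, but every operation is expressed in circuit-level primitives
(state preparation, reflections, controlled-SWAP, register measurement).

## Worked example

Generate the bundled fixture chains (including the worked-example instances
realized as continuous chains) and run the full pipeline on the 12-site
protein `|010011001111000110100011⟩` with the 2-site ligand `|1100⟩`:

```bash
qdock simulate --outdir demo --seed 0
qdock run --protein demo/device_example_protein.csv \
          --ligand  demo/device_example_ligand.csv --out report.json
```

prints

```
rank=1 offset=2 label=1100 distance=0.619363
rank=2 offset=5 label=1100 distance=0.741222
```

Both aligned occurrences of the ligand's binary pattern (protein sites 2–3
and 5–6) are located; site 2 ranks first because its continuous `(h, hb)`
values are closer to the ligand's, so its amplitude-encoded state has the
smaller SWAP-test Euclidean distance. The per-decision trace goes to stderr
(`qdock search …`), e.g. the first, whole-protein pass:

```
shift=0 offsets=[0, 2, 4, 6, 8, 10] N=6 path=grover k=1 p=0.907407 thr=0.166667 present=True
```

`N=6` distinct windows, one Grover iteration, ligand-window probability
49/54 ≈ 0.907407 ≫ 1/6 — the pattern is present, so the range is bisected and
the recursion continues down to single windows. A search with no candidate
exits with code 3 (absence of docking sites is a result, not an error).

Library use mirrors the CLI: `locate_docking_sites(protein, ligand, ranges)`
returns candidates plus the full decision trace, `rank_candidates(...)` adds
distances and ranks; `RunConfig` selects backend (`exact`/`sampling`), shots,
seed, iteration override and diffusion implementation.

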