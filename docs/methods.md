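# Methods

## Model and reduced units

Two pearl-necklace chains (hard spheres of radius `r`, consecutive
centres fixed at `2r`) are confined in a spherocylinder: a cylinder of
diameter `D` with hemispherical caps, total tip-to-tip length `L`.
`D = 1` defines the length unit and the aspect ratio `A = L/D` defaults
to 4, so `V = π(D/2)²(L−D) + (4/3)π(D/2)³ = 11π/12`.  The tip-to-tip
convention matters: with it, solving `N_total·(4/3)πr³ = φV` at
`φ = 0.05` gives diameter ratios `D/d = 11.33` for 400 beads and
`21.67` for 2800 beads, matching the printed ≈11 → ≈22 range; a
body-only length convention does not.

A bead is inside the container iff its centre is inside the
spherocylinder eroded by `r`; the boundary counts as inside (closed
container), with a `1e-12` relative slack so exactly-on-boundary
constructions do not fail on floating-point ties.

Interactions are purely hard: overlap of non-bonded beads (centre
distance `< 2r`), wall violation, and topology-changing moves are
forbidden; everything else has zero energy.  Temperature therefore
never enters and no Boltzmann factor is computed.

## Initial configurations

The builders are deterministic.  Each chain is laid on a cubic lattice
of spacing `2r` (bond lengths exact by construction; non-bonded lattice
neighbours are exactly tangent, which is legal).  Linear chains follow
a 3-D boustrophedon.  Rings are built as two mirrored serpentine
strands in adjacent lattice planes joined by single lattice bonds; for
bead counts beyond one plane-pair's capacity, per-pair racetrack cycles
are spliced along a shared vertical edge, which preserves exact bonds
and closure for any even count.  Odd rings add one bead via an
isosceles detour on the closing bond, pointing into reserved empty
space.  Segregated mode packs the chains into opposite z-halves,
innermost rows one lattice spacing short of the mid-plane (`λ < 0` by
construction); overlapping mode packs them into coincident z-intervals
on opposite sides of the axis (`λ` equals the common extent).  The
lattice start is far from equilibrium; the discard phase of the Monte
Carlo run performs the burn-in, and the segregated/overlapping control
(below) confirms the equilibrium averages do not depend on the start.

The builders accept a `seed` argument for interface stability but do
not consume randomness.

## Moves

One iteration is one attempted move.  A crankshaft proposal picks a
chain uniformly, a first pivot bead `i` uniformly, a segment length `s`
uniform in `[1, S_max]`, a direction, and an angle uniform in
`(−θ_max, θ_max)`; the beads strictly between the pivots rotate rigidly
about the pivot axis.  On circular chains the second pivot is
`i ± s (mod N)`.  On linear chains a segment overshooting either end
reflects into a *terminal* rotation: every bead beyond the reflected
interior pivot rotates about a uniformly random axis through that
pivot.  The direction draw is deliberate: reflecting only forward
overshoots would make terminal moves reach one end only and freeze the
other terminal bead entirely, destroying ergodicity exactly where the
end-bead observables live.  Proposals are symmetric, so acceptance is
pure constraint checking.

Defaults `S_max = min(N/2, 60)` and `θ_max = π` (an unrestricted angle
maximises mixing per move; `S_max` caps the cost of the swept-path
check).  An optional rigid whole-chain translation move exists for
diagnostics but is off by default and excluded from every headline run.

Neighbour search uses a linked-cell list with cell edge `3r`, serving
both the `2r` overlap test and the `3r` contact cutoff; the inner loop
is compiled with numba.  A run draws every random number from a single
seeded generator, so a seed fixes the trajectory bit for bit.

## Topology control

Tangent hard beads form an impenetrable tube, so *continuous* motion
cannot cross a chain without a hard-core overlap at some instant.
Discrete rotations can; the engine therefore subdivides a rotation into
the minimum number of equal angular substeps such that the largest bead
displacement per substep (chord `2R_max sin(Δθ/2)` at the largest
rotation radius in the moved set) stays below one bead radius, and
requires the hard-core condition at every intermediate configuration.
The substep check covers the beads whose mutual topology is conserved:
the moved ring itself (knot type) and, when the partner chain is also a
ring, the partner (linking number).  Moves of a linear chain are never
swept — an open chain can thread a ring by continuous motion anyway, so
no invariant is at stake.  Intermediate configurations are not wall
checked: the wall is not a topological obstacle, and endpoint validity
is what equilibrium requires.

Defence in depth: during every run the engine periodically recomputes
exact invariants on the current state — the Gauss linking number
(segment-pairwise solid-angle summation, rounded to integer with a
0.2 residual guard) and a knot detector — and aborts on any violation.
The knot detector first shrinks the ring by isotopy-preserving vertex
removals (a vertex goes when the triangle it spans with its neighbours
is pierced by no other segment; near-degenerate hits count as hits, so
the reduction is conservative), then computes the Alexander determinant
`|Δ(−1)|` from the crossing data of a seeded random planar projection,
with degenerate projections re-drawn.  The determinant is evaluated
exactly by Gaussian elimination modulo two large primes; agreement of
the residues identifies small values with negligible ambiguity.  The
determinant is 1 for the unknot, 3 for the trefoil, 5 for the
figure-eight; it is not a complete invariant, but it separates the
unknot from every knot a rare undetected strand passage could produce
in practice — a documented limitation, not a gap in the audit's
purpose.

## Observables

* `λ = min(zmax₁, zmax₂) − max(zmin₁, zmin₂)` over bead centres;
  `λ/L` uses the total container length.
* Contact = centre distance strictly `< 3r` (exactly `3r` is not a
  contact; the choice is measure-zero and fixed for bit-exactness).
* `p_inter`: contacts over all `N₁N₂` cross-chain pairs. `p_intra`:
  contacts over non-consecutive same-chain pairs — `N(N−3)/2` per
  circular chain, `(N−1)(N−2)/2` per linear chain — pooled over both
  chains.
* End-bead classes: every terminal bead of every linear chain
  contributes and the ends are averaged.  `p_end_inter` pairs an end
  with all beads of the other chain.  `p_end_intra` pairs an end with
  the *internal* beads of its own chain, excluding both terminals and
  the bead bonded to the probed end (`N−3` partners per end).  Whether
  the opposite terminal should be excluded is genuinely ambiguous; the
  choice is isolated in one predicate (`_end_intra_partners`) so it can
  be flipped, and at `N = 200` it changes denominators by 0.5%.
* Fold boost: `(p_end_inter/p_end_intra)` of the probed system divided
  by `(p_inter/p_intra)` of the reference system; non-computable ratios
  (zero denominators) are flagged, not raised.

## Error analysis

Blocking (iterated pairwise block averaging): at each level the
standard error of the block means is recorded; levels stop below 32
blocks.  The plateau is the first level whose estimate agrees with the
next level's within its own uncertainty `σ/√(2(n_b−1))` — an automated
stand-in for plateau-by-eye; when no plateau appears the largest level
estimate is returned with a warning flag (conservative).  The
integrated autocorrelation time uses `τ = 1/2 + Σ ρ(t)` with the
self-consistent window `W ≥ 6τ(W)`; `τ = 0.5` for uncorrelated samples,
and the convention is carried in the result object.  Both estimators
are validated against AR(1) closed forms and against each other
(`blocking ≈ naive·√(2τ)`).

## Study conditions and problem sizes

Headline runs use `N = 200` per chain (D/d ≈ 11), `φ = 0.05`, aspect 4,
discard `2000N = 4×10⁵` iterations, sample every `20N = 4000`.  The
sampling phase is `2×10⁷` iterations (5000 samples).  That length was
set by the slowest mode in the comparison: the axial overlap of the
linear pair has `τ ≈ 10²` samples, and the run must resolve the
ordering `λ/L(lin+lin) > λ/L(circ+lin) > λ/L(circ+circ)` beyond
combined blocking errors; the faster contact-ratio observables are
comfortably converged at that length.  For production use,
`target_tau_samples` extends runs adaptively until the sample count
reaches a chosen multiple (default design point: 200) of the worst
observable's `τ`.

The N=1400 systems (D/d ≈ 22, ≈8-fold and ≈10-fold end-bead boosts)
are hours-scale; they are registered machine-readably in
`REFERENCE_CLAIMS` with `desk_scale=False` and runnable via
`run_reference_claim`.

## What the tests do and do not show

The synthetic fixtures (lattice starts, hand-built micro-systems,
canonical knots/links, AR(1) series) exercise every contract the
simulator relies on, and the micro-system test validates the engine's
sampling distribution against an independent rejection-sampling oracle.
What passing them shows is correctness of the model as specified —
hard beads, freely jointed bonds, athermal moves.  They do not make the
model more biological: DNA stiffness, supercoiling, nucleoid proteins
and osmotic compaction are all outside the model, so quantitative
transfer to real chromosomes is limited to the generic entropic effects
the model isolates.

## Known limitations

* Monte Carlo iterations carry no physical time; only equilibrium
  averages are meaningful, not kinetics.
* The knot detector is determinant-based (see above); a knot with
  determinant 1 would pass, but no such knot is reachable by a single
  undetected crossing event.
* `linking_number` refuses loops closer than `1e-9` of their scale
  (near-singular solid angles); the hard-core constraint keeps
  simulation states far from that regime.
* Packing fails gracefully (with the attempted density reported) for
  very fat beads or extreme volume fractions; side-by-side overlapping
  starts need roughly `φ ≲ 0.3` at moderate N.
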