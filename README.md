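# ringmix

Monte Carlo simulation of two long hard-bead polymer chains — circular
(rings) and/or linear — co-confined in a spherocylindrical container,
built to study a question from bacterial chromosome organisation: the
chromosome is a string of torsionally constrained DNA loops
("topological domains"), and while intact loops behave like mutually
repelling rings that segregate inside the rod-shaped cell, a
double-strand break linearises a loop.  `ringmix` quantifies how that
linearisation switches a co-confined chain pair from the segregated to
the mixed state — the physical precondition for the broken ends to reach
homologous sequences on the sister chromosome during repair.

The package is for polymer/biophysics researchers who want a small,
fully testable reference implementation of this class of simulation:
athermal Metropolis Monte Carlo of pearl-necklace chains with exact
topology control and honest error bars.

## Model

* Container: cylinder of diameter `D` with hemispherical caps, total
  tip-to-tip length `L = 4D` (the aspect ratio of a rod-shaped
  bacterium).  Reduced units: `D = 1`.
* Chains: two pearl necklaces of `N` hard beads of radius `r` each, bond
  length exactly `2r`; each chain circular or linear.  The bead radius
  is solved from `2N · (4/3)πr³ = φ·V` with volume fraction `φ = 0.05`,
  the occupancy of two ~2.2 mm DNA molecules (3 nm effective diameter)
  in a ~0.6 µm³ cell.  As `N` grows at fixed `φ`, chains get thinner:
  `D/d = D/2r` rises from ≈11 (N=200/chain) to ≈22 (N=1400/chain).
* Dynamics: crankshaft Metropolis Monte Carlo.  A move rotates the
  sub-chain between two pivot beads rigidly about the pivot axis;
  segments overshooting a linear chain's end become terminal rotations
  about a random axis.  Hard constraints only (excluded volume, wall):
  a move is accepted iff no constraint is violated.
* Topology: rings must stay unknotted and mutually unlinked (the
  decatenating action of topoisomerases).  Crossings are prevented by
  subdividing each rotation into substeps so no bead moves more than one
  radius at a time and checking the hard core along the swept path;
  exact invariants — the Gauss linking number and the Alexander
  determinant `|Δ(−1)|` — are re-audited throughout every run.

Observables, measured every `20N` iterations after discarding `2000N`:

* overlap length `λ`: the axial extent shared by the two chains' bead
  centres (negative when a gap separates them), reported as `λ/L`;
* contact probabilities at cutoff `3r`: inter-chain, intra-chain
  (non-consecutive pairs), and the same two classes restricted to the
  terminal beads of linear chains.

Error bars come from the blocking method (iterated pairwise block
averaging to a plateau) and integrated autocorrelation times.

## Worked example

```python
from ringmix import RunConfig, run_system, end_boost

common = dict(n=200, total_iterations=400_000 + 5_000_000)
rings = run_system(RunConfig(topologies="circular+circular", seed=11, **common))
mixed = run_system(RunConfig(topologies="circular+linear", seed=12, **common))

m, e, tau = rings.observables["lam_over_L"]
print(f"ring pair   lam/L = {m:.3f} +/- {e:.3f}")
ratio, err = rings.ratios["intra_over_inter"]
print(f"ring pair   p_intra/p_inter = {ratio:.0f} +/- {err:.0f}")
boost, berr = end_boost(mixed, rings)
print(f"end-bead boost (mixed vs ring pair) = {boost:.1f} +/- {berr:.1f}")
```

Output from the run above:

```
ring pair   lam/L = 0.038 +/- 0.006
ring pair   p_intra/p_inter = 110 +/- 10
end-bead boost (mixed vs ring pair) = 6.1 +/- 0.9
```

Read: the two rings barely share any axial extent (segregated state),
an average ring bead is >100× more likely to touch its own chain than
the other ring, and the *terminal* beads of a linearised chain
co-confined with a ring enjoy a ≈6-fold boost of their inter/intra
contact ratio over that ring-pair baseline — the broken ends, not the
whole chain, do the mixing.

A command-line interface mirrors the library: `ringmix simulate
config.json`, `ringmix sweep configs.json`, `ringmix analyze
series.csv`, and `ringmix fixtures` (canonical Hopf-link / trefoil /
figure-eight coordinate files).

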