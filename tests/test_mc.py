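import numpy as np
import pytest

import ringmix as rm
from ringmix.mc import (CrankshaftProposal, MCConfig, attempt_move,
                        propose_crankshaft, run_mc)
from ringmix.polymer import (ChainSpec, SystemState, build_initial_segregated,
                             validate_state)


class FakeRng:
    """Deterministic stand-in for a Generator: feeds scripted draws."""

    def __init__(self, integers=(), randoms=(), uniforms=()):
        self._int = list(integers)
        self._rand = list(randoms)
        self._unif = list(uniforms)

    def integers(self, low, high):
        return self._int.pop(0)

    def random(self):
        return self._rand.pop(0)

    def uniform(self, low, high):
        return self._unif.pop(0)

    def standard_normal(self, size=None):
        return np.array([1.0, 0.0, 0.0]) if size else 1.0


def small_system(geom, n=40, topologies=("circular", "circular"), phi=0.05):
    r = rm.solve_bead_radius(2 * n, phi, geom)
    specs = tuple(ChainSpec(t, n, r) for t in topologies)
    return build_initial_segregated(specs, geom, seed=0)


class TestProposals:
    def test_circular_interior_moved_set(self, geom):
        state = small_system(geom, 40, ("circular", "circular"))
        rng = FakeRng(integers=[0, 5, 3], randoms=[], uniforms=[0.7])
        prop = propose_crankshaft(state, rng, MCConfig(total_iterations=1))
        assert prop.chain == 0 and prop.pivots == (5, 8)
        assert list(prop.moved) == [6, 7]
        assert not prop.terminal

    def test_linear_overshoot_reflects_to_terminal_move(self, geom):
        state = small_system(geom, 200, ("linear", "linear"))
        # chain 0, i=198, s=4, forward direction: pivot 196, moved {197,198,199}
        rng = FakeRng(integers=[0, 198, 4], randoms=[0.2], uniforms=[0.3])
        prop = propose_crankshaft(state, rng, MCConfig(total_iterations=1))
        assert prop.terminal and prop.pivots == (196,)
        assert list(prop.moved) == [197, 198, 199]

    def test_linear_undershoot_mirrors_at_low_end(self, geom):
        state = small_system(geom, 200, ("linear", "linear"))
        rng = FakeRng(integers=[0, 1, 4], randoms=[0.9], uniforms=[0.3])
        prop = propose_crankshaft(state, rng, MCConfig(total_iterations=1))
        assert prop.terminal and prop.pivots == (3,)
        assert list(prop.moved) == [0, 1, 2]

    def test_wrap_pivot_pair_moves_nothing_at_s1(self, geom):
        state = small_system(geom, 40, ("circular", "circular"))
        rng = FakeRng(integers=[1, 7, 1], randoms=[], uniforms=[1.0])
        prop = propose_crankshaft(state, rng, MCConfig(total_iterations=1))
        assert len(prop.moved) == 0


class TestAttemptMove:
    def test_zero_angle_accepted_bitwise_unchanged(self, geom):
        state = small_system(geom, 40)
        before = state.positions.copy()
        prop = CrankshaftProposal(
            chain=0, pivots=(5, 8), theta=0.0, moved=np.array([6, 7]),
            anchor=state.coords[0][5].copy(),
            axis=state.coords[0][8] - state.coords[0][5])
        accepted, state = attempt_move(state, prop)
        assert accepted
        assert np.array_equal(state.positions, before)
        assert state.iteration_count == 1

    def test_wall_violation_rejected_state_unchanged(self, geom):
        state = small_system(geom, 60, ("linear", "linear"))
        before = state.positions.copy()
        # Rotate the terminal segment by a huge angle about an axis that
        # hurls it through the wall: find one by scanning angles.
        spec = state.specs[0]
        rejected = False
        for theta in np.linspace(0.5, np.pi, 8):
            prop = CrankshaftProposal(
                chain=0, pivots=(56,), theta=float(theta),
                moved=np.arange(57, 60), anchor=state.coords[0][56].copy(),
                axis=np.array([1.0, 0.0, 0.0]), terminal=True)
            new = rm.topology.rotate_about_axis(
                state.coords[0][prop.moved], prop.anchor, prop.axis, prop.theta)
            if not state.geometry.contains(new, spec.r).all():
                accepted, state = attempt_move(state, prop)
                assert not accepted
                rejected = True
                break
        assert rejected
        assert np.array_equal(state.positions, before)

    def test_long_python_walk_preserves_invariants(self, geom):
        state = small_system(geom, 30, ("circular", "linear"))
        rng = np.random.default_rng(7)
        config = MCConfig(total_iterations=1)
        accepted = 0
        for _ in range(600):
            prop = propose_crankshaft(state, rng, config)
            ok, state = attempt_move(state, prop)
            accepted += ok
        assert accepted > 0
        assert validate_state(state).ok


class TestRunMC:
    def test_deterministic_series(self, geom):
        results = []
        for _ in range(2):
            state = small_system(geom, 40, ("circular", "linear"))
            cfg = MCConfig(total_iterations=60_000, discard_iterations=10_000,
                           sample_interval=1_000, seed=31, audit_interval=10)
            results.append(run_mc(state, cfg))
        a, b = results
        assert a.accepted == b.accepted
        assert a.samples.equals(b.samples)

    def test_discard_only_run_yields_no_samples(self, geom):
        state = small_system(geom, 40)
        cfg = MCConfig(total_iterations=20_000, discard_iterations=20_000,
                       sample_interval=500, seed=3)
        result = run_mc(state, cfg)
        assert len(result.samples) == 0
        assert result.attempted == 20_000
        assert 0 < result.acceptance_rate <= 1

    def test_state_invariants_hold_after_run(self, geom):
        state = small_system(geom, 60, ("circular", "circular"))
        cfg = MCConfig(total_iterations=150_000, discard_iterations=0,
                       sample_interval=2_000, seed=17, audit_interval=15)
        result = run_mc(state, cfg)
        assert validate_state(state).ok
        assert all(entry["audit"].passed for entry in result.audits)

    def test_bond_lengths_do_not_drift(self, geom):
        state = small_system(geom, 60, ("circular", "linear"))
        cfg = MCConfig(total_iterations=1_000_000, discard_iterations=0,
                       sample_interval=1_000_000, seed=5, audit_interval=0)
        run_mc(state, cfg)
        for spec, pts in zip(state.specs, state.coords):
            bonds = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if spec.topology == "circular":
                bonds = np.append(bonds, np.linalg.norm(pts[0] - pts[-1]))
            assert np.abs(bonds - spec.bond_length).max() < 1e-9 * spec.r

    def test_acceptance_rate_falls_with_density(self, geom):
        rates = []
        for phi in (0.02, 0.05, 0.10):
            state = small_system(geom, 60, ("linear", "linear"), phi=phi)
            cfg = MCConfig(total_iterations=120_000, discard_iterations=20_000,
                           sample_interval=120_000, seed=9)
            rates.append(run_mc(state, cfg).acceptance_rate)
        assert rates[0] > rates[1] > rates[2] > 0
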