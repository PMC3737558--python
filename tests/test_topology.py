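import numpy as np
import pytest

import ringmix as rm
from ringmix import topology as topo
from ringmix.mc import CrankshaftProposal
from ringmix.polymer import ChainSpec, SystemState, build_initial_segregated


class TestLinkingNumber:
    def test_unlinked_circles(self):
        a, b = topo.unlinked_circles()
        assert topo.linking_number(a, b) == 0

    def test_hopf_link(self):
        a, b = topo.hopf_link()
        assert abs(topo.linking_number(a, b)) == 1

    def test_rigid_rotation_invariance(self, rng):
        a, b = topo.hopf_link()
        lk = topo.linking_number(a, b)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        shift = rng.standard_normal(3)
        assert topo.linking_number(a @ q.T + shift, b @ q.T + shift) == lk

    def test_orientation_reversal_antisymmetry(self):
        a, b = topo.hopf_link()
        assert topo.linking_number(a, b[::-1]) == -topo.linking_number(a, b)

    def test_too_close_raises(self):
        a = topo.circle_loop(n=16)
        b = a + np.array([1e-12, 0.0, 0.0])
        with pytest.raises(topo.TopologyError):
            topo.linking_number(a, b)


class TestKnotCheck:
    @pytest.mark.parametrize("n", [3, 5, 12, 40])
    def test_convex_polygon_is_unknot(self, n):
        res = topo.knot_check(topo.circle_loop(n=n))
        assert res.determinant == 1 and res.unknot_compatible

    def test_trefoil_determinant(self):
        assert topo.knot_check(topo.torus_trefoil()).determinant == 3

    def test_figure_eight_determinant(self):
        assert topo.knot_check(topo.figure_eight()).determinant == 5

    def test_twisted_unknot(self):
        # A loop with a full twist (one obligatory crossing pair in most
        # projections) still has determinant 1.
        t = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        pts = np.column_stack([np.sin(t) + 0.9 * np.sin(2 * t),
                               np.cos(t) - 0.9 * np.cos(2 * t),
                               0.4 * np.sin(3 * t)])
        res = topo.knot_check(pts, simplify=False)
        assert res.determinant == 1

    @pytest.mark.parametrize("loop_fn, expected",
                             [(topo.torus_trefoil, 3), (topo.figure_eight, 5)])
    def test_projection_independence(self, loop_fn, expected):
        loop = loop_fn()
        values = {topo.knot_check(loop, seed=seed, simplify=False).determinant
                  for seed in range(20)}
        assert values == {expected}

    def test_simplification_preserves_knot_type(self):
        loop = topo.torus_trefoil(n=120)
        reduced = topo.simplify_loop(loop)
        assert len(reduced) < len(loop)
        assert topo.knot_check(reduced, simplify=False).determinant == 3


def _sweep_fixture():
    """Ring A with a one-bead crankshaft that must sweep through a taut
    segment of ring B one way round, and misses it the other way."""
    r = 0.05
    a = 2 * r
    y0, z0 = 0.0, 0.0
    height = np.sqrt(a * a - (a / 2) ** 2)  # 0.0866: crankshaft radius
    chain_a = np.array([
        [-a / 2, y0, z0], [0.0, y0, z0 - height], [a / 2, y0, z0],
        # remaining beads parked far below, clear of both sweep paths
        [a / 2, y0, z0 - 0.5], [0.0, y0, z0 - 0.6], [-a / 2, y0, z0 - 0.5],
    ])
    # Ring B: taut row through (0, y0 + height, z0) along x, return row far away.
    near = [[x, y0 + height, z0] for x in np.arange(-0.25, 0.26, 0.1)]
    far = [[x, y0 + height, z0 + 1.0] for x in np.arange(0.25, -0.26, -0.1)]
    chain_b = np.array(near + far)
    geometry = rm.ConfinementGeometry(diameter=4.0, aspect=2.0)
    specs = (ChainSpec("circular", len(chain_a), r),
             ChainSpec("circular", len(chain_b), r))
    state = SystemState(geometry, specs, np.vstack([chain_a, chain_b]))

    def proposal(theta):
        return CrankshaftProposal(
            chain=0, pivots=(0, 2), theta=theta, moved=np.array([1]),
            anchor=chain_a[0].copy(), axis=chain_a[2] - chain_a[0])

    return state, proposal


class TestCrossingFree:
    def test_sweep_through_taut_segment_is_blocked(self):
        state, proposal = _sweep_fixture()
        assert not topo.crossing_free(state, proposal(np.pi))

    def test_reverse_sweep_is_allowed(self):
        state, proposal = _sweep_fixture()
        assert topo.crossing_free(state, proposal(-np.pi))

    def test_zero_angle_is_trivially_free(self):
        state, proposal = _sweep_fixture()
        assert topo.crossing_free(state, proposal(0.0))

    def test_endpoints_of_blocked_sweep_are_overlap_free(self):
        # The fixture is only meaningful if the endpoint configuration
        # itself is valid: the collision must happen mid-sweep.
        state, proposal = _sweep_fixture()
        prop = proposal(np.pi)
        end = topo.rotate_about_axis(
            state.coords[0][prop.moved], prop.anchor, prop.axis, prop.theta)
        d = np.linalg.norm(state.coords[1] - end[0], axis=1)
        assert d.min() >= 2 * state.specs[0].r


class TestAudit:
    def test_fresh_state_passes(self, geom):
        r = rm.solve_bead_radius(200, 0.05, geom)
        specs = (ChainSpec("circular", 100, r), ChainSpec("circular", 100, r))
        state = build_initial_segregated(specs, geom, seed=0)
        audit = topo.audit_topology(state)
        assert audit.passed and audit.linking == 0
        assert audit.knot_determinants == [1, 1]

    def test_hopf_linked_state_fails(self):
        a, b = topo.hopf_link(n=24)
        r = 0.01
        geometry = rm.ConfinementGeometry(diameter=10.0, aspect=1.0)
        specs = (ChainSpec("circular", 24, r), ChainSpec("circular", 24, r))
        state = SystemState(geometry, specs, np.vstack([a, b]))
        audit = topo.audit_topology(state)
        assert not audit.passed and abs(audit.linking) == 1

    def test_linear_pair_passes_trivially(self, geom):
        r = rm.solve_bead_radius(120, 0.05, geom)
        specs = (ChainSpec("linear", 60, r), ChainSpec("linear", 60, r))
        state = build_initial_segregated(specs, geom, seed=0)
        audit = topo.audit_topology(state)
        assert audit.passed and audit.linking is None
        assert audit.knot_determinants == []
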