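import math

import numpy as np
import pytest

import ringmix as rm
import oracles
from ringmix.observables import (end_contact_probabilities, fold_boost,
                                 inter_contact_probability,
                                 intra_contact_probability, measure,
                                 overlap_length)
from ringmix.polymer import ChainSpec, SystemState


def pair_state(chain0, chain1, topologies=("linear", "linear"), r=0.05):
    geometry = rm.ConfinementGeometry(diameter=6.0, aspect=2.0)
    specs = (ChainSpec(topologies[0], len(chain0), r),
             ChainSpec(topologies[1], len(chain1), r))
    return SystemState(geometry, specs, np.vstack([chain0, chain1]))


def rod(n, r, z0=0.0, x=0.0):
    return np.array([[x, 0.0, z0 + 2 * r * i] for i in range(n)])


class TestOverlapLength:
    def test_coincident_chains_share_full_extent(self):
        a = rod(5, 0.05)
        state = pair_state(a, a + [0.3, 0.0, 0.0])
        assert overlap_length(state) == pytest.approx(0.4)

    def test_axial_gap_gives_negative_overlap(self):
        state = pair_state(rod(5, 0.05), rod(5, 0.05, z0=0.7, x=0.3))
        assert overlap_length(state) == pytest.approx(-0.3)

    def test_abutting_extents_give_zero(self):
        state = pair_state(rod(5, 0.05), rod(5, 0.05, z0=0.4, x=0.3))
        assert overlap_length(state) == pytest.approx(0.0)

    def test_invariance_under_axial_rotation_and_z_equivariance(self, rng):
        state = pair_state(rng.uniform(-0.4, 0.4, (8, 3)),
                           rng.uniform(-0.4, 0.4, (9, 3)))
        lam = overlap_length(state)
        angle = 1.234
        c, s = math.cos(angle), math.sin(angle)
        q = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
        rotated = pair_state(state.coords[0] @ q.T, state.coords[1] @ q.T)
        assert overlap_length(rotated) == pytest.approx(lam, rel=1e-12)
        flipped = pair_state(state.coords[0] * [1, 1, -1],
                             state.coords[1] * [1, 1, -1])
        assert overlap_length(flipped) == pytest.approx(lam, rel=1e-12)


class TestContactProbabilities:
    def test_two_of_nine_cross_pairs(self):
        r = 0.05
        a = rod(3, r)
        b = a.copy() + [0.5, 0.0, 0.0]
        b[0] = a[0] + [2.5 * r, 0.0, 0.0]   # contact
        b[1] = a[1] + [2.9 * r, 0.0, 0.0]   # contact
        state = pair_state(a, b, r=r)
        expected = oracles.inter_contacts(a, b, 3 * r)
        assert expected == pytest.approx(2 / 9)
        assert inter_contact_probability(state) == expected

    def test_chain_swap_symmetry(self, rng):
        state = oracles.random_pair_state(rng)
        swapped = SystemState(state.geometry, state.specs[::-1],
                              np.vstack([state.coords[1], state.coords[0]]))
        assert inter_contact_probability(state) == \
            inter_contact_probability(swapped)

    def test_straight_rod_has_no_intra_contacts(self):
        r = 0.05
        state = pair_state(rod(20, r), rod(20, r, x=1.0), r=r)
        assert intra_contact_probability(state, 0) == 0.0

    def test_exactly_3r_is_not_a_contact(self):
        r = 0.05
        a = rod(3, r)
        b = a + [3 * r, 0.0, 0.0]
        state = pair_state(a, b, r=r)
        assert inter_contact_probability(state) == 0.0

    @pytest.mark.parametrize("case", range(8))
    def test_matches_exhaustive_oracle_on_small_systems(self, case):
        rng = np.random.default_rng(5000 + case)
        state = oracles.random_pair_state(rng)
        cut = 3 * state.specs[0].r
        assert inter_contact_probability(state) == \
            oracles.inter_contacts(state.coords[0], state.coords[1], cut)
        for c in (0, 1):
            hits, pairs = oracles.intra_contacts(
                state.coords[c], state.specs[c].topology == "circular", cut)
            assert pairs == state.specs[c].n_intra_pairs
            assert intra_contact_probability(state, c) == hits / pairs

    def test_no_inter_contacts_beyond_gap_of_3r(self, rng):
        r = 0.05
        a = rng.uniform(-0.3, 0.3, (12, 3))
        b = rng.uniform(-0.3, 0.3, (12, 3))
        b[:, 2] += (a[:, 2].max() - b[:, 2].min()) + 3.2 * r
        state = pair_state(a, b, r=r)
        assert overlap_length(state) < -3 * r
        assert inter_contact_probability(state) == 0.0


class TestEndContacts:
    def test_straight_isolated_rod_has_zero_end_intra(self):
        r = 0.05
        state = pair_state(rod(10, r), rod(10, r, x=2.0), r=r)
        p_inter, p_intra = end_contact_probabilities(state)
        assert p_intra == 0.0 and p_inter == 0.0

    def test_hand_placed_pair_matches_oracle(self):
        r = 0.05
        a = np.array([[0, 0, 0], [0, 0, 0.1], [0, 0.08, 0.16],
                      [0.09, 0.1, 0.1]])
        b = a + [0.12, 0.0, 0.0]
        state = pair_state(a, b, r=r)
        expected = oracles.end_contacts([a, b], [True, True], 3 * r)
        assert end_contact_probabilities(state) == pytest.approx(expected)

    def test_hairpin_fold_counts_as_contact(self):
        r = 0.05
        pts = rod(6, r)
        pts[5] = pts[3] + [2.5 * r, 0.0, 0.0]  # end folded near bead 3
        state = pair_state(pts, rod(6, r, x=3.0), r=r)
        _, p_intra = end_contact_probabilities(state)
        # 4 ends x 3 eligible partners; exactly one pair is a contact
        assert p_intra == pytest.approx(1 / 12)

    def test_mixed_system_uses_linear_chain_ends_only(self, rng):
        state = oracles.random_pair_state(rng, n0=20, n1=25)
        # Force a mixed system regardless of the random draw.
        specs = (ChainSpec("circular", 20, state.specs[0].r),
                 ChainSpec("linear", 25, state.specs[1].r))
        state = SystemState(state.geometry, specs, state.positions)
        cut = 3 * specs[0].r
        expected = oracles.end_contacts(list(state.coords), [False, True], cut)
        assert end_contact_probabilities(state) == pytest.approx(expected)

    def test_ring_pair_has_no_ends(self, geom):
        r = rm.solve_bead_radius(80, 0.05, geom)
        specs = (ChainSpec("circular", 40, r), ChainSpec("circular", 40, r))
        state = rm.build_initial_segregated(specs, geom)
        with pytest.raises(ValueError):
            end_contact_probabilities(state)
        sample = measure(state)
        assert math.isnan(sample.p_end_inter)


class TestFoldBoost:
    def test_identical_ratios_give_one(self):
        assert fold_boost(0.02, 0.02) == pytest.approx(1.0)

    def test_six_fold(self):
        assert fold_boost(0.06, 0.01) == pytest.approx(6.0)

    def test_argument_order_gives_reciprocal(self):
        assert fold_boost(0.01, 0.06) == pytest.approx(1 / 6)

    def test_zero_denominator_flagged_not_raised(self):
        with pytest.warns(RuntimeWarning):
            assert math.isnan(fold_boost(0.06, 0.0))
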