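"""Independent brute-force oracles used by the test suite.

Every function here is a plain double loop over bead pairs, written
without reference to the package's own counting code, so that the fast
implementations can be checked against an independent enumeration.
"""

import numpy as np


def dist(a, b):
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def inter_contacts(c0, c1, cutoff):
    hits = 0
    for p in c0:
        for q in c1:
            if dist(p, q) < cutoff:
                hits += 1
    return hits / (len(c0) * len(c1))


def intra_contacts(pts, circular, cutoff):
    n = len(pts)
    hits = pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            consecutive = (j - i == 1) or (circular and i == 0 and j == n - 1)
            if consecutive:
                continue
            pairs += 1
            if dist(pts[i], pts[j]) < cutoff:
                hits += 1
    return hits, pairs


def end_contacts(chains, linear_flags, cutoff):
    """(p_end_inter, p_end_intra) averaged over all ends of all linear
    chains, with the internal-bead convention: both terminals and the
    bead adjacent to the probed end are excluded from intra partners."""
    inter_hits = inter_pairs = intra_hits = intra_pairs = 0
    for c, (pts, linear) in enumerate(zip(chains, linear_flags)):
        if not linear:
            continue
        other = chains[1 - c]
        n = len(pts)
        for end, adjacent in ((0, 1), (n - 1, n - 2)):
            for q in other:
                inter_pairs += 1
                if dist(pts[end], q) < cutoff:
                    inter_hits += 1
            for j in range(1, n - 1):
                if j == adjacent:
                    continue
                intra_pairs += 1
                if dist(pts[end], pts[j]) < cutoff:
                    intra_hits += 1
    p_inter = inter_hits / inter_pairs
    p_intra = intra_hits / intra_pairs if intra_pairs else float("nan")
    return p_inter, p_intra


def random_pair_state(rng, n0=None, n1=None, r=0.05, box=0.6):
    """A random (not necessarily physical) two-chain configuration for
    exercising the contact counters; chains with <= 50 beads."""
    import ringmix as rm
    from ringmix.polymer import ChainSpec, SystemState

    n0 = n0 or int(rng.integers(4, 51))
    n1 = n1 or int(rng.integers(4, 51))
    t0 = "circular" if rng.random() < 0.5 else "linear"
    t1 = "circular" if rng.random() < 0.5 else "linear"
    specs = (ChainSpec(t0, n0, r), ChainSpec(t1, n1, r))
    pts = rng.uniform(-box, box, size=(n0 + n1, 3))
    geometry = rm.ConfinementGeometry(diameter=4.0, aspect=2.0)
    return SystemState(geometry, specs, pts)
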