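"""Measured quantities: axial overlap length and contact probabilities.

The axial overlap length ``lambda`` is the length of the z interval
shared by the two chains' bead centres: negative when an empty zone
separates the chains, zero when their extents just touch, and up to the
full container length when they mix completely.  It is reported both raw
and normalised by the total container length ``L``.

Two beads are *in contact* when their centre distance is strictly
smaller than ``3 r``.  Four pair populations are distinguished:

* inter-chain — all pairs with one bead in each chain;
* intra-chain — all non-consecutive same-chain pairs;
* end-bead inter-chain — pairs of one terminal bead of a linear chain
  with any bead of the other chain;
* end-bead intra-chain — pairs of a terminal bead with the internal,
  non-consecutive beads of its own chain.

"Internal" excludes both terminal beads, and "non-consecutive" further
excludes the bead bonded to the probed end, so each end has ``N - 3``
eligible intra partners.  Both ends contribute and are averaged.  The
choice to exclude the opposite terminal bead is isolated in
:func:`_end_intra_partners` so it can be flipped in one place.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist

from .polymer import TOP_CIRCULAR, TOP_LINEAR, SystemState

__all__ = [
    "ObservableSample",
    "overlap_length",
    "inter_contact_probability",
    "intra_contact_probability",
    "end_contact_probabilities",
    "fold_boost",
    "measure",
]


@dataclass(frozen=True)
class ObservableSample:
    """One measurement record."""

    iteration: int
    lam: float
    lam_over_L: float
    p_inter: float
    p_intra: float
    p_end_inter: float
    p_end_intra: float

    def as_dict(self) -> dict:
        return asdict(self)


def overlap_length(state: SystemState) -> float:
    """Axial overlap ``min(zmax_1, zmax_2) - max(zmin_1, zmin_2)`` over
    bead centres; negative when a gap separates the chains."""
    z0 = state.coords[0][:, 2]
    z1 = state.coords[1][:, 2]
    return float(min(z0.max(), z1.max()) - max(z0.min(), z1.min()))


def _cutoff(state: SystemState) -> float:
    return 3.0 * state.specs[0].r


def inter_contact_probability(state: SystemState) -> float:
    """Fraction of inter-chain pairs in contact (distance < 3r)."""
    d = cdist(state.coords[0], state.coords[1])
    return float((d < _cutoff(state)).sum() / d.size)


def _intra_counts(state: SystemState, chain: int):
    spec = state.specs[chain]
    pts = state.coords[chain]
    n = spec.n
    d = cdist(pts, pts)
    i, j = np.triu_indices(n, k=2)
    keep = np.ones(len(i), dtype=bool)
    if spec.topology == TOP_CIRCULAR:
        keep &= ~((i == 0) & (j == n - 1))  # the wrap pair is bonded
    contacts = int((d[i[keep], j[keep]] < _cutoff(state)).sum())
    return contacts, int(keep.sum())


def intra_contact_probability(state: SystemState, chain: int) -> float:
    """Fraction of non-consecutive same-chain pairs in contact.

    Denominator: ``N(N-3)/2`` for circular chains (the wrap pair counts
    as consecutive), ``(N-1)(N-2)/2`` for linear chains.
    """
    contacts, pairs = _intra_counts(state, chain)
    assert pairs == state.specs[chain].n_intra_pairs
    return contacts / pairs


def _end_intra_partners(n: int, end: int) -> np.ndarray:
    """Eligible intra partners of terminal bead ``end``: internal beads
    (both terminals excluded) that are not bonded to the probed end."""
    if end == 0:
        return np.arange(2, n - 1)
    return np.arange(1, n - 2)


def end_contact_probabilities(state: SystemState):
    """End-bead contact probabilities ``(p_end_inter, p_end_intra)``.

    Averages over every terminal bead of every linear chain in the
    system.  Raises on circular-circular systems, which have no ends.
    """
    linear = [c for c, s in enumerate(state.specs) if s.topology == TOP_LINEAR]
    if not linear:
        raise ValueError("end-bead observables need at least one linear chain")
    cut = _cutoff(state)
    inter_contacts = inter_pairs = 0
    intra_contacts = intra_pairs = 0
    for c in linear:
        pts = state.coords[c]
        other = state.coords[1 - c]
        n = state.specs[c].n
        for end in (0, n - 1):
            d_inter = np.linalg.norm(other - pts[end], axis=1)
            inter_contacts += int((d_inter < cut).sum())
            inter_pairs += len(other)
            partners = _end_intra_partners(n, end)
            d_intra = np.linalg.norm(pts[partners] - pts[end], axis=1)
            intra_contacts += int((d_intra < cut).sum())
            intra_pairs += len(partners)
    p_end_intra = (intra_contacts / intra_pairs if intra_pairs
                   else math.nan)  # chains of < 4 beads have no internal partners
    return inter_contacts / inter_pairs, p_end_intra


def fold_boost(end_ratio: float, avg_ratio: float) -> float:
    """How many times larger the end-bead inter/intra contact ratio of
    one system is than the average-bead inter/intra ratio of another."""
    if not (math.isfinite(end_ratio) and math.isfinite(avg_ratio)) \
            or avg_ratio <= 0 or end_ratio <= 0:
        warnings.warn("fold boost is not computable: a contact ratio is "
                      "zero or non-finite", RuntimeWarning)
        return math.nan
    return end_ratio / avg_ratio


def measure(state: SystemState) -> ObservableSample:
    """All standard observables of one configuration."""
    lam = overlap_length(state)
    L = state.geometry.total_length
    c0, p0 = _intra_counts(state, 0)
    c1, p1 = _intra_counts(state, 1)
    has_linear = any(s.topology == TOP_LINEAR for s in state.specs)
    if has_linear:
        p_end_inter, p_end_intra = end_contact_probabilities(state)
    else:
        p_end_inter = p_end_intra = math.nan
    return ObservableSample(
        iteration=state.iteration_count,
        lam=lam,
        lam_over_L=lam / L,
        p_inter=inter_contact_probability(state),
        p_intra=(c0 + c1) / (p0 + p1),
        p_end_inter=p_end_inter,
        p_end_intra=p_end_intra,
    )
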