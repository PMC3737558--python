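"""Topological invariants and chain-crossing prevention.

Tangent hard beads (bond length equal to the bead diameter) form an
impenetrable tube, so a *continuous* motion of one chain can never pass
through another without creating a hard-core overlap at some instant.
Discrete Monte Carlo rotations, however, can jump straight through a
chain.  Two defences are used here:

* :func:`crossing_free` subdivides a proposed rotation into angular
  substeps small enough that no bead moves further than one bead radius
  per substep, and requires the hard-core condition to hold at every
  intermediate configuration.  A crossing would have to step over the
  overlap window undetected, which the displacement bound forbids.
* :func:`audit_topology` periodically recomputes exact invariants — the
  Gauss linking number between circular chains and a knot detector for
  each circular chain — so that any soundness gap in the per-move test
  would be caught.

The knot detector is the Alexander determinant ``|Delta(-1)|`` computed
from the crossing data of a generic planar projection (1 for the unknot,
3 for the trefoil, 5 for the figure-eight knot).  It is not a complete
invariant, but it separates the unknot from every knot reachable by a
rare undetected strand passage in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from bisect import bisect_right

import numpy as np

__all__ = [
    "TopologyError",
    "KnotCheckResult",
    "TopologyAudit",
    "rotate_about_axis",
    "linking_number",
    "simplify_loop",
    "knot_check",
    "crossing_free",
    "audit_topology",
    "hopf_link",
    "unlinked_circles",
    "torus_trefoil",
    "figure_eight",
    "circle_loop",
]

# Two large primes for exact modular determinants; agreement between the
# residues identifies small determinant values with negligible ambiguity.
_P1 = 1_000_000_007
_P2 = 998_244_353


class TopologyError(RuntimeError):
    """Raised when an invariant cannot be evaluated reliably."""


def rotate_about_axis(points: np.ndarray, anchor: np.ndarray, axis: np.ndarray,
                      theta: float) -> np.ndarray:
    """Rotate ``points`` rigidly by ``theta`` about the line through
    ``anchor`` with direction ``axis`` (Rodrigues formula)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0.0:
        raise ValueError("rotation axis has zero length")
    u = axis / norm
    p = np.atleast_2d(points) - anchor
    c, s = np.cos(theta), np.sin(theta)
    cross = np.cross(np.broadcast_to(u, p.shape), p)
    dot = p @ u
    rotated = p * c + cross * s + np.outer(dot, u) * (1.0 - c)
    return rotated + anchor


# ---------------------------------------------------------------------------
# Gauss linking number
# ---------------------------------------------------------------------------

def linking_number(loop_a: np.ndarray, loop_b: np.ndarray) -> int:
    """Exact Gauss linking number of two closed polygonal curves.

    Sums, over every pair of segments (one from each loop), the signed
    solid angle the pair contributes to the Gauss double integral and
    divides by ``4 pi``.  The result is rounded to the nearest integer;
    a residual above 0.2 or a near-singular segment pair (the loops
    closer than ``1e-9`` times their scale) raises :class:`TopologyError`.
    """
    a = np.asarray(loop_a, dtype=float)
    b = np.asarray(loop_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or len(a) < 3:
        raise ValueError("loop_a must be an (n>=3, 3) array")
    if b.ndim != 2 or b.shape[1] != 3 or len(b) < 3:
        raise ValueError("loop_b must be an (n>=3, 3) array")

    a1 = a
    a2 = np.roll(a, -1, axis=0)
    b1 = b
    b2 = np.roll(b, -1, axis=0)

    # Pairwise endpoint difference vectors, shape (na, nb, 3).
    r13 = b1[None, :, :] - a1[:, None, :]
    r14 = b2[None, :, :] - a1[:, None, :]
    r23 = b1[None, :, :] - a2[:, None, :]
    r24 = b2[None, :, :] - a2[:, None, :]

    scale = max(np.ptp(a, axis=0).max(), np.ptp(b, axis=0).max(), 1e-300)
    for rr in (r13, r14, r23, r24):
        d = np.sqrt((rr * rr).sum(axis=2))
        if d.min() < 1e-9 * scale:
            raise TopologyError("loops pass within 1e-9 of each other; linking "
                                "number cannot be evaluated")

    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)

    def _unit(v):
        norm = np.sqrt((v * v).sum(axis=2, keepdims=True))
        small = norm < 1e-14 * scale * scale
        norm = np.where(small, 1.0, norm)
        return v / norm

    n1, n2, n3, n4 = _unit(n1), _unit(n2), _unit(n3), _unit(n4)

    def _asin_dot(u, v):
        d = np.clip((u * v).sum(axis=2), -1.0, 1.0)
        return np.arcsin(d)

    omega = (_asin_dot(n1, n2) + _asin_dot(n2, n3)
             + _asin_dot(n3, n4) + _asin_dot(n4, n1))

    seg_a = a2 - a1
    seg_b = b2 - b1
    sign = np.sign((np.cross(seg_b[None, :, :], seg_a[:, None, :]) * r13).sum(axis=2))
    lk = (omega * sign).sum() / (4.0 * np.pi)

    nearest = round(lk)
    if abs(lk - nearest) > 0.2:
        raise TopologyError(f"linking number sum {lk:.4f} is not close to an integer")
    return int(nearest)


# ---------------------------------------------------------------------------
# Loop simplification (isotopy-preserving vertex removal)
# ---------------------------------------------------------------------------

def _segments_hit_triangle(p0, p1, p2, seg_a, seg_b, eps):
    """Boolean array: does each 3D segment intersect triangle (p0,p1,p2)?

    Conservative Moller-Trumbore: near-degenerate hits count as hits, so
    callers that *skip* an action on a hit stay safe.
    """
    e1 = p1 - p0
    e2 = p2 - p0
    d = seg_b - seg_a
    h = np.cross(d, e2)
    det = h @ e1
    area_n = np.cross(e1, e2)
    area = np.linalg.norm(area_n)
    if area < eps * eps:
        # Degenerate (collinear) triangle spans no surface.
        return np.zeros(len(seg_a), dtype=bool)
    parallel = np.abs(det) < 1e-12 * area
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(parallel, 0.0, 1.0 / np.where(parallel, 1.0, det))
        s = seg_a - p0
        u = ((s * h).sum(axis=1)) * inv
        q = np.cross(s, e1)
        v = ((d * q).sum(axis=1)) * inv
        t = (q @ e2) * inv
    tol = 1e-9
    hit = (~parallel
           & (u >= -tol) & (v >= -tol) & (u + v <= 1.0 + tol)
           & (t >= -tol) & (t <= 1.0 + tol))
    # Parallel segments lying in the triangle plane are rare; treat a
    # parallel segment whose endpoints straddle or touch the plane as a hit
    # so the caller behaves conservatively.
    if parallel.any():
        nrm = area_n / area
        da = (seg_a - p0) @ nrm
        db = (seg_b - p0) @ nrm
        coplanarish = (np.abs(da) < tol) | (np.abs(db) < tol) | (da * db < 0)
        hit |= parallel & coplanarish
    return hit


def simplify_loop(loop: np.ndarray, max_passes: int = 100) -> np.ndarray:
    """Reduce a closed polygon by knot-type-preserving vertex removals.

    A vertex is removed when the triangle spanned by it and its two
    neighbours is not pierced by any other segment of the loop; sliding
    the two edges across that empty triangle onto the chord is then an
    isotopy.  Equilibrated confined rings typically collapse to a
    triangle, which makes the subsequent projection-based knot check
    cheap and numerically robust.
    """
    pts = np.asarray(loop, dtype=float).copy()
    scale = max(np.ptp(pts, axis=0).max(), 1e-300)
    for _ in range(max_passes):
        n = len(pts)
        if n <= 4:
            break
        removed_any = False
        i = 0
        while i < len(pts) and len(pts) > 4:
            n = len(pts)
            im1 = (i - 1) % n
            ip1 = (i + 1) % n
            tri = (pts[im1], pts[i], pts[ip1])
            # segments not sharing a vertex with the triangle
            idx = np.arange(n)
            nxt = (idx + 1) % n
            excluded = np.isin(idx, [(i - 2) % n, im1, i, ip1])
            seg_a = pts[idx[~excluded]]
            seg_b = pts[nxt[~excluded]]
            if len(seg_a) == 0 or not _segments_hit_triangle(
                    tri[0], tri[1], tri[2], seg_a, seg_b, 1e-12 * scale).any():
                pts = np.delete(pts, i, axis=0)
                removed_any = True
            else:
                i += 1
        if not removed_any:
            break
    return pts


# ---------------------------------------------------------------------------
# Knot detection: Alexander determinant at t = -1
# ---------------------------------------------------------------------------

def _det_mod(matrix: np.ndarray, p: int) -> int:
    """Determinant of an integer matrix modulo prime ``p`` (Gaussian
    elimination over GF(p); exact for arbitrary matrix size)."""
    m = np.mod(matrix.astype(np.int64), p)
    n = m.shape[0]
    if n == 0:
        return 1
    det = 1
    for col in range(n):
        pivot_rows = np.nonzero(m[col:, col])[0]
        if len(pivot_rows) == 0:
            return 0
        pr = col + int(pivot_rows[0])
        if pr != col:
            m[[col, pr]] = m[[pr, col]]
            det = (-det) % p
        pivot = int(m[col, col])
        det = (det * pivot) % p
        inv = pow(pivot, p - 2, p)
        rows = m[col + 1:, col]
        nz = np.nonzero(rows)[0]
        if len(nz):
            factors = (rows[nz] * inv) % p
            m[col + 1 + nz, col:] = np.mod(
                m[col + 1 + nz, col:] - factors[:, None] * m[col, col:], p)
    return int(det % p)


def _project_crossings(pts: np.ndarray, rng: np.random.Generator):
    """Crossing data of a random generic planar projection.

    Returns a list of crossings ``(under_pos, over_pos)`` where each
    position is the scalar ``segment_index + parameter`` along the loop,
    or ``None`` if the projection was degenerate and must be retried.
    """
    n = len(pts)
    # Random rotation: QR of a Gaussian matrix gives a Haar orthogonal Q.
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    xyz = pts @ q.T
    xy = xyz[:, :2]
    depth = xyz[:, 2]
    scale = max(np.ptp(xy, axis=0).max(), 1e-300)
    eps_par = 1e-10
    tol = 1e-7

    a1 = xy
    a2 = np.roll(xy, -1, axis=0)
    d = a2 - a1

    crossings = []
    for i in range(n):
        js = np.arange(i + 2, n if i > 0 else n - 1)
        if len(js) == 0:
            continue
        r = a1[js] - a1[i]
        denom = d[i, 0] * d[js, 1] - d[i, 1] * d[js, 0]
        parallel = np.abs(denom) < eps_par * scale * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(parallel, -1.0,
                         (r[:, 0] * d[js, 1] - r[:, 1] * d[js, 0]) / denom)
            t = np.where(parallel, -1.0,
                         (r[:, 0] * d[i, 1] - r[:, 1] * d[i, 0]) / denom)
        inside = (s > 0) & (s < 1) & (t > 0) & (t < 1)
        in_range = (s > -tol) & (s < 1 + tol) & (t > -tol) & (t < 1 + tol)
        near_edge = in_range & (
            ((s > -tol) & (s < tol)) | ((s > 1 - tol) & (s < 1 + tol))
            | ((t > -tol) & (t < tol)) | ((t > 1 - tol) & (t < 1 + tol)))
        if (near_edge & ~parallel).any():
            return None  # intersection too close to a vertex: retry
        for k in np.nonzero(inside)[0]:
            j = int(js[k])
            zi = depth[i] + s[k] * (depth[(i + 1) % n] - depth[i])
            zj = depth[j] + t[k] * (depth[(j + 1) % n] - depth[j])
            if abs(zi - zj) < 1e-12 * max(scale, 1.0):
                return None  # ambiguous over/under: retry
            pos_i = i + float(s[k])
            pos_j = j + float(t[k])
            if zi > zj:
                crossings.append((pos_j, pos_i))   # j under, i over
            else:
                crossings.append((pos_i, pos_j))
    return crossings


@dataclass(frozen=True)
class KnotCheckResult:
    """Outcome of the planar-projection knot detector."""

    determinant: int
    unknot_compatible: bool
    crossings: int
    simplified_vertices: int

    def __bool__(self) -> bool:  # truthy iff compatible with the unknot
        return self.unknot_compatible


def knot_check(loop: np.ndarray, seed: int = 0, max_retries: int = 25,
               simplify: bool = True) -> KnotCheckResult:
    """Knot detector: Alexander determinant ``|Delta(-1)|`` of a closed
    polygon, from the crossing data of a generic planar projection.

    The loop is first reduced by :func:`simplify_loop` (an isotopy, so the
    knot type is unchanged), then projected along a seeded random
    direction; degenerate projections are re-drawn up to ``max_retries``
    times.  The determinant is evaluated exactly by modular arithmetic.
    A value of 1 is compatible with the unknot; the trefoil gives 3 and
    the figure-eight knot 5.
    """
    pts = np.asarray(loop, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("loop must be an (n>=3, 3) array")
    if simplify:
        pts = simplify_loop(pts)
    rng = np.random.default_rng(seed)
    crossings = None
    for _ in range(max_retries):
        crossings = _project_crossings(pts, rng)
        if crossings is not None:
            break
    if crossings is None:
        raise TopologyError("no generic projection found after "
                            f"{max_retries} perturbation attempts")

    m = len(crossings)
    if m <= 1:
        # Zero crossings is an embedded plane curve; one crossing is
        # always removable (first Reidemeister move).
        return KnotCheckResult(1, True, m, len(pts))

    # Arcs: the loop is cut at every underpass; arc k runs from the k-th
    # underpass (in loop order) to the next one.
    under_positions = sorted(c[0] for c in crossings)

    def arc_of(pos: float) -> int:
        idx = bisect_right(under_positions, pos) - 1
        return idx % m

    rows = np.zeros((m, m), dtype=np.int64)
    for k, (under_pos, over_pos) in enumerate(crossings):
        out_arc = arc_of(under_pos + 1e-12)        # arc starting here
        in_arc = (out_arc - 1) % m                 # arc ending here
        over_arc = arc_of(over_pos)
        # Wirtinger relation abelianised at t = -1; the crossing sign only
        # changes the row by a unit and cannot affect |det|.
        rows[k, over_arc] += 2
        rows[k, in_arc] -= 1
        rows[k, out_arc] -= 1

    minor = rows[:-1, :-1]
    d1 = _det_mod(minor, _P1)
    d2 = _det_mod(minor, _P2)
    v1 = min(d1, _P1 - d1)
    v2 = min(d2, _P2 - d2)
    if v1 != v2:
        # Determinant too large to identify through the residues: it is
        # certainly not 1, which is all the audit needs.
        return KnotCheckResult(max(v1, v2), False, m, len(pts))
    return KnotCheckResult(v1, v1 == 1, m, len(pts))


# ---------------------------------------------------------------------------
# Swept-move crossing prevention
# ---------------------------------------------------------------------------

def substep_count(radius_max: float, bead_radius: float, theta: float) -> int:
    """Number of equal angular substeps needed so the largest bead
    displacement per substep (chord ``2 R sin(dtheta/2)``) stays below one
    bead radius."""
    if radius_max <= 0.0 or theta == 0.0:
        return 1
    arg = min(1.0, 0.999 * bead_radius / (2.0 * radius_max))
    dtheta = 2.0 * np.arcsin(arg)
    return max(1, int(np.ceil(abs(theta) / dtheta)))


def _topology_partners(state, chain: int) -> np.ndarray:
    """Global indices of beads whose mutual topology with ``chain`` is a
    conserved quantity: the chain itself if circular, plus any *other*
    circular chain (linking number conservation)."""
    from .polymer import TOP_CIRCULAR  # local import avoids a cycle

    offsets = state.chain_offsets()
    keep = []
    for c, spec in enumerate(state.specs):
        if spec.topology != TOP_CIRCULAR:
            continue
        if c == chain or state.specs[chain].topology == TOP_CIRCULAR:
            keep.append(np.arange(offsets[c], offsets[c] + spec.n))
    if not keep:
        return np.empty(0, dtype=int)
    return np.concatenate(keep)


def crossing_free(state, proposal) -> bool:
    """True iff the swept path of a proposed rotation never violates the
    hard-core condition against topology-conserving partner beads.

    The proposal's endpoint configuration is assumed to have passed the
    excluded-volume and wall tests already; this routine checks the
    intermediate configurations at displacement-bounded angular substeps.
    Moves on a linear chain in a system without a second circular chain
    conserve no topological invariant and are trivially crossing-free.
    """
    from .polymer import TOP_CIRCULAR

    moved = np.asarray(proposal.moved, dtype=int)
    if len(moved) == 0 or proposal.theta == 0.0:
        return True
    spec = state.specs[proposal.chain]
    if spec.topology != TOP_CIRCULAR:
        other = state.specs[1 - proposal.chain]
        if other.topology != TOP_CIRCULAR:
            return True
        # Crossing a linear chain through a ring threads/unthreads it, which
        # is reachable by continuous motion anyway: no invariant to protect.
        return True

    coords = state.all_coords()
    partners = _topology_partners(state, proposal.chain)
    offsets = state.chain_offsets()
    moved_global = moved + offsets[proposal.chain]
    static = np.setdiff1d(partners, moved_global, assume_unique=False)
    if len(static) == 0:
        return True

    r = spec.r
    pts = coords[moved_global]
    # Perpendicular distances to the rotation axis set the chord bound.
    axis = np.asarray(proposal.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rel = pts - proposal.anchor
    perp = rel - np.outer(rel @ axis, axis)
    r_max = float(np.sqrt((perp * perp).sum(axis=1)).max())
    nsub = substep_count(r_max, r, proposal.theta)
    if nsub <= 1:
        return True

    bonded = _bonded_pairs_mask(state, moved_global, static)
    static_pts = coords[static]
    limit2 = (2.0 * r) ** 2 * (1.0 - 1e-10)
    for k in range(1, nsub):
        inter = rotate_about_axis(pts, proposal.anchor, axis,
                                  proposal.theta * k / nsub)
        d2 = ((inter[:, None, :] - static_pts[None, :, :]) ** 2).sum(axis=2)
        d2[bonded] = np.inf
        if (d2 < limit2).any():
            return False
    return True


def _bonded_pairs_mask(state, moved_global: np.ndarray, static_global: np.ndarray):
    """Mask (moved x static) of bonded pairs, to exempt them from the
    hard-core test (consecutive beads are exactly tangent by construction)."""
    from .polymer import TOP_CIRCULAR

    offsets = state.chain_offsets()
    mask = np.zeros((len(moved_global), len(static_global)), dtype=bool)
    for c, spec in enumerate(state.specs):
        lo, hi = offsets[c], offsets[c] + spec.n
        mi = (moved_global >= lo) & (moved_global < hi)
        si = (static_global >= lo) & (static_global < hi)
        if not mi.any() or not si.any():
            continue
        a = moved_global[mi] - lo
        b = static_global[si] - lo
        diff = np.abs(a[:, None] - b[None, :])
        bonded = diff == 1
        if spec.topology == TOP_CIRCULAR:
            bonded |= diff == spec.n - 1
        mask[np.ix_(mi, si)] = bonded
    return mask


# ---------------------------------------------------------------------------
# Periodic invariant audit
# ---------------------------------------------------------------------------

@dataclass
class TopologyAudit:
    """Result of one invariant audit of a system state."""

    passed: bool
    linking: int | None = None
    knot_determinants: list = field(default_factory=list)
    messages: list = field(default_factory=list)


def audit_topology(state, seed: int = 0) -> TopologyAudit:
    """Assert zero linking between circular chains and unknottedness of
    every circular chain.  Systems without circular chains pass trivially.
    """
    from .polymer import TOP_CIRCULAR

    audit = TopologyAudit(passed=True)
    circular = [c for c, spec in enumerate(state.specs)
                if spec.topology == TOP_CIRCULAR]
    for c in circular:
        res = knot_check(state.coords[c], seed=seed)
        audit.knot_determinants.append(res.determinant)
        if not res.unknot_compatible:
            audit.passed = False
            audit.messages.append(
                f"chain {c} knot determinant {res.determinant} != 1")
    if len(circular) == 2:
        lk = linking_number(state.coords[circular[0]], state.coords[circular[1]])
        audit.linking = lk
        if lk != 0:
            audit.passed = False
            audit.messages.append(f"linking number {lk} != 0")
    return audit


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

def circle_loop(center=(0.0, 0.0, 0.0), radius: float = 1.0, normal: str = "z",
                n: int = 64) -> np.ndarray:
    """Regular polygon approximating a circle, in the plane normal to one
    of the coordinate axes."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    c, s = np.cos(t) * radius, np.sin(t) * radius
    z = np.zeros(n)
    if normal == "z":
        pts = np.column_stack([c, s, z])
    elif normal == "y":
        pts = np.column_stack([c, z, s])
    elif normal == "x":
        pts = np.column_stack([z, c, s])
    else:
        raise ValueError("normal must be 'x', 'y' or 'z'")
    return pts + np.asarray(center, dtype=float)


def hopf_link(n: int = 64):
    """The canonical Hopf link: unit circle in the xy plane at the origin
    and unit circle in the xz plane centred at (1, 0, 0); linking +/-1."""
    return circle_loop((0, 0, 0), 1.0, "z", n), circle_loop((1, 0, 0), 1.0, "y", n)


def unlinked_circles(separation: float = 10.0, n: int = 64):
    """Two coaxial unit circles far apart; linking number 0."""
    return (circle_loop((0, 0, 0), 1.0, "z", n),
            circle_loop((separation, 0, 0), 1.0, "z", n))


def torus_trefoil(n: int = 60) -> np.ndarray:
    """Polygonal trefoil knot ((2,3) torus knot); determinant 3."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = (2.0 + np.cos(3 * t)) * np.cos(2 * t)
    y = (2.0 + np.cos(3 * t)) * np.sin(2 * t)
    z = np.sin(3 * t)
    return np.column_stack([x, y, z])


def figure_eight(n: int = 80) -> np.ndarray:
    """Polygonal figure-eight knot; determinant 5."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = (2.0 + np.cos(2 * t)) * np.cos(3 * t)
    y = (2.0 + np.cos(2 * t)) * np.sin(3 * t)
    z = np.sin(4 * t)
    return np.column_stack([x, y, z])
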