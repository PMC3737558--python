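"""Bead chains, system state, and initial-configuration builders.

A chain is a pearl necklace: ``N`` hard spheres of radius ``r`` whose
consecutive centres sit at exactly ``2r``, either closed into a ring
(``circular``) or open (``linear``).  The full simulation state is two
such chains plus the confining geometry.

Initial configurations are built deterministically by packing each chain
onto a cubic lattice of spacing ``2r`` inside the container, following a
serpentine (boustrophedon) route; rings are closed as pairs of mirrored
serpentine strands joined by single lattice bonds.  The lattice start is
far from equilibrium but satisfies every state invariant exactly, and
the Monte Carlo discard phase performs the randomising burn-in.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .geometry import ConfinementGeometry, ConfigurationError

TOP_CIRCULAR = "circular"
TOP_LINEAR = "linear"

__all__ = [
    "TOP_CIRCULAR",
    "TOP_LINEAR",
    "ChainSpec",
    "SystemState",
    "PackingError",
    "Violation",
    "StateReport",
    "build_initial_segregated",
    "build_initial_overlapping",
    "validate_state",
    "write_xyz",
    "read_xyz",
    "save_state_json",
    "load_state_json",
]


class PackingError(RuntimeError):
    """Raised when a chain cannot be packed into its assigned region."""


@dataclass(frozen=True)
class ChainSpec:
    """One chain: topology, bead count and bead radius (reduced units)."""

    topology: str
    n: int
    r: float

    def __post_init__(self) -> None:
        if self.topology not in (TOP_CIRCULAR, TOP_LINEAR):
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        minimum = 3 if self.topology == TOP_CIRCULAR else 2
        if self.n < minimum:
            raise ConfigurationError(
                f"{self.topology} chain needs at least {minimum} beads, got {self.n}")
        if self.r <= 0:
            raise ConfigurationError(f"bead radius must be positive, got {self.r}")

    @property
    def bond_length(self) -> float:
        return 2.0 * self.r

    @property
    def n_intra_pairs(self) -> int:
        """Number of non-consecutive same-chain pairs (the intra-chain
        contact denominator): ``N(N-3)/2`` circular, ``(N-1)(N-2)/2`` linear."""
        if self.topology == TOP_CIRCULAR:
            return self.n * (self.n - 3) // 2
        return (self.n - 1) * (self.n - 2) // 2


@dataclass
class SystemState:
    """Two bead chains in a spherocylinder.

    ``positions`` stores all bead centres contiguously (chain 0 first);
    ``coords`` exposes per-chain views into the same memory.
    """

    geometry: ConfinementGeometry
    specs: tuple
    positions: np.ndarray
    iteration_count: int = 0

    def __post_init__(self) -> None:
        self.specs = tuple(self.specs)
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        if self.positions.shape != (self.n_beads, 3):
            raise ConfigurationError(
                f"positions shape {self.positions.shape} does not match specs "
                f"({self.n_beads} beads expected)")

    @property
    def n_beads(self) -> int:
        return sum(s.n for s in self.specs)

    def chain_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum([s.n for s in self.specs])[:-1]])

    @property
    def coords(self):
        out = []
        off = 0
        for s in self.specs:
            out.append(self.positions[off:off + s.n])
            off += s.n
        return tuple(out)

    def all_coords(self) -> np.ndarray:
        return self.positions

    def copy(self) -> "SystemState":
        return SystemState(self.geometry, self.specs, self.positions.copy(),
                           self.iteration_count)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    kind: str            # "bond", "overlap", "confinement", "topology"
    chain: int | None
    indices: tuple
    magnitude: float
    message: str


@dataclass
class StateReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok

    def summary(self) -> str:
        if self.ok:
            return "state valid"
        return "; ".join(v.message for v in self.violations)


def _bonded_pairs(spec: ChainSpec):
    i = np.arange(spec.n - 1)
    pairs = np.column_stack([i, i + 1])
    if spec.topology == TOP_CIRCULAR:
        pairs = np.vstack([pairs, [spec.n - 1, 0]])
    return pairs


def validate_state(state: SystemState, check_topology: bool = True,
                   max_report: int = 20) -> StateReport:
    """Check every state invariant and report violations.

    Checks bond lengths (``2r`` within ``1e-9 r``), the hard-core
    condition for all non-bonded pairs, whole-bead confinement, and (for
    circular chains, if ``check_topology``) zero linking number and
    unknottedness.  Consecutive beads are exempt from the hard-core test:
    their distance is pinned at exactly ``2r`` by construction.
    """
    from . import topology as topo

    report = StateReport()
    geom = state.geometry
    offsets = state.chain_offsets()

    for c, spec in enumerate(state.specs):
        pts = state.coords[c]
        pairs = _bonded_pairs(spec)
        d = np.linalg.norm(pts[pairs[:, 1]] - pts[pairs[:, 0]], axis=1)
        bad = np.nonzero(np.abs(d - spec.bond_length) > 1e-9 * spec.r)[0]
        for b in bad[:max_report]:
            report.violations.append(Violation(
                "bond", c, tuple(pairs[b]), float(d[b]),
                f"chain {c} bond {tuple(pairs[b])} length {d[b]:.6g} != "
                f"{spec.bond_length:.6g}"))
        inside = geom.contains(pts, spec.r)
        for b in np.nonzero(~inside)[0][:max_report]:
            report.violations.append(Violation(
                "confinement", c, (int(b),), 0.0,
                f"chain {c} bead {b} protrudes from the container"))

    # Hard-core condition over all non-bonded pairs (within and across).
    all_pts = state.all_coords()
    n = len(all_pts)
    r = max(s.r for s in state.specs)
    limit = 2.0 * min(s.r for s in state.specs)
    d = cdist(all_pts, all_pts)
    np.fill_diagonal(d, np.inf)
    for c, spec in enumerate(state.specs):
        for a, b in _bonded_pairs(spec):
            d[offsets[c] + a, offsets[c] + b] = np.inf
            d[offsets[c] + b, offsets[c] + a] = np.inf
    ii, jj = np.nonzero(np.triu(d < limit * (1.0 - 1e-9), k=1))
    for a, b in list(zip(ii, jj))[:max_report]:
        report.violations.append(Violation(
            "overlap", None, (int(a), int(b)), float(d[a, b]),
            f"beads {a} and {b} at distance {d[a, b]:.6g} < {limit:.6g}"))

    if check_topology:
        circular = [c for c, s in enumerate(state.specs)
                    if s.topology == TOP_CIRCULAR]
        for c in circular:
            res = topo.knot_check(state.coords[c])
            if not res.unknot_compatible:
                report.violations.append(Violation(
                    "topology", c, (), float(res.determinant),
                    f"chain {c} knot determinant {res.determinant} != 1"))
        if len(circular) == 2:
            lk = topo.linking_number(state.coords[circular[0]],
                                     state.coords[circular[1]])
            if lk != 0:
                report.violations.append(Violation(
                    "topology", None, tuple(circular), float(lk),
                    f"linking number {lk} != 0"))
    return report


# ---------------------------------------------------------------------------
# Lattice packing
# ---------------------------------------------------------------------------

def _serpentine_sites(m: int, n_cols: int, n_rows: int):
    """Boustrophedon over an (n_cols x n_rows) grid, truncated at ``m``
    sites; starts with the designated edge (0,0) -> (0,1)."""
    sites = []
    for j in range(n_cols):
        rows = range(n_rows) if j % 2 == 0 else range(n_rows - 1, -1, -1)
        for q in rows:
            sites.append((j, q))
            if len(sites) == m:
                return sites
    raise PackingError(f"serpentine capacity {n_cols * n_rows} < {m}")


def _pair_cycle(m_t: int, n_cols: int, n_rows: int, lower: int, upper: int):
    """Closed racetrack: a serpentine strand in plane ``lower`` plus its
    reversed copy in the adjacent plane ``upper``.  Both joining bonds are
    single lattice steps, so all bond lengths stay exactly one spacing."""
    strand = _serpentine_sites(m_t, n_cols, n_rows)
    a = [(j, q, lower) for (j, q) in strand]
    b = [(j, q, upper) for (j, q) in reversed(strand)]
    return a + b


def _closed_loop_sites(m: int, n_pairs: int, n_cols: int, n_rows: int):
    """Closed lattice loop of ``2 m`` sites across ``n_pairs`` adjacent
    plane pairs, built by splicing per-pair racetracks along a shared
    vertical edge at column 0, rows 0-1."""
    cap = n_cols * n_rows
    sizes = []
    rem = m
    for t in range(n_pairs):
        reserve = 2 * (n_pairs - 1 - t)
        take = min(cap, rem - reserve)
        if take < 2:
            raise PackingError("cannot distribute sites over plane pairs")
        sizes.append(take)
        rem -= take
    if rem != 0:
        raise PackingError(f"lattice capacity exceeded by {rem} sites")

    cycle = _pair_cycle(sizes[0], n_cols, n_rows, 0, 1)
    for t in range(1, n_pairs):
        lt = _pair_cycle(sizes[t], n_cols, n_rows, 2 * t, 2 * t + 1)
        v_up = (0, 1, 2 * t - 1)
        u_up = (0, 0, 2 * t - 1)
        i = cycle.index(v_up)
        assert cycle[(i + 1) % len(cycle)] == u_up
        block = lt[1:] + [lt[0]]
        cycle = cycle[:i + 1] + block + cycle[i + 1:]
    return cycle


def _linear_sites(n: int, n_cols: int, n_rows: int, n_planes: int):
    """Open 3D boustrophedon: serpentine each plane, reversing the route
    on alternate planes so plane transitions are single lattice steps."""
    plane_route = _serpentine_sites(n_cols * n_rows, n_cols, n_rows)
    sites = []
    for p in range(n_planes):
        route = plane_route if p % 2 == 0 else plane_route[::-1]
        for (j, q) in route:
            sites.append((j, q, p))
            if len(sites) == n:
                return sites
    raise PackingError(f"lattice capacity {n_cols * n_rows * n_planes} < {n}")


def _plan_columns(a: float, r_pack: float, y_max: float):
    if r_pack <= y_max:
        return 0
    half_width = math.sqrt(r_pack * r_pack - y_max * y_max)
    n_cols = int(2.0 * half_width / a) + 1
    while n_cols > 0 and (n_cols - 1) / 2.0 * a > half_width:
        n_cols -= 1
    return n_cols


def _build_chain_canonical(spec: ChainSpec, geom: ConfinementGeometry,
                           mode: str) -> np.ndarray:
    """Pack one chain into its canonical region.

    Segregated mode packs into the negative-z half with the innermost row
    one lattice spacing short of the mid-plane; overlapping mode packs
    into a symmetric z interval in the negative-y half of the cross
    section.  The partner chain is obtained by mirroring z (segregated)
    or y (overlapping).
    """
    a = spec.bond_length
    r_pack = geom.radius - spec.r - 0.02 * a
    zc = geom.cap_half_length
    circular = spec.topology == TOP_CIRCULAR

    if circular and spec.n == 3:
        h = a * math.sqrt(3.0) / 2.0
        z0 = -2.0 * a if mode == "segregated" else 0.0
        pts = np.array([[-a / 2.0, 0.0, z0],
                        [a / 2.0, 0.0, z0],
                        [0.0, 0.0, z0 - h]])
        return pts

    odd = circular and spec.n % 2 == 1
    odd_reserve = (math.sqrt(3.0) / 2.0 + 0.05) * a if odd else 0.0
    m = spec.n // 2 if circular else spec.n

    plan = None
    max_stack = 64
    for stack in range(1, max_stack + 1):
        if circular:
            if stack > max(1, m // 2):
                break
            n_planes = 2 * stack
        else:
            n_planes = stack
        if mode == "segregated":
            y = (np.arange(n_planes) - (n_planes - 1) / 2.0) * a
        else:
            y = -(0.75 + np.arange(n_planes)) * a
        y_max = float(np.abs(y).max())
        n_cols = _plan_columns(a, r_pack, y_max)
        if n_cols < 1:
            break
        per_level = (stack if circular else n_planes) * n_cols
        n_rows = max(2 if circular else 1, math.ceil(m / per_level))
        if mode == "segregated":
            fits = n_rows * a + odd_reserve + 0.02 * a <= zc
        else:
            fits = (n_rows - 1) / 2.0 * a + odd_reserve + 0.02 * a <= zc
        if fits and (stack if circular else n_planes) * n_cols * n_rows >= m:
            plan = (n_planes, n_cols, n_rows, y)
            break
    if plan is None:
        density = spec.n * (4.0 / 3.0) * math.pi * spec.r ** 3 / geom.volume
        raise PackingError(
            f"cannot pack {spec.topology} chain of {spec.n} beads "
            f"(per-chain volume fraction {density:.3g}) into its half-container")

    n_planes, n_cols, n_rows, y_planes = plan
    if circular:
        sites = _closed_loop_sites(m, n_planes // 2, n_cols, n_rows)
    else:
        sites = _linear_sites(m, n_cols, n_rows, n_planes)

    x_of = lambda j: (j - (n_cols - 1) / 2.0) * a
    if mode == "segregated":
        z_of = lambda q: -(n_rows - q) * a
    else:
        z_of = lambda q: (q - (n_rows - 1) / 2.0) * a

    pts = np.array([[x_of(j), y_planes[p], z_of(q)] for (j, q, p) in sites])

    if odd:
        # One extra bead on the closing bond, pushed outward along -z: the
        # bond splits into two exact-2r bonds via an isosceles detour.
        j0, q0, p_last = sites[-1][0], sites[-1][1], sites[-1][2]
        p_first = sites[0][2]
        y_mid = 0.5 * (y_planes[p_last] + y_planes[p_first])
        apex = np.array([x_of(j0), y_mid, z_of(q0) - math.sqrt(3.0) / 2.0 * a])
        pts = np.vstack([pts, apex])
    return pts


def _mirror(points: np.ndarray, axis: int) -> np.ndarray:
    out = points.copy()
    out[:, axis] = -out[:, axis]
    return out


def _assemble(specs, geom, mode, seed) -> SystemState:
    del seed  # builders are fully deterministic; kept for interface stability
    specs = tuple(specs)
    if len(specs) != 2:
        raise ConfigurationError("a system consists of exactly two chains")
    chains = []
    for c, spec in enumerate(specs):
        pts = _build_chain_canonical(spec, geom, mode)
        if c == 1:
            pts = _mirror(pts, 2 if mode == "segregated" else 1)
        chains.append(pts)
    state = SystemState(geom, specs, np.vstack(chains))
    report = validate_state(state, check_topology=True)
    if not report.ok:
        raise PackingError(f"packed state failed validation: {report.summary()}")
    return state


def build_initial_segregated(specs, geom: ConfinementGeometry,
                             seed: int = 0) -> SystemState:
    """Valid initial state with the two chains in disjoint z intervals
    (axial overlap length <= 0).  Deterministic."""
    return _assemble(specs, geom, "segregated", seed)


def build_initial_overlapping(specs, geom: ConfinementGeometry,
                              seed: int = 0) -> SystemState:
    """Valid initial state with the two chains' z intervals coincident
    (chains side by side across the cylinder axis).  Used as the control
    start to confirm that ring-ring segregation does not depend on the
    initial configuration.  Deterministic."""
    return _assemble(specs, geom, "overlapping", seed)


# ---------------------------------------------------------------------------
# Snapshots and exact restart
# ---------------------------------------------------------------------------

def write_xyz(state: SystemState, path, comment: str = "") -> None:
    """Append one XYZ frame; the element field carries the chain id."""
    with open(path, "a") as fh:
        fh.write(f"{state.n_beads}\n")
        fh.write(f"iteration={state.iteration_count} {comment}\n")
        for c, pts in enumerate(state.coords):
            for x, y, z in pts:
                fh.write(f"C{c} {x:.12g} {y:.12g} {z:.12g}\n")


def read_xyz(path):
    """Read all frames from an XYZ trajectory written by :func:`write_xyz`.

    Returns a list of ``(iteration, per_chain_coords)`` tuples.
    """
    frames = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i])
        comment = lines[i + 1]
        iteration = 0
        for token in comment.split():
            if token.startswith("iteration="):
                iteration = int(token.split("=")[1])
        chains: dict = {}
        for k in range(n):
            parts = lines[i + 2 + k].split()
            chains.setdefault(parts[0], []).append([float(v) for v in parts[1:4]])
        frames.append((iteration,
                       tuple(np.asarray(chains[k]) for k in sorted(chains))))
        i += 2 + n
    return frames


def save_state_json(state: SystemState, path) -> None:
    """Structured dump (geometry, specs, coordinates, iteration count)
    sufficient for exact restart."""
    payload = {
        "geometry": {"diameter": state.geometry.diameter,
                     "aspect": state.geometry.aspect},
        "specs": [{"topology": s.topology, "n": s.n, "r": s.r}
                  for s in state.specs],
        "iteration_count": state.iteration_count,
        "positions": state.positions.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_state_json(path) -> SystemState:
    with open(path) as fh:
        payload = json.load(fh)
    geom = ConfinementGeometry(**payload["geometry"])
    specs = tuple(ChainSpec(**s) for s in payload["specs"])
    return SystemState(geom, specs, np.asarray(payload["positions"]),
                       payload["iteration_count"])
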