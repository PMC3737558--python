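"""Metropolis Monte Carlo over crankshaft moves with hard constraints.

The potential is athermal: every configuration is either allowed (all
hard constraints satisfied) or forbidden, so a proposed move is accepted
iff the rotated beads violate no hard-core pair, stay inside the
container, and pass the swept-path crossing check where chain topology
must be conserved.  No Boltzmann factor is ever computed and temperature
plays no role.

One *iteration* is one attempted move.  The sampling schedule measures
observables every ``20 N`` iterations after discarding the first
``2000 N`` (``N`` = beads per chain); both are configurable.

Two code paths implement the same move semantics: a compiled kernel
(:mod:`ringmix._kernels`) used by :func:`run_mc` for production, and the
plain-Python :func:`propose_crankshaft` / :func:`attempt_move` pair used
by fine-grained tests; the micro-system sampling tests cross-validate
the kernel against an independent rejection-sampling oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels, observables, topology
from .geometry import ConfigurationError
from .polymer import TOP_CIRCULAR, SystemState, validate_state

__all__ = [
    "MCConfig",
    "CrankshaftProposal",
    "MCRunResult",
    "MCAuditFailure",
    "propose_crankshaft",
    "apply_proposal",
    "attempt_move",
    "run_mc",
]

_CHUNK_MAX = 1_000_000


@dataclass
class MCConfig:
    """Engine parameters.

    ``discard_iterations`` and ``sample_interval`` default to ``2000 N``
    and ``20 N`` (``N`` beads per chain).  ``s_max`` is the largest
    crankshaft segment in bonds, default ``min(N // 2, 60)``; the
    rotation angle is uniform in ``(-theta_max, theta_max)``.  The rigid
    whole-chain translation move is off by default and is excluded from
    all headline runs.
    """

    total_iterations: int
    discard_iterations: int | None = None
    sample_interval: int | None = None
    s_max: int | None = None
    theta_max: float = math.pi
    seed: int = 0
    audit_interval: int = 25
    translation_prob: float = 0.0
    translation_max: float | None = None

    def resolved(self, state: SystemState) -> dict:
        n = max(s.n for s in state.specs)
        s_max = self.s_max if self.s_max is not None else min(n // 2, 60)
        out = {
            "discard_iterations": (self.discard_iterations
                                   if self.discard_iterations is not None
                                   else 2000 * n),
            "sample_interval": (self.sample_interval
                                if self.sample_interval is not None
                                else 20 * n),
            "s_max": max(1, s_max),
            "translation_max": (self.translation_max
                                if self.translation_max is not None
                                else state.geometry.diameter / 4.0),
        }
        if not 0 < self.theta_max <= math.pi:
            raise ConfigurationError("theta_max must lie in (0, pi]")
        if out["sample_interval"] < 1:
            raise ConfigurationError("sample_interval must be >= 1")
        if not 0 <= self.seed < 2**31:
            raise ConfigurationError("seed must fit in a signed 32-bit int")
        return out


@dataclass
class CrankshaftProposal:
    """One attempted move: which beads rotate, about which axis, by how
    much.  For linear end-moves only a single interior pivot exists and
    the axis is a random direction through it (``terminal=True``)."""

    chain: int
    pivots: tuple
    theta: float
    moved: np.ndarray          # local bead indices within the chain
    anchor: np.ndarray
    axis: np.ndarray
    terminal: bool = False


def propose_crankshaft(state: SystemState, rng: np.random.Generator,
                       config: MCConfig) -> CrankshaftProposal:
    """Draw one crankshaft proposal.

    The chain and first pivot are uniform; the segment length ``s`` is
    uniform in ``[1, s_max]`` and runs in a uniform random direction.  On
    a circular chain the second pivot is ``i + s (mod N)``.  On a linear
    chain a segment overshooting an end reflects into a terminal
    rotation: every bead beyond the reflected interior pivot rotates
    about a uniformly random axis through that pivot.
    """
    res = config.resolved(state)
    c = int(rng.integers(0, 2))
    spec = state.specs[c]
    n = spec.n
    i = int(rng.integers(0, n))
    smx = max(1, min(res["s_max"], n // 2))
    s = int(rng.integers(1, smx + 1))
    theta = float(rng.uniform(-config.theta_max, config.theta_max))
    pts = state.coords[c]

    if spec.topology == TOP_CIRCULAR:
        j = (i + s) % n
        moved = (i + 1 + np.arange(s - 1)) % n
        anchor = pts[i].copy()
        axis = pts[j] - pts[i]
        return CrankshaftProposal(c, (i, j), theta, moved, anchor, axis)

    d = 1 if rng.random() < 0.5 else -1
    j = i + d * s
    if 0 <= j < n:
        lo, hi = min(i, j), max(i, j)
        moved = np.arange(lo + 1, hi)
        anchor = pts[lo].copy()
        axis = pts[hi] - pts[lo]
        return CrankshaftProposal(c, (lo, hi), theta, moved, anchor, axis)

    if j >= n:
        p = 2 * (n - 1) - j
        moved = np.arange(p + 1, n)
    else:
        p = -j
        moved = np.arange(0, p)
    axis = rng.standard_normal(3)
    while np.linalg.norm(axis) < 1e-12:
        axis = rng.standard_normal(3)
    return CrankshaftProposal(c, (p,), theta, moved, pts[p].copy(), axis,
                              terminal=True)


def apply_proposal(state: SystemState, proposal: CrankshaftProposal,
                   theta: float | None = None) -> np.ndarray:
    """New positions of the moved beads after the (partial) rotation."""
    pts = state.coords[proposal.chain][proposal.moved]
    angle = proposal.theta if theta is None else theta
    if len(pts) == 0 or angle == 0.0:
        return pts.copy()
    return topology.rotate_about_axis(pts, proposal.anchor, proposal.axis,
                                      angle)


def attempt_move(state: SystemState, proposal: CrankshaftProposal):
    """Hard-constraint Metropolis acceptance of one proposal.

    Accepts iff the rotated beads violate no hard-core pair, stay inside
    the container, and the swept path is crossing-free.  The move is
    applied atomically: on rejection the state is unchanged.  The
    iteration counter increments either way.  Returns ``(accepted,
    state)``.
    """
    state.iteration_count += 1
    moved = np.asarray(proposal.moved, dtype=int)
    if len(moved) == 0 or proposal.theta == 0.0:
        if len(moved) > 0:
            new = apply_proposal(state, proposal)
            state.coords[proposal.chain][moved] = new
        return True, state

    spec = state.specs[proposal.chain]
    new = apply_proposal(state, proposal)
    if not state.geometry.contains(new, spec.r).all():
        return False, state

    offsets = state.chain_offsets()
    moved_global = moved + offsets[proposal.chain]
    all_pts = state.all_coords()
    static = np.setdiff1d(np.arange(state.n_beads), moved_global)
    d2 = ((new[:, None, :] - all_pts[static][None, :, :]) ** 2).sum(axis=2)
    bonded = topology._bonded_pairs_mask(state, moved_global, static)
    d2[bonded] = np.inf
    limit2 = (2.0 * spec.r) ** 2 * (1.0 - 1e-10)
    if (d2 < limit2).any():
        return False, state

    if not topology.crossing_free(state, proposal):
        return False, state

    state.coords[proposal.chain][moved] = new
    return True, state


class MCAuditFailure(RuntimeError):
    """A topology or state audit failed during a run; carries the state."""

    def __init__(self, message, state, audit):
        super().__init__(message)
        self.state = state
        self.audit = audit


@dataclass
class MCRunResult:
    """Sample series and run metadata returned by :func:`run_mc`."""

    samples: pd.DataFrame
    accepted: int
    attempted: int
    audits: list
    seed: int
    resolved: dict

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.attempted if self.attempted else math.nan


def _kernel_setup(state: SystemState):
    specs = state.specs
    if len(specs) != 2:
        raise ConfigurationError("the engine simulates exactly two chains")
    if abs(specs[0].r - specs[1].r) > 1e-12 * specs[0].r:
        raise ConfigurationError("both chains must share one bead radius")
    r = specs[0].r
    geom = state.geometry
    circ = [1 if s.topology == TOP_CIRCULAR else 0 for s in specs]
    both_circ = circ[0] == 1 and circ[1] == 1
    # Sweep policy: moves of a circular chain must not change its knot
    # type; with two rings the mutual linking number is conserved too.
    sweep = [c for c in circ]
    sweep_other = 1 if both_circ else 0

    edge = 3.0 * r
    ncx = max(1, int(geom.diameter / edge))
    ncz = max(1, int(geom.total_length / edge))
    inv_e = 1.0 / edge
    n = state.n_beads
    head = np.full(ncx * ncx * ncz, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cell_of = np.zeros(n, dtype=np.int64)
    _kernels.build_cells(state.positions, -geom.radius, -geom.total_length / 2.0,
                         inv_e, ncx, ncx, ncz, head, nxt, cell_of)
    return {
        "start1": specs[0].n,
        "n0": specs[0].n, "n1": specs[1].n,
        "circ0": circ[0], "circ1": circ[1],
        "r": r,
        "rr2": (2.0 * r) ** 2 * (1.0 - 1e-10),
        "wall_r2": (geom.radius - r) ** 2 * (1.0 + 1e-12),
        "zc": geom.cap_half_length,
        "sweep0": sweep[0], "sweep1": sweep[1], "sweep_other": sweep_other,
        "x0": -geom.radius, "z0": -geom.total_length / 2.0,
        "inv_e": inv_e, "ncx": ncx, "ncy": ncx, "ncz": ncz,
        "head": head, "nxt": nxt, "cell_of": cell_of,
        "moved": np.zeros(n, dtype=np.int64),
        "newpos": np.zeros((n, 3)),
        "moved_flag": np.zeros(n, dtype=np.uint8),
    }


def _run_kernel(state, ks, cfg, res, n_iter):
    return _kernels.run_chunk(
        state.positions, ks["start1"], ks["n0"], ks["n1"],
        ks["circ0"], ks["circ1"], ks["r"], ks["rr2"], ks["wall_r2"], ks["zc"],
        res["s_max"], cfg.theta_max, ks["sweep0"], ks["sweep1"],
        ks["sweep_other"], cfg.translation_prob, res["translation_max"],
        n_iter, ks["x0"], ks["z0"], ks["inv_e"], ks["ncx"], ks["ncy"],
        ks["ncz"], ks["head"], ks["nxt"], ks["cell_of"], ks["moved"],
        ks["newpos"], ks["moved_flag"])


def run_mc(state: SystemState, config: MCConfig, observers=None,
           validate_at_audit: bool = True) -> MCRunResult:
    """Run the sampling schedule on ``state`` (evolved in place).

    Executes ``total_iterations`` attempted moves; after the discard
    phase, measures the standard observables (and any extra ``observers``
    callbacks, each ``state -> dict``) every ``sample_interval``
    iterations.  Every ``audit_interval``-th sample the exact topology
    invariants (and, optionally, all geometric state invariants) are
    re-checked; a failure raises :class:`MCAuditFailure` with the
    offending state attached.
    """
    res = config.resolved(state)
    total = config.total_iterations
    discard = min(res["discard_iterations"], total)
    ks = _kernel_setup(state)
    _kernels.seed_rng(config.seed)

    accepted = 0
    attempted = 0
    records = []
    audits = []

    remaining = discard
    while remaining > 0:
        chunk = min(remaining, _CHUNK_MAX)
        accepted += _run_kernel(state, ks, config, res, chunk)
        attempted += chunk
        state.iteration_count += chunk
        remaining -= chunk

    n_samples = (total - discard) // res["sample_interval"]
    for k in range(n_samples):
        accepted += _run_kernel(state, ks, config, res, res["sample_interval"])
        attempted += res["sample_interval"]
        state.iteration_count += res["sample_interval"]

        sample = observables.measure(state)
        record = sample.as_dict()
        if observers:
            for obs in observers:
                record.update(obs(state))
        records.append(record)

        if config.audit_interval and (k + 1) % config.audit_interval == 0:
            audit = topology.audit_topology(state)
            entry = {"iteration": state.iteration_count, "audit": audit}
            if validate_at_audit:
                report = validate_state(state, check_topology=False)
                entry["state_report"] = report
                if not report.ok:
                    audits.append(entry)
                    raise MCAuditFailure(
                        f"state invariants violated at iteration "
                        f"{state.iteration_count}: {report.summary()}",
                        state, entry)
            audits.append(entry)
            if not audit.passed:
                raise MCAuditFailure(
                    f"topology audit failed at iteration "
                    f"{state.iteration_count}: {'; '.join(audit.messages)}",
                    state, entry)

    samples = pd.DataFrame.from_records(records) if records else pd.DataFrame()
    return MCRunResult(samples, accepted, attempted, audits,
                       config.seed, res)
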