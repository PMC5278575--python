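"""Metropolis–Hastings simulated annealing of bead-chain genome structures.

Each chromosome is a chain of touching spherical beads (consecutive center
distance = sum of radii).  Structures live inside a spherical nucleus of
radius R; lamin-flagged beads are pulled to the nuclear wall via a
zero-radius dummy bead at the origin, interacting bead pairs are pulled
together, and all other beads feel a weak centering pull.  The loss is a
sum of weighted quadratic terms over the constraints,

    L = Σ k_ij (‖b_i − b_j‖ − d_ij)²,

minimized by proposing one of five connectivity-preserving moves per
iteration (whole-chain translation, whole-chain rotation, crankshaft of an
interior run, pivot of a terminal arm, single-bead hinge), rejecting any
move that clashes beads or exits the nucleus, and otherwise accepting by
the Metropolis criterion at a geometrically cooled temperature.  All moves
are rigid transforms of the affected run, so consecutive-bead distances
are preserved to machine precision.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    MOVE_KINDS,
    AnnealSchedule,
    Bead,
    Constraint,
    ConstraintKind,
    NucleusGeometry,
    StructureEnsemble,
)

__all__ = [
    "BeadModel",
    "AnnealResult",
    "build_constraints",
    "loss",
    "init_structure",
    "propose_move",
    "anneal",
    "run_ensemble",
]

logger = logging.getLogger(__name__)

_KIND_CODE = {
    ConstraintKind.PAIR_ATTRACT: 0,
    ConstraintKind.PAIR_LOWER_BOUND: 1,
    ConstraintKind.PERIPHERY: 2,
    ConstraintKind.CENTER: 3,
}

#: absolute slack (μm or nm) on clash / containment checks, so exact
#: touching of chain neighbors never counts as a clash
GEOM_TOL = 1e-9


def build_constraints(
    beads: Sequence[Bead],
    pairs: Sequence[tuple[int, int]],
    geometry: NucleusGeometry,
    pair_weight: float = 1.0,
    periphery_weight: float = 1.0,
    center_weight: float = 0.01,
) -> list[Constraint]:
    """Assemble the constraint set for a scaled bead model.

    Each interacting bead pair gets an attraction with target distance
    r_i + r_j (touching without overlap); each lamin-flagged bead a
    periphery restraint with target R − r_i (touching the nuclear wall);
    every non-lamin bead a weak centering pull (target 0).  The centering
    weight defaults to 0.01 — a full-strength pull on every bead would
    collapse the interior.
    """
    n = len(beads)
    out: list[Constraint] = []
    for i, j in pairs:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise ValueError(f"pair ({i}, {j}) does not reference two distinct beads")
        out.append(
            Constraint(ConstraintKind.PAIR_ATTRACT, i, j,
                       beads[i].radius + beads[j].radius, pair_weight)
        )
    for i, b in enumerate(beads):
        if b.lamin:
            out.append(
                Constraint(ConstraintKind.PERIPHERY, i, -1,
                           geometry.radius - b.radius, periphery_weight)
            )
        elif center_weight > 0:
            out.append(Constraint(ConstraintKind.CENTER, i, -1, 0.0, center_weight))
    return out


class _Compiled:
    """Constraints flattened to arrays, with a per-bead index for
    incremental loss evaluation."""

    def __init__(self, constraints: Sequence[Constraint], n_beads: int):
        m = len(constraints)
        self.kind = np.empty(m, dtype=np.int8)
        self.i = np.empty(m, dtype=np.intp)
        self.j = np.empty(m, dtype=np.intp)
        self.d = np.empty(m, dtype=float)
        self.k = np.empty(m, dtype=float)
        per_bead: list[list[int]] = [[] for _ in range(n_beads)]
        for c_id, c in enumerate(constraints):
            self.kind[c_id] = _KIND_CODE[c.kind]
            self.i[c_id] = c.i
            self.j[c_id] = max(c.j, 0)  # radial kinds ignore j
            self.d[c_id] = c.target
            self.k[c_id] = c.weight
            per_bead[c.i].append(c_id)
            if c.kind in (ConstraintKind.PAIR_ATTRACT, ConstraintKind.PAIR_LOWER_BOUND):
                per_bead[c.j].append(c_id)
        self.is_pair = self.kind <= 1
        self.per_bead = [np.array(ids, dtype=np.intp) for ids in per_bead]

    def terms(self, coords: np.ndarray, ids: np.ndarray | None = None) -> np.ndarray:
        """Per-constraint loss contributions (for constraint subset ``ids``)."""
        kind = self.kind if ids is None else self.kind[ids]
        i = self.i if ids is None else self.i[ids]
        j = self.j if ids is None else self.j[ids]
        d = self.d if ids is None else self.d[ids]
        k = self.k if ids is None else self.k[ids]
        bi = coords[i]
        dist = np.where(
            kind <= 1,
            np.linalg.norm(bi - coords[j], axis=1),
            np.linalg.norm(bi, axis=1),
        )
        dev = dist - d
        # one-sided kinds penalize only the short side (dist < target)
        one_sided = (kind == 1) | (kind == 2)
        dev = np.where(one_sided, np.minimum(dev, 0.0), dev)
        return k * dev**2


def loss(coords: np.ndarray, constraints: Sequence[Constraint]) -> float:
    """Total loss L = Σ k_ij (‖b_i − b_j‖ − d_ij)² over all constraints
    (one-sided for lower-bound and periphery kinds)."""
    coords = np.asarray(coords, dtype=float)
    comp = _Compiled(constraints, len(coords))
    return float(comp.terms(coords).sum())


def chains_from_beads(beads: Sequence[Bead]) -> list[tuple[int, int]]:
    """Index ranges [start, stop) of maximal runs sharing (chrom, homolog)."""
    chains: list[tuple[int, int]] = []
    start = 0
    for k in range(1, len(beads) + 1):
        if k == len(beads) or (
            (beads[k].interval.chrom, beads[k].homolog)
            != (beads[start].interval.chrom, beads[start].homolog)
        ):
            chains.append((start, k))
            start = k
    return chains


@dataclass
class BeadModel:
    """A bead list with its chain partition, constraints and geometry,
    ready for optimization.  ``geometry=None`` models an unbounded domain
    (used at locus scale)."""

    beads: list[Bead]
    constraints: list[Constraint]
    geometry: NucleusGeometry | None = None
    chains: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chains:
            self.chains = chains_from_beads(self.beads)
        for start, stop in self.chains:
            ivs = [self.beads[k].interval for k in range(start, stop)]
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"beads overlap or are unsorted within chain: {a} then {b}"
                    )

    @property
    def radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.beads])

    @property
    def n_beads(self) -> int:
        return len(self.beads)


# ---------------------------------------------------------------------------
# geometry helpers


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _rotate_about(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
                  angle: float) -> np.ndarray:
    return (points - origin) @ _rotation_matrix(axis, angle).T + origin


# ---------------------------------------------------------------------------
# moves


def propose_move(
    coords: np.ndarray,
    chains: Sequence[tuple[int, int]],
    move_kind: str,
    rng: np.random.Generator,
    max_step: float = 0.5,
    max_angle: float = math.pi / 2,
    max_segment: int = 20,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Propose one connectivity-preserving move.

    Returns ``(bead_indices, new_coords)`` or ``None`` when the sampled
    geometry is degenerate for the chosen kind (caller resamples).  Every
    kind applies a rigid transform to the affected run, so all
    consecutive-bead distances are preserved exactly.
    """
    start, stop = chains[rng.integers(len(chains))]
    n = stop - start

    if move_kind == "chain_translate":
        v = _random_unit(rng) * rng.uniform(0.0, max_step)
        idx = np.arange(start, stop)
        return idx, coords[idx] + v

    if move_kind == "chain_rotate":
        idx = np.arange(start, stop)
        if n == 1:
            return idx, coords[idx].copy()
        center = coords[idx].mean(axis=0)
        angle = rng.uniform(-max_angle, max_angle)
        return idx, _rotate_about(coords[idx], center, _random_unit(rng), angle)

    if move_kind == "crankshaft":
        if n < 3:
            return None
        a = int(rng.integers(0, n - 2))
        b = int(rng.integers(a + 2, min(n, a + 2 + max_segment)))
        pa, pb = coords[start + a], coords[start + b]
        axis = pb - pa
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            return None
        idx = np.arange(start + a + 1, start + b)
        angle = rng.uniform(-max_angle, max_angle)
        return idx, _rotate_about(coords[idx], pa, axis / norm, angle)

    if move_kind == "arm_pivot":
        if n < 2:
            return None
        if rng.random() < 0.5:  # tail arm
            h = int(rng.integers(max(0, n - 1 - max_segment), n - 1))
            idx = np.arange(start + h + 1, stop)
        else:  # head arm
            h = int(rng.integers(1, min(n, max_segment + 1)))
            idx = np.arange(start, start + h)
        hinge = coords[start + h]
        angle = rng.uniform(-max_angle, max_angle)
        return idx, _rotate_about(coords[idx], hinge, _random_unit(rng), angle)

    if move_kind == "bead_hinge":
        if n == 1:
            return None
        i = int(rng.integers(0, n))
        bead = start + i
        if i == 0 or i == n - 1:
            nb = coords[bead + 1] if i == 0 else coords[bead - 1]
            d = np.linalg.norm(coords[bead] - nb)
            new = nb + _random_unit(rng) * d
            return np.array([bead]), new[None, :]
        p, q = coords[bead - 1], coords[bead + 1]
        pq = q - p
        L = np.linalg.norm(pq)
        if L < 1e-12:
            return None
        u = pq / L
        d1 = np.linalg.norm(coords[bead] - p)
        d2 = np.linalg.norm(coords[bead] - q)
        t = (d1 * d1 - d2 * d2 + L * L) / (2.0 * L)
        rho_sq = d1 * d1 - t * t
        if rho_sq <= 0:
            return None  # collinear: the circle is a point
        rho = math.sqrt(rho_sq)
        e1 = np.cross(u, _random_unit(rng))
        ne1 = np.linalg.norm(e1)
        if ne1 < 1e-9:
            return None
        e1 /= ne1
        e2 = np.cross(u, e1)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        new = p + u * t + rho * (math.cos(phi) * e1 + math.sin(phi) * e2)
        return np.array([bead]), new[None, :]

    raise ValueError(f"unknown move kind {move_kind!r}")


# ---------------------------------------------------------------------------
# clash / containment


def _violations(
    coords: np.ndarray,
    radii: np.ndarray,
    idx: np.ndarray,
    new_xyz: np.ndarray,
    R: float | None,
) -> bool:
    """True iff placing beads ``idx`` at ``new_xyz`` clashes any unmoved
    bead or (when bounded) exits the nucleus.  Moved-vs-moved pairs are
    skipped: rigid moves preserve their internal distances."""
    if R is not None:
        if np.any(np.linalg.norm(new_xyz, axis=1) + radii[idx] > R + GEOM_TOL):
            return True
    diff = new_xyz[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    sumr = radii[idx][:, None] + radii[None, :]
    mask = np.ones_like(dist, dtype=bool)
    mask[:, idx] = False  # ignore moved-vs-moved (and self)
    return bool(np.any(dist[mask] < (sumr - GEOM_TOL)[mask]))


def check_structure(
    model: BeadModel, coords: np.ndarray, rel_tol: float = 1e-6
) -> None:
    """Assert chain connectivity, containment and non-overlap; raises
    AssertionError with a diagnostic otherwise."""
    radii = model.radii
    for s, e in model.chains:
        for k in range(s, e - 1):
            target = radii[k] + radii[k + 1]
            d = np.linalg.norm(coords[k] - coords[k + 1])
            assert abs(d - target) <= rel_tol * target, (
                f"chain break at beads {k},{k + 1}: {d} vs {target}"
            )
    if model.geometry is not None:
        R = model.geometry.radius
        out = np.linalg.norm(coords, axis=1) + radii
        assert np.all(out <= R * (1 + rel_tol)), "bead outside nucleus"
    dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    sumr = radii[:, None] + radii[None, :]
    np.fill_diagonal(dist, np.inf)
    assert np.all(dist >= sumr - rel_tol * sumr - GEOM_TOL), "bead overlap"


# ---------------------------------------------------------------------------
# initialization


def init_structure(
    model: BeadModel,
    seed: int | np.random.Generator = 0,
    max_chain_restarts: int = 300,
    max_global_restarts: int = 20,
) -> np.ndarray:
    """Self-avoiding random-walk initialization.

    Chains are grown one bead at a time directly inside the nucleus:
    consecutive beads exactly touch (step length r_k + r_{k+1}), every
    bead must stay contained (‖b‖ + r ≤ R) and clash-free against all
    beads placed so far, across chains.  Dead ends trigger a restart of
    the offending chain, then of the whole configuration.  Deterministic
    given the seed; raises if the geometry cannot be satisfied.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    radii = model.radii
    R = model.geometry.radius if model.geometry is not None else None
    coords = np.zeros((model.n_beads, 3))

    for _ in range(max_global_restarts):
        placed: list[int] = []
        failed = False
        for start, stop in model.chains:
            if not _grow_chain(coords, radii, placed, start, stop, R, rng,
                               max_chain_restarts):
                failed = True
                break
            placed.extend(range(start, stop))
        if not failed:
            return coords
    raise RuntimeError(
        "failed to initialize a clash-free contained structure; "
        "consider a larger nucleus or lower occupancy"
    )


def _grow_chain(
    coords: np.ndarray,
    radii: np.ndarray,
    placed: list[int],
    start: int,
    stop: int,
    R: float | None,
    rng: np.random.Generator,
    max_restarts: int,
) -> bool:
    """Grow beads [start, stop) as a self-avoiding walk avoiding ``placed``."""
    prev = np.asarray(placed, dtype=np.intp)

    def clashes(k: int, cand: np.ndarray) -> bool:
        if R is not None and np.linalg.norm(cand) + radii[k] > R:
            return True
        others = np.concatenate([prev, np.arange(start, k)])
        if others.size == 0:
            return False
        d = np.linalg.norm(coords[others] - cand, axis=1)
        return bool(np.any(d < radii[others] + radii[k] - GEOM_TOL))

    for _ in range(max_restarts):
        ok = True
        for k in range(start, stop):
            for _ in range(150):
                if k == start:
                    if R is not None:
                        room = R - radii[k]
                        cand = _random_unit(rng) * (room * rng.random() ** (1.0 / 3.0))
                    else:
                        cand = np.zeros(3)
                else:
                    cand = coords[k - 1] + _random_unit(rng) * (radii[k - 1] + radii[k])
                if not clashes(k, cand):
                    coords[k] = cand
                    break
            else:
                ok = False
                break
        if ok:
            return True
    return False


# ---------------------------------------------------------------------------
# annealing


@dataclass
class AnnealResult:
    coords: np.ndarray
    initial_loss: float
    final_loss: float
    trace: list[tuple[int, float]]
    proposed: dict[str, int]
    accepted: dict[str, int]
    clash_rejected: int
    resampled: int


def anneal(
    coords: np.ndarray,
    model: BeadModel,
    schedule: AnnealSchedule,
    rng: np.random.Generator | None = None,
) -> AnnealResult:
    """Run Metropolis–Hastings simulated annealing from ``coords``.

    Per iteration: sample a move kind by weight, propose, reject outright
    on clash or nucleus exit, otherwise accept iff ΔL ≤ 0 or
    u < exp(−ΔL/T); T cools geometrically.  With T0 = 0 the dynamics are
    greedy (only non-increasing moves accepted).  Deterministic given the
    schedule seed (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(schedule.seed)
    coords = np.array(coords, dtype=float)
    radii = model.radii
    R = model.geometry.radius if model.geometry is not None else None
    comp = _Compiled(model.constraints, model.n_beads)

    terms = comp.terms(coords)
    L = float(terms.sum())
    if not math.isfinite(L):
        raise FloatingPointError("non-finite initial loss")
    initial_loss = L
    T = schedule.t0 if schedule.t0 is not None else max(L / max(model.n_beads, 1), 1e-12)
    cool = 1.0 - schedule.cooling_rate

    weights = np.asarray(schedule.move_weights, dtype=float)
    cum = np.cumsum(weights / weights.sum())
    proposed = {k: 0 for k in MOVE_KINDS}
    accepted = {k: 0 for k in MOVE_KINDS}
    clash_rejected = 0
    resampled = 0
    trace: list[tuple[int, float]] = [(0, L)]

    for it in range(1, schedule.iterations + 1):
        kind = MOVE_KINDS[int(np.searchsorted(cum, rng.random(), side="right"))]
        mv = propose_move(
            coords, model.chains, kind, rng,
            max_step=schedule.max_step,
            max_angle=schedule.max_angle,
            max_segment=schedule.max_segment,
        )
        proposed[kind] += 1
        if mv is None:
            resampled += 1
            T *= cool
            continue
        idx, new_xyz = mv
        if _violations(coords, radii, idx, new_xyz, R):
            clash_rejected += 1
            T *= cool
            continue
        affected = np.unique(np.concatenate([comp.per_bead[b] for b in idx])) \
            if len(idx) else np.array([], dtype=np.intp)
        old_xyz = coords[idx].copy()
        old_terms = terms[affected]
        coords[idx] = new_xyz
        new_terms = comp.terms(coords, affected) if affected.size else old_terms
        dL = float(new_terms.sum() - old_terms.sum())
        if dL <= 0 or (T > 0 and rng.random() < math.exp(-min(dL / T, 700.0))):
            terms[affected] = new_terms
            L += dL
            accepted[kind] += 1
        else:
            coords[idx] = old_xyz
        if not math.isfinite(L):
            raise FloatingPointError(f"non-finite loss at iteration {it}")
        T *= cool
        if it % schedule.trace_stride == 0:
            trace.append((it, L))

    # refresh against drift of the running sum
    final = float(comp.terms(coords).sum())
    if trace[-1][0] != schedule.iterations:
        trace.append((schedule.iterations, final))
    return AnnealResult(coords, initial_loss, final, trace, proposed, accepted,
                        clash_rejected, resampled)


def run_ensemble(
    model: BeadModel,
    schedule: AnnealSchedule,
    n_structures: int,
) -> tuple[StructureEnsemble, list[AnnealResult]]:
    """Generate ``n_structures`` independently initialized and annealed
    structures.  Member seeds derive deterministically from
    ``schedule.seed`` so results are reproducible and order-stable; a
    failing member is reported with a warning and skipped.
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    children = np.random.SeedSequence(schedule.seed).spawn(n_structures)
    members: list[np.ndarray] = []
    losses: list[float] = []
    results: list[AnnealResult] = []
    for m, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        try:
            coords = init_structure(model, rng)
            res = anneal(coords, model, schedule, rng=rng)
        except Exception as exc:  # noqa: BLE001 - per-member failure policy
            warnings.warn(f"ensemble member {m} failed: {exc}", stacklevel=2)
            continue
        members.append(res.coords)
        losses.append(res.final_loss)
        results.append(res)
        logger.info("member %d/%d: loss %.4g -> %.4g", m + 1, n_structures,
                    res.initial_loss, res.final_loss)
    ensemble = StructureEnsemble(
        beads=list(model.beads), members=members, losses=losses,
        geometry=model.geometry,
    )
    return ensemble, results
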