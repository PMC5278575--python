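"""Fragment-resolution conformational modeling of a single locus from
5C-style contact matrices.

Each restriction fragment becomes one bead of radius 0.005 nm per bp of
fragment length, chained in genomic order.  Pairwise constraints come from
the contact matrix: non-adjacent pairs with zero contacts get a
non-interaction (lower-bound) restraint, pairs at or above an interaction
threshold get an attraction; neighboring fragments get no extra restraint
because chain connectivity already keeps them touching.  Ensembles are
annealed with whole-chain translation and rotation moves disabled and no
bounding nucleus, then superposed by Procrustes analysis (no scaling,
reflections allowed) and grouped by average-linkage agglomerative
clustering on Manhattan distances between flattened coordinate vectors.
"""
from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import orthogonal_procrustes

from .core import (
    AnnealSchedule,
    Bead,
    Constraint,
    ConstraintKind,
    GenomicInterval,
    StructureEnsemble,
)
from .engine import AnnealResult, BeadModel, run_ensemble

__all__ = [
    "FRAGMENT_SCALE_NM_PER_BP",
    "fragment_to_bead",
    "locus_beads",
    "build_5c_constraints",
    "run_locus_ensemble",
    "procrustes_align",
    "cluster_ensemble",
    "pair_distance_distribution",
]

#: nm of bead radius per bp of restriction-fragment length
FRAGMENT_SCALE_NM_PER_BP = 0.005


def fragment_to_bead(length: int) -> float:
    """Bead radius in nm for a restriction fragment of ``length`` bp."""
    if length <= 0:
        raise ValueError("fragment length must be positive")
    return FRAGMENT_SCALE_NM_PER_BP * length


def locus_beads(lengths: list[int], chrom: str = "locus", origin: int = 0) -> list[Bead]:
    """One chain of fragment beads laid end to end in genomic order."""
    beads: list[Bead] = []
    pos = origin
    for k, L in enumerate(lengths):
        beads.append(
            Bead(k, GenomicInterval(chrom, pos, pos + L), radius=fragment_to_bead(L))
        )
        pos += L
    return beads


def build_5c_constraints(
    matrix: np.ndarray,
    interaction_threshold: float,
    d_interact: float,
    d_noninteract: float,
) -> list[Constraint]:
    """Derive pairwise restraints from a symmetric fragment×fragment count
    matrix (thresholds and target distances are cell-type-specific inputs).

    Non-adjacent zero-count pairs -> lower bound at ``d_noninteract``;
    non-adjacent pairs with count >= ``interaction_threshold`` ->
    attraction at ``d_interact``; adjacent fragments are skipped (the
    connected chain already constrains them).
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T):
        raise ValueError("5C matrix must be square and symmetric")
    out: list[Constraint] = []
    for i in range(n):
        for j in range(i + 2, n):  # j > i+1: skip adjacent pairs
            c = matrix[i, j]
            if c == 0:
                out.append(Constraint(ConstraintKind.PAIR_LOWER_BOUND, i, j, d_noninteract))
            elif c >= interaction_threshold:
                out.append(Constraint(ConstraintKind.PAIR_ATTRACT, i, j, d_interact))
    return out


def run_locus_ensemble(
    beads: list[Bead],
    constraints: list[Constraint],
    n: int = 1000,
    iterations: int = 40_000,
    cooling_rate: float = 0.000125,
    seed: int = 0,
    max_step: float = 50.0,
) -> tuple[StructureEnsemble, list[AnnealResult]]:
    """Anneal ``n`` locus conformations in an unbounded domain with
    whole-chain translation and rotation moves excluded (the internal
    moves fully explore a single free chain)."""
    model = BeadModel(beads=beads, constraints=constraints, geometry=None)
    schedule = AnnealSchedule(
        iterations=iterations,
        cooling_rate=cooling_rate,
        seed=seed,
        move_weights=(0.0, 0.0, 1.0, 1.0, 1.0),
        max_step=max_step,
    )
    return run_ensemble(model, schedule, n)


def procrustes_align(
    ensemble: StructureEnsemble,
    reference: int | None = None,
) -> StructureEnsemble:
    """Superpose every member onto a common reference by orthogonal
    Procrustes analysis: optimal rotation (reflections allowed) and
    translation, no scaling.

    The reference defaults to the member with the lowest recorded loss.
    A degenerate member with all beads coincident is left untransformed.
    """
    if len(ensemble) < 2:
        raise ValueError("alignment needs at least two members")
    if reference is None:
        reference = int(np.argmin(ensemble.losses)) if ensemble.losses else 0
    ref = ensemble.members[reference]
    ref_centroid = ref.mean(axis=0)
    ref_c = ref - ref_centroid
    aligned: list[np.ndarray] = []
    for m in ensemble.members:
        mc = m - m.mean(axis=0)
        if np.allclose(mc, 0.0):
            aligned.append(m.copy())
            continue
        Q, _ = orthogonal_procrustes(mc, ref_c)
        aligned.append(mc @ Q + ref_centroid)
    return StructureEnsemble(
        beads=list(ensemble.beads),
        members=aligned,
        losses=list(ensemble.losses),
        geometry=ensemble.geometry,
    )


def cluster_ensemble(
    ensemble: StructureEnsemble,
    n_clusters: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage agglomerative clustering of aligned members on
    Manhattan (city-block) distances between flattened coordinates.

    Returns integer labels (1-based, one per member) and the member
    indices of the largest cluster.
    """
    if len(ensemble) < 2:
        return np.ones(len(ensemble), dtype=int), np.arange(len(ensemble))
    X = ensemble.stacked().reshape(len(ensemble), -1)
    Z = linkage(X, method="average", metric="cityblock")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    sizes = np.bincount(labels)
    majority = int(np.argmax(sizes))
    return labels, np.flatnonzero(labels == majority)


def pair_distance_distribution(
    ensemble: StructureEnsemble, i: int, j: int
) -> np.ndarray:
    """Per-member Euclidean distance between two bead centers."""
    n = ensemble.n_beads
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"bead index out of range for {n} beads")
    stacked = ensemble.stacked()
    return np.linalg.norm(stacked[:, i] - stacked[:, j], axis=1)
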