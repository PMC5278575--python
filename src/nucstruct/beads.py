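"""Build a diploid bead-chain model from TAD and LAD tracks.

Each chromosome becomes a chain of beads tiling it end to end: overlapping
or book-ended TADs are merged, and every region not covered by a TAD gets
one gap bead.  Bead radii follow a volume-proportional law
(radius ∝ genomic length^(1/3)) scaled so that total bead volume equals a
fixed fraction of the model nucleus volume — 15% of a 5-μm-radius sphere by
default.  Beads overlapping a LAD by at least one base pair are flagged as
lamin-associated.  The haploid model is then duplicated into homologs A and
B, replicating constraints within each homolog.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import Bead, GenomicInterval, NucleusGeometry

__all__ = [
    "merge_and_fill",
    "build_beads",
    "scale_radii",
    "assign_lamin",
    "diploidize",
    "map_interactions_to_beads",
]


def merge_and_fill(
    tads: Iterable[GenomicInterval],
    chrom_sizes: Mapping[str, int],
) -> dict[str, list[GenomicInterval]]:
    """Merge overlapping/adjacent TADs and fill uncovered regions so each
    chromosome in ``chrom_sizes`` is tiled exactly by ``[0, size)``.

    Returns one ordered interval list per chromosome.  Chromosomes absent
    from ``chrom_sizes`` are rejected; so are intervals beyond the
    chromosome end.
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for t in tads:
        if t.chrom not in chrom_sizes:
            raise ValueError(f"TAD on unknown chromosome {t.chrom!r}")
        if t.end > chrom_sizes[t.chrom]:
            raise ValueError(
                f"TAD {t.chrom}:{t.start}-{t.end} exceeds chromosome size "
                f"{chrom_sizes[t.chrom]}"
            )
        by_chrom[t.chrom].append(t)

    tiling: dict[str, list[GenomicInterval]] = {}
    for chrom, size in chrom_sizes.items():
        merged: list[list[int]] = []
        for t in sorted(by_chrom.get(chrom, []), key=lambda t: (t.start, t.end)):
            if merged and t.start <= merged[-1][1]:  # overlap or book-ended
                merged[-1][1] = max(merged[-1][1], t.end)
            else:
                merged.append([t.start, t.end])
        out: list[GenomicInterval] = []
        cursor = 0
        for start, end in merged:
            if start > cursor:
                out.append(GenomicInterval(chrom, cursor, start))
            out.append(GenomicInterval(chrom, start, end))
            cursor = end
        if cursor < size:
            out.append(GenomicInterval(chrom, cursor, size))
        tiling[chrom] = out
    return tiling


def build_beads(tiling: Mapping[str, Sequence[GenomicInterval]]) -> list[Bead]:
    """Turn a per-chromosome tiling into beads with placeholder radii."""
    beads: list[Bead] = []
    for chrom in tiling:
        for iv in tiling[chrom]:
            beads.append(Bead(bead_id=len(beads), interval=iv))
    return beads


def scale_radii(beads: Sequence[Bead], geom: NucleusGeometry) -> list[Bead]:
    """Set radii proportional to genomic length^(1/3), normalized so total
    bead volume equals ``geom.occupancy`` of the nucleus volume.

    The cube-root law makes bead volume proportional to genomic length, so
    the occupancy constraint pins the single free prefactor:
    ``radius_i = c · L_i^(1/3)`` with ``c³ · Σ L_i = occupancy · R³``.
    """
    if not beads:
        raise ValueError("cannot scale an empty bead list")
    lengths = np.array([b.interval.length for b in beads], dtype=float)
    c = (geom.occupancy * geom.radius**3 / lengths.sum()) ** (1.0 / 3.0)
    return [b.with_radius(c * L ** (1.0 / 3.0)) for b, L in zip(beads, lengths)]


def assign_lamin(beads: Sequence[Bead], lads: Iterable[GenomicInterval]) -> list[Bead]:
    """Flag beads overlapping any LAD by >=1 bp; clear all other flags."""
    lads_by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for lad in lads:
        lads_by_chrom[lad.chrom].append(lad)
    out: list[Bead] = []
    for b in beads:
        flag = any(b.interval.overlaps(lad) for lad in lads_by_chrom.get(b.interval.chrom, ()))
        out.append(Bead(b.bead_id, b.interval, b.homolog, b.radius, flag))
    return out


def diploidize(
    beads: Sequence[Bead],
    pairs: Iterable[tuple[int, int]] = (),
) -> tuple[list[Bead], list[tuple[int, int]]]:
    """Duplicate a haploid model into homologs A and B.

    ``pairs`` are bead-index pairs (Hi-C constraints) on the haploid model;
    each is replicated within homolog A and within homolog B — never across
    homologs, since population-averaged input data cannot be phased.  Lamin
    flags are carried to both copies.  Returned bead ids are re-numbered
    0..2n−1 with homolog B appended after homolog A.
    """
    n = len(beads)
    out: list[Bead] = []
    for homolog, offset in (("A", 0), ("B", n)):
        for b in beads:
            out.append(Bead(b.bead_id + offset, b.interval, homolog, b.radius, b.lamin))
    out_pairs: list[tuple[int, int]] = []
    for i, j in pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"pair ({i}, {j}) outside haploid bead range 0..{n - 1}")
        out_pairs.append((i, j))
        out_pairs.append((i + n, j + n))
    return out, out_pairs


def map_interactions_to_beads(
    pairs: Iterable[tuple[str, int, str, int]],
    beads: Sequence[Bead],
    binsize: int,
) -> list[tuple[int, int]]:
    """Map significant bin pairs to bead-index pairs via bin midpoints.

    Each bin ``(chrom, start)`` is assigned to the bead whose interval
    contains its midpoint.  Pairs collapsing onto a single bead are dropped;
    duplicate bead pairs are de-duplicated.  Intended for a haploid bead
    list (diploidization replicates the pairs afterwards).
    """
    # index beads per chromosome, sorted by start, for bisection
    starts: dict[str, list[int]] = defaultdict(list)
    idx: dict[str, list[int]] = defaultdict(list)
    for k, b in enumerate(beads):
        starts[b.interval.chrom].append(b.interval.start)
        idx[b.interval.chrom].append(k)
    for chrom in starts:
        order = np.argsort(starts[chrom])
        starts[chrom] = [starts[chrom][o] for o in order]
        idx[chrom] = [idx[chrom][o] for o in order]

    def locate(chrom: str, binstart: int) -> int:
        mid = binstart + binsize // 2
        if chrom not in starts:
            raise ValueError(f"bin midpoint {chrom}:{mid} outside bead tiling")
        pos = int(np.searchsorted(starts[chrom], mid, side="right")) - 1
        if pos < 0:
            raise ValueError(f"bin midpoint {chrom}:{mid} precedes bead tiling")
        k = idx[chrom][pos]
        if not beads[k].interval.contains(chrom, mid):
            raise ValueError(f"bin midpoint {chrom}:{mid} outside bead tiling")
        return k

    seen: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    for chromA, binA, chromB, binB in pairs:
        i, j = locate(chromA, binA), locate(chromB, binB)
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out
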