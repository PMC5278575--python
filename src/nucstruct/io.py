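"""Readers and writers for the external text formats the tool touches.

Supported formats: BED (3+ columns, 0-based half-open) for TAD and LAD
tracks, whitespace-delimited sparse contact triplets
(``chromA binA chromB binB count``), a tab-delimited structure table (one
row per bead, coordinates in μm at genome scale), and Chimera CMM XML
marker files for visualization.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import Bead, ContactRecord, GenomicInterval

__all__ = [
    "read_bed",
    "read_chrom_sizes",
    "read_contacts",
    "write_contacts",
    "write_structure",
    "read_structure_table",
]


class ParseError(ValueError):
    """Raised for malformed input lines; carries the offending line number."""


_BED_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (>=3 tab-delimited columns) into intervals, in file
    order.  Header/comment lines (``#``, ``track``, ``browser``) are skipped
    and columns beyond the third are ignored."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-delimited columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                intervals.append(GenomicInterval(fields[0], start, end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>size`` file into an ordered mapping."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom size'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def read_contacts(path: str | Path, binsize: int) -> list[ContactRecord]:
    """Read sparse Hi-C contacts from a 5-column triplet file.

    Records are canonicalized (lexicographically lower endpoint first) and
    duplicate pairs are summed.  Bin coordinates must be multiples of
    ``binsize``; counts must be non-negative.
    """
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    counts: dict[tuple[str, int, str, int], int] = defaultdict(int)
    order: list[tuple[str, int, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 whitespace-delimited columns")
            chromA, chromB = fields[0], fields[2]
            try:
                binA, binB, count = int(fields[1]), int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count {count}")
            for b in (binA, binB):
                if b % binsize != 0:
                    raise ValueError(
                        f"{path}:{lineno}: bin {b} not aligned to binsize {binsize}"
                    )
            rec = ContactRecord.make(chromA, binA, chromB, binB, count)
            if rec.key not in counts:
                order.append(rec.key)
            counts[rec.key] += count
    return [ContactRecord(*key, counts[key]) for key in order]


def write_contacts(records: Iterable[ContactRecord], path: str | Path) -> None:
    """Dump contacts as a normalized, sorted triplet file."""
    recs = sorted(records, key=lambda r: r.key)
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f"{r.chromA}\t{r.binA}\t{r.chromB}\t{r.binB}\t{r.count}\n")


# ---------------------------------------------------------------------------
# structure output

_TABLE_COLUMNS = (
    "bead_id", "chrom", "homolog", "start", "end", "x", "y", "z", "radius", "lamin",
)

# qualitative palette cycled per chromosome for CMM coloring
_PALETTE = [
    (0.89, 0.10, 0.11), (0.22, 0.49, 0.72), (0.30, 0.69, 0.29),
    (0.60, 0.31, 0.64), (1.00, 0.50, 0.00), (1.00, 1.00, 0.20),
    (0.65, 0.34, 0.16), (0.97, 0.51, 0.75), (0.60, 0.60, 0.60),
]


def _check_finite(coords: np.ndarray) -> None:
    if not np.all(np.isfinite(coords)):
        bad = np.argwhere(~np.isfinite(coords))
        raise ValueError(f"non-finite coordinate at bead index {bad[0][0]}; refusing to write")


def write_structure(
    beads: Sequence[Bead],
    coords: np.ndarray,
    path: str | Path,
    dialect: str = "table",
) -> None:
    """Write one structure (bead list + coordinates) to disk.

    ``table`` emits a tab-delimited file, one row per bead, ordered by
    (chrom, homolog, start), with coordinates at full float precision.
    ``cmm`` emits a Chimera XML marker file with one marker per bead,
    colored by chromosome, and links joining chain successors.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(beads), 3):
        raise ValueError("coords shape must be (n_beads, 3)")
    _check_finite(coords)
    if dialect == "table":
        _write_table(beads, coords, path)
    elif dialect == "cmm":
        _write_cmm(beads, coords, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_table(beads: Sequence[Bead], coords: np.ndarray, path: str | Path) -> None:
    order = sorted(
        range(len(beads)),
        key=lambda k: (beads[k].interval.chrom, beads[k].homolog, beads[k].interval.start),
    )
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for k in order:
            b, (x, y, z) = beads[k], coords[k]
            fh.write(
                f"{b.bead_id}\t{b.interval.chrom}\t{b.homolog}\t"
                f"{b.interval.start}\t{b.interval.end}\t"
                f"{x:.17g}\t{y:.17g}\t{z:.17g}\t{b.radius:.17g}\t{int(b.lamin)}\n"
            )


def read_structure_table(path: str | Path) -> tuple[list[Bead], np.ndarray]:
    """Read back a structure table written by :func:`write_structure`."""
    beads: list[Bead] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TABLE_COLUMNS:
            raise ParseError(f"{path}:1: unrecognized structure-table header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_TABLE_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(_TABLE_COLUMNS)} columns")
            beads.append(
                Bead(
                    bead_id=int(f[0]),
                    interval=GenomicInterval(f[1], int(f[3]), int(f[4])),
                    homolog=f[2],
                    radius=float(f[8]),
                    lamin=bool(int(f[9])),
                )
            )
            rows.append([float(f[5]), float(f[6]), float(f[7])])
    return beads, np.asarray(rows, dtype=float)


def _chain_key(b: Bead) -> tuple[str, str]:
    return (b.interval.chrom, b.homolog)


def _write_cmm(beads: Sequence[Bead], coords: np.ndarray, path: str | Path) -> None:
    root = ET.Element("marker_set", name="nucstruct")
    chroms: list[str] = []
    for b in beads:
        if b.interval.chrom not in chroms:
            chroms.append(b.interval.chrom)
    color = {c: _PALETTE[i % len(_PALETTE)] for i, c in enumerate(chroms)}
    for k, b in enumerate(beads):
        r, g, bl = color[b.interval.chrom]
        ET.SubElement(
            root, "marker",
            id=str(k),
            x=f"{coords[k, 0]:.6f}", y=f"{coords[k, 1]:.6f}", z=f"{coords[k, 2]:.6f}",
            radius=f"{b.radius:.6f}",
            r=f"{r:.3f}", g=f"{g:.3f}", b=f"{bl:.3f}",
            chrID=b.interval.chrom, beadID=str(b.bead_id),
        )
    # link consecutive beads of the same chain (chrom + homolog)
    for k in range(len(beads) - 1):
        if _chain_key(beads[k]) == _chain_key(beads[k + 1]):
            ET.SubElement(root, "link", id1=str(k), id2=str(k + 1), r="0.5", g="0.5", b="0.5")
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
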