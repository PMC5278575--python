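"""Synthetic toy genomes, Hi-C contact maps and 5C matrices.

These generators emulate the statistical structure the method assumes:
TAD tilings of small chromosomes, clustered LAD blocks covering a set
fraction of the genome, power-law distance decay of intra-chromosomal
contact counts with heterogeneous per-bin propensities and a flat
inter-chromosomal background, planted enriched pairs for power/FDR
studies, and block-structured locus matrices.  Everything is a pure
function of (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import ContactRecord, GenomicInterval

__all__ = [
    "SyntheticSpec",
    "make_toy_genome",
    "make_synthetic_contacts",
    "make_locus_matrix",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic data generator.

    Defaults mirror typical 1-Mb-resolution Hi-C inputs: contact decay
    ~ d^(−1), LADs covering about a third of the genome in multi-TAD
    blocks, modest lognormal per-bin propensity spread standing in for
    GC/accessibility bias, and 8-fold-enriched planted pairs for
    recovery benchmarks.
    """

    n_chrom: int = 2
    chrom_size: int = 60_000_000
    binsize: int = 1_000_000
    tad_size_range: tuple[int, int] = (300_000, 1_200_000)
    lad_fraction: float = 0.3
    decay_exponent: float = 1.0
    base_intensity: float = 100.0
    inter_intensity: float = 0.5
    propensity_sigma: float = 0.25
    planted_pairs: int = 20
    enrichment: float = 8.0
    noise: str = "poisson"  # 'poisson' | 'negative_binomial'
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chrom < 1 or self.chrom_size < 1 or self.binsize < 1:
            raise ValueError("counts and sizes must be positive")
        lo, hi = self.tad_size_range
        if not 0 < lo <= hi:
            raise ValueError("invalid tad_size_range")
        if hi > self.chrom_size:
            raise ValueError("tad_size_range exceeds chromosome size")
        if not 0.0 <= self.lad_fraction <= 1.0:
            raise ValueError("lad_fraction must be in [0, 1]")
        if self.enrichment < 1.0:
            raise ValueError("enrichment must be >= 1")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def _chrom_names(n: int) -> list[str]:
    return [f"chr{k + 1}" for k in range(n)]


def make_toy_genome(
    spec: SyntheticSpec,
) -> tuple[dict[str, int], list[GenomicInterval], list[GenomicInterval]]:
    """Generate chromosome sizes, a TAD tiling and clustered LADs.

    TAD sizes are uniform in ``tad_size_range`` (the last TAD absorbs the
    chromosome remainder); LADs are contiguous runs of 2–6 TADs sampled
    until they cover ≈ ``lad_fraction`` of each chromosome, matching the
    block nature of real LADs and keeping LAD edges on TAD boundaries.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = {c: spec.chrom_size for c in _chrom_names(spec.n_chrom)}
    tads: list[GenomicInterval] = []
    lads: list[GenomicInterval] = []
    lo, hi = spec.tad_size_range

    for chrom, size in sizes.items():
        bounds = [0]
        while bounds[-1] < size:
            bounds.append(min(size, bounds[-1] + int(rng.integers(lo, hi + 1))))
        chrom_tads = [
            GenomicInterval(chrom, a, b) for a, b in zip(bounds, bounds[1:])
        ]
        tads.extend(chrom_tads)

        if spec.lad_fraction <= 0:
            continue
        n = len(chrom_tads)
        in_lad = np.zeros(n, dtype=bool)
        target = spec.lad_fraction * size
        covered = 0.0
        # sample multi-TAD runs until target coverage; bail when (nearly) full
        while covered < target and not in_lad.all():
            start = int(rng.integers(0, n))
            run = int(rng.integers(2, 7))
            for k in range(start, min(start + run, n)):
                if not in_lad[k]:
                    in_lad[k] = True
                    covered += chrom_tads[k].length
        # merge marked runs into LAD intervals
        k = 0
        while k < n:
            if in_lad[k]:
                j = k
                while j + 1 < n and in_lad[j + 1]:
                    j += 1
                lads.append(GenomicInterval(chrom, chrom_tads[k].start, chrom_tads[j].end))
                k = j + 1
            else:
                k += 1
    return sizes, tads, lads


def make_synthetic_contacts(
    spec: SyntheticSpec,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[list[ContactRecord], list[tuple[str, int, str, int]]]:
    """Simulate sparse Hi-C counts with planted enriched pairs.

    Intra-chromosomal means follow μ(d) = A·(d/binsize)^(−γ) multiplied by
    lognormal per-bin propensities (normalized to unit mean); planted
    pairs, sampled at separations of 2–20 bins, have their mean multiplied
    by the enrichment factor.  Inter-chromosomal means are flat.  Counts
    are Poisson or negative binomial; zero-count pairs are omitted from
    the sparse output.  Returns the records and the planted-pair ground
    truth (canonical bin keys).
    """
    rng = np.random.default_rng(spec.seed + 1)
    if chrom_sizes is None:
        chrom_sizes = {c: spec.chrom_size for c in _chrom_names(spec.n_chrom)}
    bs = spec.binsize
    n_bins = {c: -(-s // bs) for c, s in chrom_sizes.items()}
    chroms = list(n_bins)

    prop = {
        c: np.exp(rng.normal(0.0, spec.propensity_sigma, n_bins[c]))
        for c in chroms
    }
    for c in chroms:
        prop[c] /= prop[c].mean()

    # choose planted intra-chromosomal pairs at 2..20-bin separations
    candidates: list[tuple[str, int, int]] = []
    for c in chroms:
        B = n_bins[c]
        for i in range(B):
            for j in range(i + 2, min(i + 21, B)):
                candidates.append((c, i, j))
    n_plant = min(spec.planted_pairs, len(candidates))
    planted_idx = rng.choice(len(candidates), size=n_plant, replace=False)
    planted = {candidates[k] for k in planted_idx}

    def draw(mu: np.ndarray) -> np.ndarray:
        if spec.noise == "poisson":
            return rng.poisson(mu)
        r = 1.0 / spec.dispersion
        return rng.negative_binomial(r, r / (r + mu))

    records: list[ContactRecord] = []
    truth: list[tuple[str, int, str, int]] = []
    for c in chroms:
        B = n_bins[c]
        p = prop[c]
        ii, jj = np.triu_indices(B, k=1)
        mu = spec.base_intensity * (jj - ii) ** (-spec.decay_exponent) * p[ii] * p[jj]
        for k, (i, j) in enumerate(zip(ii, jj)):
            if (c, int(i), int(j)) in planted:
                mu[k] *= spec.enrichment
        counts = draw(mu)
        for i, j, x in zip(ii, jj, counts):
            if x > 0:
                records.append(ContactRecord(c, int(i) * bs, c, int(j) * bs, int(x)))
        for ci, i, j in sorted(planted):
            if ci == c:
                truth.append((c, i * bs, c, j * bs))

    for a in range(len(chroms)):
        for b in range(a + 1, len(chroms)):
            ca, cb = chroms[a], chroms[b]
            mu = spec.inter_intensity * np.outer(prop[ca], prop[cb])
            counts = draw(mu)
            for i, j in zip(*np.nonzero(counts)):
                records.append(
                    ContactRecord.make(ca, int(i) * bs, cb, int(j) * bs,
                                       int(counts[i, j]))
                )
    return records, truth


def make_locus_matrix(
    n_fragments: int,
    groups: int = 2,
    within_mean: float = 20.0,
    between_mean: float = 0.0,
    length_range: tuple[int, int] = (2_000, 10_000),
    seed: int = 0,
) -> tuple[np.ndarray, list[int]]:
    """Block-structured symmetric 5C count matrix plus fragment lengths.

    Fragments are split into ``groups`` contiguous blocks; within-block
    pairs have Poisson(``within_mean``) counts, between-block pairs
    Poisson(``between_mean``) (zero mean gives exact zeros).  Fragment
    lengths are uniform in ``length_range``.
    """
    if n_fragments < 3:
        raise ValueError("need at least 3 fragments")
    if groups < 1 or groups > n_fragments:
        raise ValueError("invalid group count")
    rng = np.random.default_rng(seed)
    block = np.repeat(np.arange(groups), -(-n_fragments // groups))[:n_fragments]
    mat = np.zeros((n_fragments, n_fragments))
    for i in range(n_fragments):
        for j in range(i + 1, n_fragments):
            mean = within_mean if block[i] == block[j] else between_mean
            mat[i, j] = mat[j, i] = rng.poisson(mean) if mean > 0 else 0.0
    lengths = rng.integers(length_range[0], length_range[1] + 1, n_fragments)
    return mat, [int(L) for L in lengths]
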