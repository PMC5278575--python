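"""Significance testing of Hi-C bin pairs against a distance-decay background.

The test asks, for each candidate bin pair, how surprising its observed
contact count is given (a) the total contact activity of each of the two
bins (their marginals), (b) the grand total of contacts, and (c) the
expected count for pairs at that genomic distance.  The observed count is
modeled with Fisher's non-central hypergeometric distribution
NCHG(N, n_i, n_j, ω): conditioning on the marginals absorbs per-bin
propensity (GC content, accessibility, copy number), while the odds
parameter ω tilts the null toward the distance-decay expectation,

    ω = E_decay(pair) / (n_i · n_j / N),

so the test reduces exactly to the central hypergeometric when the decay
background equals the marginal-product expectation.  Upper-tail p-values
are corrected with Benjamini–Hochberg, separately within the
intra-chromosomal and inter-chromosomal families; inter-chromosomal calls
can additionally be required to recur across supporting datasets.
"""
from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .core import ContactRecord

__all__ = [
    "DecayProfile",
    "NCHGResult",
    "SignificantCalls",
    "estimate_decay",
    "nchg_pvalue",
    "omega_for_pair",
    "call_significant",
    "recurrence_filter",
]

#: lower clamp for the odds parameter, used when the decay expectation is 0
OMEGA_FLOOR = 1e-12


@dataclass
class DecayProfile:
    """Distance-binned expected contact counts.

    ``expected_count[k]`` is the mean observed count over *all* bin pairs
    (zero-count pairs included) at genomic distance ``distance_bins[k]``;
    ``inter_expected`` is the single mean over all inter-chromosomal pairs.
    """

    binsize: int
    distance_bins: np.ndarray
    expected_count: np.ndarray
    inter_expected: float
    n_bins: dict[str, int] = field(default_factory=dict)

    def expected(self, rec_or_key) -> float:
        """Expected count for a (possibly zero-count) pair."""
        chromA, binA, chromB, binB = (
            rec_or_key.key if isinstance(rec_or_key, ContactRecord) else rec_or_key
        )
        if chromA != chromB:
            return self.inter_expected
        d = abs(binB - binA)
        k = d // self.binsize
        if k >= len(self.expected_count):
            raise ValueError(f"distance {d} outside the estimated decay range")
        return float(self.expected_count[k])

    def expected_marginal(self, chrom: str, binstart: int) -> float:
        """Expected total contact count of one bin under the decay profile
        (sum of the pair expectations over every partner bin), used to
        normalize observed marginals into per-bin propensities."""
        if chrom not in self.n_bins:
            raise ValueError(f"chromosome {chrom!r} not in the profile's bin universe")
        B = self.n_bins[chrom]
        i = binstart // self.binsize
        if not 0 <= i < B:
            raise ValueError(f"bin {binstart} outside chromosome {chrom}")
        d = np.abs(np.arange(B) - i)
        intra = float(self.expected_count[d[d > 0]].sum())
        other_bins = sum(b for c, b in self.n_bins.items() if c != chrom)
        return intra + self.inter_expected * other_bins

    def expected_total(self) -> float:
        """Expected grand total of contacts under the profile (each pair
        counted once): half the sum of expected marginals."""
        tot = 0.0
        for chrom, B in self.n_bins.items():
            for i in range(B):
                tot += self.expected_marginal(chrom, i * self.binsize)
        return 0.5 * tot


def _infer_n_bins(contacts: Sequence[ContactRecord], binsize: int) -> dict[str, int]:
    n_bins: dict[str, int] = {}
    for r in contacts:
        for chrom, b in ((r.chromA, r.binA), (r.chromB, r.binB)):
            n_bins[chrom] = max(n_bins.get(chrom, 0), b // binsize + 1)
    return n_bins


def estimate_decay(
    contacts: Sequence[ContactRecord],
    binsize: int,
    n_bins: Mapping[str, int] | None = None,
) -> DecayProfile:
    """Estimate the genomic-distance/contact-frequency relationship.

    For each intra-chromosomal distance ``d`` (a multiple of ``binsize``),
    the expectation is total observed count at ``d`` divided by the number
    of bin pairs at ``d``, counting zero-count pairs in the denominator.
    The bin universe per chromosome is taken from ``n_bins`` or inferred
    from the largest coordinate seen.
    """
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    nb = dict(n_bins) if n_bins is not None else _infer_n_bins(contacts, binsize)
    if not nb:
        raise ValueError("no contacts to estimate a decay profile from")

    max_b = max(nb.values())
    sums = np.zeros(max_b, dtype=float)
    inter_sum = 0.0
    any_intra = False
    for r in contacts:
        if r.is_intra:
            any_intra = True
            sums[abs(r.binB - r.binA) // binsize] += r.count
        else:
            inter_sum += r.count
    if not any_intra:
        raise ValueError("no intra-chromosomal contacts; cannot estimate decay")

    # pairs at distance d bins on a chromosome of B bins: max(0, B - d)
    npairs = np.zeros(max_b, dtype=float)
    for B in nb.values():
        d = np.arange(max_b)
        npairs += np.maximum(0, B - d)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = np.where(npairs > 0, sums / np.maximum(npairs, 1), 0.0)

    chroms = list(nb)
    inter_pairs = 0.0
    for a in range(len(chroms)):
        for b in range(a + 1, len(chroms)):
            inter_pairs += nb[chroms[a]] * nb[chroms[b]]
    inter_expected = inter_sum / inter_pairs if inter_pairs > 0 else 0.0

    return DecayProfile(
        binsize=binsize,
        distance_bins=np.arange(max_b) * binsize,
        expected_count=expected,
        inter_expected=inter_expected,
        n_bins=nb,
    )


def nchg_pvalue(x: int, n_i: int, n_j: int, N: int, omega: float) -> float:
    """Upper tail P(X >= x) of Fisher's non-central hypergeometric
    distribution with parameters (N, n_i, n_j, omega).

    Computed over the full support ``max(0, n_i+n_j−N)..min(n_i, n_j)``
    with log-space weights ``log C(n_i,k) + log C(N−n_i, n_j−k) + k·log ω``
    normalized by logsumexp; exact (up to rounding) for any ω > 0.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if n_i < 0 or n_j < 0 or n_i > N or n_j > N:
        raise ValueError(f"inconsistent marginals n_i={n_i}, n_j={n_j}, N={N}")
    kmin, kmax = max(0, n_i + n_j - N), min(n_i, n_j)
    if not 0 <= x <= kmax:
        raise ValueError(f"x={x} outside support [0, {kmax}]")
    if x <= kmin:
        return 1.0
    k = np.arange(kmin, kmax + 1)
    logw = (
        gammaln(n_i + 1) - gammaln(k + 1) - gammaln(n_i - k + 1)
        + gammaln(N - n_i + 1) - gammaln(n_j - k + 1) - gammaln(N - n_i - n_j + k + 1)
        + k * math.log(omega)
    )
    tail = logsumexp(logw[k >= x]) - logsumexp(logw)
    return float(min(1.0, math.exp(tail)))


def omega_for_pair(
    profile: DecayProfile,
    pair: tuple[str, int, str, int],
    expected_total: float | None = None,
) -> float:
    """Odds parameter tilting the NCHG null toward the distance-decay
    expectation.

    For independent Poisson counts, the count of one pair conditional on
    its two marginals and the grand total follows Fisher's NCHG exactly,
    with ω equal to the odds ratio of the collapsed 2×2 table of means.
    Evaluating that table under the decay profile (pair mean E, expected
    marginals m_i, m_j, expected total M) gives

        ω = E · (M − m_i − m_j + E) / ((m_i − E) · (m_j − E)).

    The observed marginals then supply the per-bin propensity adjustment
    through the NCHG conditioning itself.  ω = 1 exactly (central test)
    when E equals the independence expectation m_i·m_j/M.  Clamped to
    [:data:`OMEGA_FLOOR`, ∞); degenerate margins fall back to the floor.
    """
    chromA, binA, chromB, binB = pair
    m_i = profile.expected_marginal(chromA, binA)
    m_j = profile.expected_marginal(chromB, binB)
    M = profile.expected_total() if expected_total is None else expected_total
    E = profile.expected(pair)
    denom = (m_i - E) * (m_j - E)
    if denom <= 0:
        return OMEGA_FLOOR
    rest = M - m_i - m_j + E
    if rest <= 0:
        return OMEGA_FLOOR
    return max(E * rest / denom, OMEGA_FLOOR)


@dataclass(frozen=True)
class NCHGResult:
    """Per-pair significance result."""

    pair: tuple[str, int, str, int]
    observed: int
    n_i: int
    n_j: int
    N: int
    expected: float
    omega: float
    p: float
    q: float = float("nan")

    @property
    def is_intra(self) -> bool:
        return self.pair[0] == self.pair[2]


@dataclass
class SignificantCalls:
    """Output of :func:`call_significant`.

    ``intra`` holds only the intra-chromosomal pairs passing the FDR
    threshold; ``inter`` holds *all* tested inter-chromosomal candidates
    with q-values adjusted within the inter-chromosomal family, so that
    recurrence filtering can be applied downstream.
    """

    binsize: int
    fdr: float
    intra: list[NCHGResult]
    inter: list[NCHGResult]

    def significant_inter_keys(self) -> set[tuple[str, int, str, int]]:
        return {r.pair for r in self.inter if r.q <= self.fdr}

    @property
    def pairs(self) -> list[tuple[str, int, str, int]]:
        return [r.pair for r in self.intra]


def _marginals(contacts: Sequence[ContactRecord], binsize: int) -> tuple[dict, int]:
    n: dict[tuple[str, int], int] = defaultdict(int)
    N = 0
    for r in contacts:
        N += r.count
        n[(r.chromA, r.binA)] += r.count
        if (r.chromA, r.binA) != (r.chromB, r.binB):
            n[(r.chromB, r.binB)] += r.count
    return n, N


def _bh(results: list[NCHGResult]) -> list[NCHGResult]:
    if not results:
        return []
    pvals = np.array([r.p for r in results])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        NCHGResult(r.pair, r.observed, r.n_i, r.n_j, r.N, r.expected, r.omega, r.p, float(q))
        for r, q in zip(results, qvals)
    ]


def call_significant(
    contacts: Sequence[ContactRecord],
    binsize: int,
    fdr_intra: float = 1e-4,
    min_count: int = 3,
    n_bins: Mapping[str, int] | None = None,
) -> SignificantCalls:
    """Test every candidate pair (observed count >= ``min_count``) for
    enrichment over the distance-decay background.

    Benjamini–Hochberg adjustment is applied genome-wide, separately to the
    intra- and inter-chromosomal families.  Intra-chromosomal pairs are
    returned only if ``q <= fdr_intra``; all inter-chromosomal candidates
    are returned with their p/q for downstream recurrence filtering.
    """
    if not 0 < fdr_intra < 1:
        raise ValueError("fdr_intra must lie strictly between 0 and 1")
    profile = estimate_decay(contacts, binsize, n_bins=n_bins)
    marg, N = _marginals(contacts, binsize)
    M = profile.expected_total()

    intra: list[NCHGResult] = []
    inter: list[NCHGResult] = []
    for r in contacts:
        if r.count < min_count:
            continue
        n_i = marg[(r.chromA, r.binA)]
        n_j = marg[(r.chromB, r.binB)]
        x = min(r.count, min(n_i, n_j))
        omega = omega_for_pair(profile, r.key, M)
        p = nchg_pvalue(x, n_i, n_j, N, omega)
        res = NCHGResult(r.key, r.count, n_i, n_j, N, profile.expected(r.key), omega, p)
        (intra if r.is_intra else inter).append(res)

    intra = [r for r in _bh(intra) if r.q <= fdr_intra]
    inter = _bh(inter)
    return SignificantCalls(binsize=binsize, fdr=fdr_intra, intra=intra, inter=inter)


def recurrence_filter(
    focal: SignificantCalls,
    others: Iterable[SignificantCalls],
    min_support: int = 4,
) -> list[tuple[str, int, str, int]]:
    """Keep inter-chromosomal pairs significant in the focal dataset and in
    strictly more than ``min_support`` of the other datasets."""
    others = list(others)
    for o in others:
        if o.binsize != focal.binsize:
            raise ValueError(
                f"bin grid mismatch: focal binsize {focal.binsize}, other {o.binsize}"
            )
    other_keys = [o.significant_inter_keys() for o in others]
    kept: list[tuple[str, int, str, int]] = []
    for key in sorted(focal.significant_inter_keys()):
        support = sum(key in ks for ks in other_keys)
        if support > min_support or (not others and min_support == 0):
            kept.append(key)
    return kept
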