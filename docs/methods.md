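# Methods

## Model

`nucstruct` models each chromosome as a chain of touching spherical beads
inside a spherical nucleus of radius *R* (default 5 μm). At genome scale a
bead is one contact domain (TAD) or one uncovered gap region; at locus
scale a bead is one restriction fragment. The modeled structure is the set
of bead centers **b**₁…**b**ₙ; consecutive beads of a chain are
constrained to touch exactly (center distance = sum of radii), which is
maintained by construction rather than by a penalty: every Monte Carlo
move is a rigid transform of the affected run of beads.

Three data-derived restraint kinds act on the structure, plus one weak
prior, each contributing a weighted quadratic term to the loss

&nbsp;&nbsp;&nbsp;&nbsp;L = Σ k·f(‖**b**ᵢ − **b**ⱼ‖, d)²

- **pair attraction** (significant Hi-C pair, or 5C interaction): target
  distance d = rᵢ + rⱼ (touching without overlap); two-sided quadratic.
- **pair lower bound** (5C non-interaction): one-sided, penalizes only
  distances below the target.
- **periphery** (lamin-associated bead): distance to a zero-radius dummy
  bead at the origin, target d = R − rᵢ, one-sided (penalizes only being
  too central — hard containment makes the outer side unreachable, so a
  two-sided term would behave identically at feasible points).
- **center** (all other beads): pull toward the origin with target 0 and a
  small default weight k = 0.01 against 1.0 for the other kinds. A
  full-strength pull on every bead would collapse the interior and
  contradict the roughly even interior distribution the pair constraints
  should produce; the weak prior only breaks the degeneracy of otherwise
  unconstrained beads. Setting the weight to zero omits the prior
  entirely.

### Bead geometry

Bead volume is proportional to genomic length: radius = c·L^(1/3), with
the single prefactor c pinned by the occupancy condition that total bead
volume equal a fixed fraction (default 15%) of the nucleus volume over the
full diploid bead set. Overlapping *and* book-ended input domains are
merged; every uncovered region becomes exactly one gap bead, with no size
cap. A bead is lamin-flagged iff its interval overlaps a LAD by at least
one base pair. Diploidization duplicates every chain into homologs A and
B and replicates pair constraints and lamin flags within each homolog,
never across: population-averaged Hi-C and ChIP-seq cannot be phased, so
symmetric duplication is the only defensible assignment.

At locus scale the bead radius is 0.005 nm per bp of fragment length.
The published bead statistics for the α-globin ENm008 region (lengths
2 / 5151 / 7043 bp ↔ radii 0.01 / 25.76 / 35.21 nm) are consistent only
with this being a *radius*, although the accompanying prose says
"diameter"; we follow the numbers.

### Optimization

Metropolis–Hastings simulated annealing. Per iteration one of five
connectivity-preserving moves is drawn according to user weights (equal
by default):

1. whole-chain translation (random direction, length ≤ `max_step`);
2. whole-chain rotation about its center of mass;
3. crankshaft: rotation of an interior run about the axis through its two
   flanking beads;
4. arm pivot: rigid rotation of a terminal run about a random axis
   through its hinge bead;
5. single-bead hinge: an interior bead resampled uniformly on the circle
   preserving its exact distances to both neighbors (a terminal bead on
   the sphere around its single neighbor).

A proposal is rejected outright if any moved bead overlaps another bead
(center distance < sum of radii) or leaves the nucleus (‖**b**‖ + r > R);
otherwise it is accepted iff ΔL ≤ 0 or u < exp(−ΔL/T). Temperature cools
geometrically, T ← T·(1 − cooling_rate), from T₀ = initial loss / bead
count unless set explicitly; T₀ = 0 gives strictly greedy dynamics,
used by the monotonicity tests. Clash tests compare the moved beads
against all others with a vectorized distance check (exact all-pairs
semantics, verified against brute force in the tests); with an absolute
slack of 1e−9 so that exactly-touching chain neighbors never register as
clashes. Because all moves are rigid, consecutive-bead distances drift
only by accumulated floating-point rounding, orders of magnitude below
the 1e−6 relative tolerance asserted on every reported structure.

Initial structures are self-avoiding random walks grown bead by bead
directly inside the nucleus (consecutive beads touching, containment and
cross-chain avoidance enforced at every step), with per-chain and global
restarts; infeasible geometries fail loudly rather than returning an
overlapping configuration.

Ensembles are n independent initialization+annealing runs whose RNG
streams are spawned deterministically from one master seed
(`numpy.random.SeedSequence.spawn`), so results are reproducible and
independent of execution order. A failed member is skipped with a
warning; the remaining members are returned.

### Significant Hi-C interactions

Candidate bin pairs (observed count ≥ `min_count`, default 3) are tested
against a distance-decay background. The decay profile is the mean
observed count over *all* bin pairs at each genomic distance (zero-count
pairs included in the denominator), at the analysis bin size (default
1 Mb); the inter-chromosomal background is the single mean over all
inter-chromosomal bin pairs.

The test statistic is the observed count x conditional on the two bin
marginals n_i, n_j and the grand total N, modeled with Fisher's
non-central hypergeometric distribution NCHG(N, n_i, n_j, ω) and an
upper-tail p-value computed over the full support in log space. For
independent Poisson counts this conditional distribution is *exact* once
ω equals the odds ratio of the collapsed 2×2 table of means, so we set

&nbsp;&nbsp;&nbsp;&nbsp;ω = E·(M − m_i − m_j + E) / ((m_i − E)(m_j − E)),

where E is the decay expectation for the pair, m_i, m_j the *expected*
marginals of the two bins under the profile, and M the expected total.
The observed marginals then carry the per-bin propensity adjustment
(GC content, accessibility, copy number) through the conditioning itself,
while ω carries the distance dependence; ω = 1 exactly — a central
hypergeometric test — when E equals the independence expectation
m_i·m_j/M. Simpler first-order mappings (ω = E/(n_i·n_j/N), or the same
with expected marginals) were evaluated and rejected: both are
anti-conservative on deep synthetic data — the first because it cancels
the marginal conditioning entirely, the second at short distances where a
single pair is a non-negligible fraction of its marginals. Under the
package's null generator the final form yields zero calls at q ≤ 1e−4
over ten seeds and candidate p-values stochastically ≥ uniform.

Benjamini–Hochberg correction is applied genome-wide, separately within
the intra- and inter-chromosomal families (the two have different
backgrounds and different downstream filters). Intra-chromosomal pairs
are reported at q ≤ the FDR threshold (default 1e−4, i.e. FDR 0.01%);
inter-chromosomal candidates are all returned so that a recurrence filter
can require significance in strictly more than `min_support` supporting
datasets.

### Structure analysis

Radial position is always measured at the bead *center*. The
periphery/center boundary defaults to the equal-volume radius
r_half_v = R·2^(−1/3) (3.97 μm for R = 5 μm, equivalently a 1.03-μm
shell); a fixed-thickness shell (e.g. 1 μm) can be requested instead. A
bead is peripheral in a structure iff ‖**b**‖ ≥ boundary (ties
peripheral, matching the "< boundary ⇒ central" convention). Across an
ensemble, a bead is classified *periphery* if its shell fraction is
strictly > 0.67, *center* if strictly < 0.33, *intermediate* otherwise.

Chromosome shape is summarized by the volume-weighted (mass ∝ r³) radius
of gyration and by the normalized asphericity
b = (λ₁ − (λ₂+λ₃)/2)/(λ₁+λ₂+λ₃) of the gyration-tensor eigenvalues —
0 for spherically symmetric clouds, 1 in the rod limit, with 0 returned
by convention for fully coincident beads.

Model-vs-input agreement reconstructs a contact-frequency matrix (a pair
is in contact in a member iff center distance ≤ rᵢ + rⱼ + margin; the
margin defaults to 10% of the median bead radius, as no threshold is
canonical) and reports a Spearman rank correlation against the input
counts over the shared grid — rank-based because Hi-C counts are
heavy-tailed.

### Locus mode

Constraints from a symmetric 5C count matrix: zero-count non-adjacent
pairs become lower bounds at a non-interaction distance, pairs at or
above a count threshold become attractions at an interaction distance;
thresholds and the two distances are cell-type-specific inputs, not
constants, because no universal count→distance conversion exists.
Adjacent fragments get no extra restraint — the connected chain already
constrains them. Ensembles run with whole-chain translation and rotation
weights set to zero (a single unbounded chain has no meaningful global
pose) and, by default, no bounding nucleus; defaults are 1000 structures
of 40,000 iterations at cooling rate 0.000125.

Members are superposed by orthogonal Procrustes analysis onto the
lowest-loss member (rotations and reflections, no scaling) and clustered
by average-linkage agglomerative clustering on Manhattan distances
between flattened coordinate vectors, cut at two clusters by default; the
majority cluster is reported. Average linkage and the two-cluster cut are
package choices where only the method family and metric are canonical.

## Synthetic data

The generators produce what the method consumes, with the statistical
features it assumes:

- **Toy genomes**: chromosomes tiled by TADs with sizes uniform in a
  range (default 0.3–1.2 Mb on 60-Mb chromosomes); LADs as contiguous
  runs of 2–6 TADs covering ≈ a target fraction (default 0.3) of the
  genome, mirroring the blocky nature of real LADs and keeping LAD edges
  on TAD boundaries so flag assignment is unambiguous (partial-overlap
  cases are built ad hoc in the unit tests).
- **Contact maps**: intra-chromosomal means A·(d/binsize)^(−γ) with γ = 1
  and A = 100 expected counts at one-bin separation — emulating the deep,
  billion-contact 1-Mb maps this kind of analysis targets; multiplicative
  per-bin lognormal propensities (σ = 0.25) standing in for GC and
  accessibility bias; a flat inter-chromosomal background; Poisson noise
  by default with a negative-binomial option (real Hi-C is overdispersed);
  and planted pairs (default 20 at 8-fold enrichment, at separations of
  2–20 bins) with a returned ground truth for power/FDR benchmarking.
- **Locus matrices**: block-structured symmetric counts (within-block
  Poisson mean 20, between-block 0 by default) plus fragment lengths
  uniform in 2–10 kb.

What the generators do **not** emulate: copy-number variation and
karyotype abnormalities, distance-decay exponents that vary along the
genome, A/B-compartment plaid structure, and unmappable regions. Passing
the planted-pair benchmark therefore demonstrates calibration against
marginal heterogeneity and distance decay, not robustness to structural
artifacts of real cancer genomes.

## Problem sizes and fixtures

The test and acceptance workloads use deliberately small systems chosen
to exercise every code path at interactive scale: a two-chain, 20-bead
model (10 × 1-Mb beads per chain, three pair constraints, two or five
lamin beads) annealed for 20,000–50,000 iterations, ensembles of 20
structures, synthetic maps of 2 × 60 bins at 1 Mb, and loci of 8–15
fragments. The engine toy uses occupancy 0.01 so that bead radius
relative to the nucleus (≈0.08·R) is close to the genome-scale regime
(≈0.02·R for ~14,000 beads at 15%), rather than the jammed geometry that
15% occupancy would impose on only 20 beads; its constraint set is fully
satisfiable, so the optimizer's convergence criterion (final loss below
5% of initial) measures optimization quality rather than an irreducible
modeling residual. Genome-scale runs (thousands of beads, 2×10⁶
iterations, hundreds of structures) use the same code paths and are
embarrassingly parallel over member seeds.

## Numerical choices

- NCHG tails in log space via `gammaln` + `logsumexp`; exact reduction to
  the central hypergeometric at ω = 1 is verified against brute-force
  enumeration over all parameter combinations with N ≤ 60, and against
  `scipy.stats.nchypergeom_fisher` on random grids.
- ω is clamped below at 1e−12 (a zero decay expectation is maximally
  conservative for enrichment); degenerate collapsed tables fall back to
  the clamp.
- Geometry tolerances: clash/containment slack 1e−9 (absolute, μm or
  nm); structure validation 1e−6 relative; degenerate move geometry
  (zero-length crankshaft axis, collinear hinge) causes the move to be
  resampled, not an error.
- Coordinates are stored in structure tables at 17 significant digits, so
  write→read round-trips are bit-exact.
- Annealing keeps an incrementally updated loss; the final loss is
  recomputed from scratch at the end to cancel accumulated summation
  drift.

## Known limitations

- The clash check is O(moved × all beads) per proposal; adequate to a few
  thousand beads, but a spatial grid would be needed well beyond that.
- The NCHG ω uses expected (not fitted) marginals; extreme per-bin biases
  far outside the lognormal regime tested here may degrade calibration.
- No ICE/KR balancing, loop calling, or TAD calling: domains and raw
  counts are inputs.
- Single spherical nucleus only; no nucleoli or other internal anchors,
  though the constraint vocabulary (radial targets to a dummy bead)
  would extend to them.
- Whole-genome runs at published scale are compute-bound in pure Python;
  expect hours per 2×10⁶-iteration structure at ~14,000 beads.
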