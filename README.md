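# nucstruct

Ensemble 3D genome modeling from Hi-C interactions and lamin-based radial
constraints.

`nucstruct` is for researchers studying the spatial organization of
genomes — in particular where chromatin domains sit relative to the
nuclear periphery, and how lamin–genome contacts shape that radial
organization. It builds beads-on-a-string chromosome models in which each
bead is a topologically associating domain (TAD), constrains them with
(a) statistically significant Hi-C contacts and (b) lamin ChIP-seq
lamin-associated domains (LADs), optimizes ensembles of structures by
simulated annealing inside a spherical nucleus, and analyzes the radial
organization of the result. A fragment-resolution mode models single loci
from 5C matrices.

## The model

Each chromosome is a chain of touching spherical beads (consecutive
center distance = sum of radii, preserved exactly by every Monte Carlo
move). Bead volume is proportional to genomic length, scaled so all
diploid beads together fill 15% of a 5-μm-radius nucleus. Structures
minimize the loss

```
L = Σ k_ij (‖b_i − b_j‖ − d_ij)²
```

summed over constraints: pair attractions between significantly
interacting TADs (target d = r_i + r_j), radial restraints pulling
lamin-associated TADs to the nuclear wall (target d = R − r_i, measured
to a zero-radius dummy bead at the origin), and a weak centering prior on
the remaining beads. Optimization is Metropolis–Hastings annealing over
five connectivity-preserving moves (chain translation, chain rotation,
crankshaft, arm pivot, single-bead hinge), with clash and containment
rejection.

Significant Hi-C pairs are found by testing each bin pair's count x
against Fisher's non-central hypergeometric null
NCHG(N, n_i, n_j, ω) — conditional on the bin marginals and the total —
with the odds ω tilting the null toward the distance-decay expectation
(ω = 1 reduces to a central hypergeometric test when the decay matches
the independence expectation). Intra-chromosomal calls use
Benjamini–Hochberg FDR (default 0.01%); inter-chromosomal calls can
additionally be required to recur across supporting datasets.

Radial readouts divide the nucleus at the equal-volume radius
r_half_v = R·2^(−1/3) (3.97 μm for R = 5 μm) and classify each TAD as
peripheral (> 67% of structures in the shell), central (< 33%) or
intermediate. Chromosome territories are summarized by volume-weighted
gyration radii and gyration-tensor asphericity.

See `docs/methods.md` for the full model description, parameter
rationale, and numerical details.

## Worked example

Call significant contacts on a synthetic Hi-C map with 20 planted
enriched pairs:

```python
import numpy as np
import nucstruct as ns

spec = ns.SyntheticSpec(seed=0)                      # 2 chromosomes x 60 Mb
records, truth = ns.make_synthetic_contacts(spec)
calls = ns.call_significant(records, spec.binsize, fdr_intra=1e-4)
print(f"significant intra-chromosomal pairs: {len(calls.intra)}")
print(f"planted pairs recovered: {len({r.pair for r in calls.intra} & set(truth))}/{len(truth)}")
top = max(calls.intra, key=lambda r: r.observed)
print(f"strongest call: {top.pair[0]}:{top.pair[1]}-{top.pair[3]} "
      f"count={top.observed} expected={top.expected:.1f} q={top.q:.2e}")
```

```
significant intra-chromosomal pairs: 20
planted pairs recovered: 20/20
strongest call: chr1:44000000-49000000 count=185 expected=21.0 q=5.36e-69
```

All 20 planted pairs are recovered with no false calls; the strongest
sits ~9-fold above its distance-decay expectation.

Then model a small two-chromosome system with three lamin-associated
TADs and two Hi-C pair constraints, and ask where the lamin TADs end up:

```python
from nucstruct.engine import BeadModel

beads = []
for chrom in ("chr1", "chr2"):
    for k in range(10):
        beads.append(ns.Bead(len(beads),
                     ns.GenomicInterval(chrom, k * 1_000_000, (k + 1) * 1_000_000)))
geom = ns.NucleusGeometry(radius=5.0, occupancy=0.01)
beads = ns.scale_radii(beads, geom)
for i in (2, 3, 7):                                  # lamin-associated TADs
    beads[i] = ns.Bead(i, beads[i].interval, beads[i].homolog, beads[i].radius, True)
constraints = ns.build_constraints(beads, [(1, 8), (5, 12)], geom)
model = BeadModel(beads=beads, constraints=constraints, geometry=geom)

schedule = ns.AnnealSchedule(iterations=20_000, cooling_rate=0.0003, seed=1)
ensemble, results = ns.run_ensemble(model, schedule, 10)
print(f"mean loss: {np.mean([r.initial_loss for r in results]):.1f} -> "
      f"{np.mean(ensemble.losses):.3f}")

boundary = ns.half_volume_radius(geom.radius)
cls = ns.classify_radial(ensemble, boundary)
lamin_frac = np.mean([c.shell_fraction for c, b in zip(cls, beads) if b.lamin])
other_frac = np.mean([c.shell_fraction for c, b in zip(cls, beads) if not b.lamin])
print(f"equal-volume boundary: {boundary:.2f} um")
print(f"shell occupancy: lamin TADs {lamin_frac:.2f}, other TADs {other_frac:.2f}")
```

```
mean loss: 26.3 -> 1.094
equal-volume boundary: 3.97 um
shell occupancy: lamin TADs 1.00, other TADs 0.01
```

Annealing cut the loss ~25-fold (the residual is the weak centering
prior); the lamin-flagged TADs sit in the peripheral equal-volume shell
in every structure, and the unflagged TADs almost never do.

## Command line

The same pipeline is exposed as a CLI:

```sh
nucstruct simulate-data --out-dir fixtures/          # synthetic genome + Hi-C
nucstruct interactions fixtures/contacts.txt --binsize 1000000 --out sig.tsv
nucstruct model --tads fixtures/tads.bed --chrom-sizes fixtures/chrom.sizes \
    --lads fixtures/lads.bed --interactions sig.tsv \
    --n-structures 10 --seed 1 --out-dir structures/
nucstruct analyze structures/ --out-prefix results/ensemble
nucstruct locus matrix.tsv --fragments frags.bed --threshold 5 \
    --d-interact 150 --d-noninteract 120 --out-dir locus_out/
```

`model` writes one coordinate table and one Chimera CMM marker file per
structure; `analyze` emits per-bead radial classifications, per-chromosome
shape descriptors and a radial density profile as TSV.

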