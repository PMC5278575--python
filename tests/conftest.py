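"""Shared fixtures: a small diploid-style toy model used across the
engine, analysis and acceptance tests."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import nucstruct as ns
from nucstruct.engine import BeadModel

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_toy_model(
    occupancy: float = 0.01,
    lamin_ids: tuple[int, ...] = (3, 15),
    pairs: tuple[tuple[int, int], ...] = ((1, 8), (5, 12), (11, 18)),
    center_weight: float = 0.0,
    lamin_constrained: bool = True,
) -> BeadModel:
    """Two chains of 10 one-Mb beads in a 5-μm nucleus.

    The default constraint set is exactly the three pair attractions and
    the periphery restraints of the lamin-flagged beads (a satisfiable
    set); a weak center pull can be added via ``center_weight``.
    ``lamin_constrained=False`` keeps the flags (for readouts) but builds
    the constraints as if no bead were lamin-associated.
    """
    beads = []
    for chrom in ("chr1", "chr2"):
        for k in range(10):
            beads.append(
                ns.Bead(len(beads),
                        ns.GenomicInterval(chrom, k * 1_000_000, (k + 1) * 1_000_000))
            )
    geom = ns.NucleusGeometry(5.0, occupancy)
    beads = ns.scale_radii(beads, geom)
    for i in lamin_ids:
        beads[i] = ns.Bead(i, beads[i].interval, beads[i].homolog, beads[i].radius, True)
    if lamin_constrained:
        cbeads = beads
    else:
        cbeads = [ns.Bead(b.bead_id, b.interval, b.homolog, b.radius, False) for b in beads]
    cons = ns.build_constraints(cbeads, list(pairs), geom, center_weight=center_weight)
    return BeadModel(beads=beads, constraints=cons, geometry=geom)


@pytest.fixture(scope="session")
def toy_model() -> BeadModel:
    return make_toy_model()


@pytest.fixture(scope="session")
def toy_coords(toy_model) -> np.ndarray:
    return ns.init_structure(toy_model, seed=0)


@pytest.fixture(scope="session")
def small_ensemble(toy_model):
    """A quick 5-member annealed ensemble of the toy model."""
    sched = ns.AnnealSchedule(iterations=8_000, cooling_rate=0.0005, seed=11)
    ensemble, results = ns.run_ensemble(toy_model, sched, 5)
    return ensemble, results
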