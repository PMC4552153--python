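"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import pytest

from rjmap import junctions as jx
from rjmap import probedesign as pdx
from rjmap import synthdata as sd


@pytest.fixture(scope="session")
def small_library():
    return sd.build_repeat_library(4, 3, (300, 800), seed=11)


@pytest.fixture(scope="session")
def small_genome(small_library):
    return sd.simulate_genome(
        small_library,
        [("1D", 60_000, 0.45), ("2D", 50_000, 0.5)],
        te_count=20,
        nesting_prob=0.2,
        gene_count=20,
        seed=1,
    )


@pytest.fixture(scope="session")
def design_run(small_library, small_genome):
    """One full probe-design pipeline run on a small genome.

    Discovery reads carry sequencing errors; validation and target reads are
    deterministic tilings so occupancy-based filters see noise-free depth.
    """
    g = small_genome
    discovery = sd.simulate_reads(g, 1.0, 400, substitution_rate=0.003, seed=5)
    validation = sd.tile_reads(g, 30.0, 520)
    target = sd.tile_reads(g, 5.0, 520)
    detected = jx.scan_reads(discovery, small_library)
    genes = [(gid, g.sequences[c][a:b]) for c, (a, b), gid in g.genes]
    probeset = pdx.run_design_pipeline(
        detected,
        {r.id: r.sequence for r in discovery.reads},
        validation,
        target,
        genes,
    )
    return {
        "genome": g,
        "library": small_library,
        "discovery": discovery,
        "validation": validation,
        "target": target,
        "junctions": detected,
        "probeset": probeset,
    }
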