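import numpy as np
import pytest

import regulome as r
from regulome.synth import PlantedBlock, SynthConfig, simulate_regulome_inputs


@pytest.fixture
def genome():
    return r.GenomeSpec({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_tracks(genome, rng, n_segments=200, n_points=500):
    """A random segment track and point track for oracle comparisons."""
    segs = []
    for i, chrom in enumerate(("chr1", "chr2")):
        length = genome.length_of(chrom)
        n = n_segments // 2
        starts = rng.integers(0, length - 2000, size=n)
        widths = rng.integers(1, 2000, size=n)
        segs += [
            r.GenomicSegment(chrom, int(s), int(min(s + w, length)), "+", f"g{i}_{j}")
            for j, (s, w) in enumerate(zip(starts, widths))
        ]
    pts = [
        r.GenomicPoint(chrom, int(p))
        for chrom in ("chr1", "chr2")
        for p in rng.integers(0, genome.length_of(chrom), size=n_points // 2)
    ]
    return (
        r.SegmentTrack("segs", segs, genome),
        r.PointTrack("pts", pts, genome),
    )


def brute_force_segments_hit(segments, points):
    """O(S*P) containment oracle, independent of the searchsorted path."""
    pts = list(points)
    return sum(
        any(p.chrom == s.chrom and s.start <= p.pos < s.end for p in pts)
        for s in segments
    )


def brute_force_points_in_segments(segments, points):
    pts = list(points)
    return sum(
        sum(1 for p in pts if p.chrom == s.chrom and s.start <= p.pos < s.end)
        for s in segments
    )


@pytest.fixture(scope="session")
def planted_sim():
    """A synthetic regulome with one strong planted block (5 TFs x 4 diseases)."""
    cfg = SynthConfig(
        seed=42, planted_blocks=[PlantedBlock((0, 1, 2, 3, 4), (0, 1, 2, 3), 5.0)]
    )
    return simulate_regulome_inputs(cfg)


def regulome_from_sim(sim, null="hypergeometric", upstream_bp=150):
    ext = r.extend_segments(sim.gene_table, upstream_bp, 0)
    disease_tracks = r.TrackSet(
        "diseases",
        [r.genes_to_regions(sim.catalog.lists[t], ext) for t in sorted(sim.catalog.terms)],
    )
    counts = r.build_count_matrix(sim.tf_tracks, disease_tracks)
    if null == "hypergeometric":
        return r.hypergeometric_null(counts)
    return r.binomial_null(counts)
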