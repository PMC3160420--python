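"""Synthetic regulome inputs with known planted structure.

Generates everything the pipeline consumes — a genome, a gene coordinate
table, per-TF point tracks (one point at the TSS of each target gene),
disease gene lists with shared genes across diseases, and co-citation count
tables — together with the ground truth (which TF/disease blocks carry
planted enrichment, which co-citation pairs are planted associations).

Defaults emulate a down-scaled study: 4 chromosomes of 10 Mb holding 1000
non-overlapping 2 kb genes; 20 TFs each targeting genes independently with
probability 0.2 (~200 targets per TF, the same order as a top-1000 target
list against a ~20k-gene genome, scaled to the 1000-gene universe); 15
diseases drawing 50-100 genes each, sampled with replacement *across*
diseases so lists share genes, which is what makes the differential null
meaningful.  Within a planted block, a block TF's probability of targeting
a gene belonging to any of the block's diseases is multiplied by the
enrichment factor (clipped below 1).

Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genelists import CoCitationTable, DiseaseCatalog, GeneList, write_cocitation_table
from .tracks import (
    GenomeSpec,
    GenomicPoint,
    GenomicSegment,
    PointTrack,
    SegmentTrack,
    TrackSet,
)

__all__ = [
    "PlantedBlock",
    "SynthConfig",
    "SynthTruth",
    "SimulatedRegulome",
    "simulate_regulome_inputs",
    "simulate_cocitation",
]


@dataclass(frozen=True)
class PlantedBlock:
    """A (TF subset x disease subset) block with multiplied target probability."""

    tf_indices: tuple[int, ...]
    disease_indices: tuple[int, ...]
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("enrichment multiplier must be >= 1")


@dataclass
class SynthConfig:
    n_chroms: int = 4
    chrom_length_bp: int = 10_000_000
    n_genes: int = 1000
    gene_length_bp: int = 2000
    n_tfs: int = 20
    n_diseases: int = 15
    genes_per_disease: tuple[int, int] = (50, 100)
    background_hit_prob: float = 0.2
    targets_per_tf: int | None = None  # overrides background_hit_prob when set
    planted_blocks: Sequence[PlantedBlock] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length_bp", "n_genes", "gene_length_bp",
                     "n_tfs", "n_diseases"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.genes_per_disease
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError("genes_per_disease range invalid")
        if not 0 <= self.background_hit_prob <= 1:
            raise ValueError("background_hit_prob must be in [0, 1]")
        for blk in self.planted_blocks:
            if max(blk.tf_indices, default=-1) >= self.n_tfs:
                raise ValueError("planted block references TF index out of range")
            if max(blk.disease_indices, default=-1) >= self.n_diseases:
                raise ValueError("planted block references disease index out of range")


@dataclass
class SynthTruth:
    """Ground truth emitted alongside the synthetic inputs."""

    block_tf_labels: dict[str, int]  # TF name -> block id (0 = background)
    block_disease_labels: dict[str, int]
    pair_multiplier: dict[str, float]  # "tf|disease" -> applied multiplier
    planted_gene_flags: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


@dataclass
class SimulatedRegulome:
    genome: GenomeSpec
    gene_table: SegmentTrack
    tf_tracks: TrackSet
    catalog: DiseaseCatalog
    truth: SynthTruth
    config: SynthConfig

    def write_files(self, out_dir: str | Path) -> None:
        """Emit the exact file dialects the I/O layer consumes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "genome.chrom.sizes").write_text(
            "".join(f"{c}\t{l}\n" for c, l in self.genome.chrom_lengths.items())
        )
        rows = ["gene\tchrom\tstart\tend\tstrand"]
        for s in self.gene_table:
            rows.append(f"{s.label}\t{s.chrom}\t{s.start}\t{s.end}\t{s.strand}")
        (out / "genes.tsv").write_text("\n".join(rows) + "\n")
        tf_dir = out / "tf_tracks"
        tf_dir.mkdir(exist_ok=True)
        for tf in self.tf_tracks:
            lines = [f"{p.chrom}\t{p.pos}\t{p.pos + 1}" for p in tf]
            (tf_dir / f"{tf.name}.bed").write_text(
                "\n".join(lines) + ("\n" if lines else "")
            )
        lists = [
            f"{term}\t{gene}"
            for term in self.catalog.terms
            for gene in sorted(self.catalog.lists[term].genes)
        ]
        (out / "disease_lists.tsv").write_text("\n".join(lists) + "\n")
        self.truth.to_json(out / "truth.json")


def _place_genes(cfg: SynthConfig, rng: np.random.Generator) -> list[GenomicSegment]:
    """Place n_genes non-overlapping genes round-robin across chromosomes."""
    slot = cfg.gene_length_bp * 2  # gene plus an equally sized gap
    per_chrom = cfg.chrom_length_bp // slot
    if per_chrom * cfg.n_chroms < cfg.n_genes:
        raise ValueError(
            f"cannot pack {cfg.n_genes} genes of {cfg.gene_length_bp} bp into "
            f"{cfg.n_chroms} x {cfg.chrom_length_bp} bp"
        )
    width = len(str(cfg.n_genes - 1))
    segs = []
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    for i in range(cfg.n_genes):
        chrom = f"chr{i % cfg.n_chroms + 1}"
        slot_i = i // cfg.n_chroms
        jitter = int(rng.integers(0, cfg.gene_length_bp // 2))
        start = slot_i * slot + jitter
        segs.append(
            GenomicSegment(
                chrom, start, start + cfg.gene_length_bp, str(strands[i]),
                f"gene{i:0{width}d}",
            )
        )
    return segs


def simulate_regulome_inputs(cfg: SynthConfig) -> SimulatedRegulome:
    """Generate a full synthetic study with planted enrichment blocks."""
    rng = np.random.default_rng(cfg.seed)
    chroms = {f"chr{i + 1}": cfg.chrom_length_bp for i in range(cfg.n_chroms)}
    genome = GenomeSpec(chroms)
    genes = _place_genes(cfg, rng)
    gene_table = SegmentTrack("genes", genes, genome)
    gene_names = [s.label for s in genes]

    # Disease gene lists: sampled without replacement within a disease,
    # independently (so with sharing) across diseases.
    lo, hi = cfg.genes_per_disease
    d_width = len(str(cfg.n_diseases - 1))
    disease_names = [f"disease{d:0{d_width}d}" for d in range(cfg.n_diseases)]
    disease_genes: dict[str, frozenset[str]] = {}
    for d in disease_names:
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(cfg.n_genes, size=size, replace=False)
        disease_genes[d] = frozenset(gene_names[i] for i in chosen)
    catalog = DiseaseCatalog(
        {d: GeneList(d, gs, "curated") for d, gs in disease_genes.items()}
    )

    # Per-TF target probabilities, with planted multipliers on block genes.
    t_width = len(str(cfg.n_tfs - 1))
    tf_names = [f"tf{t:0{t_width}d}" for t in range(cfg.n_tfs)]
    base_p = (
        cfg.targets_per_tf / cfg.n_genes
        if cfg.targets_per_tf is not None
        else cfg.background_hit_prob
    )
    gene_index = {g: i for i, g in enumerate(gene_names)}
    tf_block = {name: 0 for name in tf_names}
    dis_block = {name: 0 for name in disease_names}
    pair_multiplier: dict[str, float] = {}
    planted_gene = np.zeros(cfg.n_genes, dtype=bool)
    prob = np.full((cfg.n_tfs, cfg.n_genes), base_p)
    for bi, blk in enumerate(cfg.planted_blocks, start=1):
        block_genes = set()
        for di in blk.disease_indices:
            dis_block[disease_names[di]] = bi
            block_genes |= disease_genes[disease_names[di]]
        gidx = np.array([gene_index[g] for g in block_genes], dtype=int)
        planted_gene[gidx] = True
        for ti in blk.tf_indices:
            tf_block[tf_names[ti]] = bi
            prob[ti, gidx] = np.minimum(base_p * blk.multiplier, 0.999)
            for di in blk.disease_indices:
                pair_multiplier[f"{tf_names[ti]}|{disease_names[di]}"] = blk.multiplier

    draws = rng.random((cfg.n_tfs, cfg.n_genes)) < prob
    tss = np.array([s.tss for s in genes])
    chrom_of = [s.chrom for s in genes]
    tracks = []
    for ti, name in enumerate(tf_names):
        targets = np.nonzero(draws[ti])[0]
        pts = [GenomicPoint(chrom_of[i], int(tss[i])) for i in targets]
        tracks.append(PointTrack(name, pts, genome))
    tf_tracks = TrackSet("tfs", tracks)

    truth = SynthTruth(
        tf_block,
        dis_block,
        pair_multiplier,
        {g: bool(planted_gene[gene_index[g]]) for g in gene_names},
    )
    return SimulatedRegulome(genome, gene_table, tf_tracks, catalog, truth, cfg)


def simulate_cocitation(
    n_docs: int,
    n_diseases: int,
    n_genes: int,
    planted: Sequence[tuple[int, int, int]] = (),
    seed: int = 0,
    disease_count_range: tuple[int, int] = (500, 5000),
    gene_count_range: tuple[int, int] = (200, 2000),
) -> tuple[CoCitationTable, dict[str, int]]:
    """Synthetic co-citation counts: null joint counts are hypergeometric.

    ``planted`` lists (disease_index, gene_index, excess) triples whose
    joint counts are inflated by ``excess`` extra co-citing documents
    (clipped at min(m, n)).  Returns the table and a truth map
    "disease|gene" -> excess for the planted pairs.
    """
    rng = np.random.default_rng(seed)
    d_width, g_width = len(str(max(n_diseases - 1, 1))), len(str(max(n_genes - 1, 1)))
    diseases = [f"disease{d:0{d_width}d}" for d in range(n_diseases)]
    genes = [f"gene{g:0{g_width}d}" for g in range(n_genes)]
    m = rng.integers(*disease_count_range, size=n_diseases, endpoint=True)
    n = rng.integers(*gene_count_range, size=n_genes, endpoint=True)
    if m.max() > n_docs or n.max() > n_docs:
        raise ValueError("count ranges exceed n_docs")
    joint: dict[tuple[str, str], int] = {}
    for di in range(n_diseases):
        ks = rng.hypergeometric(m[di], n_docs - m[di], n, size=n_genes)
        for gi in range(n_genes):
            if ks[gi] > 0:
                joint[(diseases[di], genes[gi])] = int(ks[gi])
    truth: dict[str, int] = {}
    for di, gi, excess in planted:
        if excess < 0:
            raise ValueError("planted excess must be >= 0")
        key = (diseases[di], genes[gi])
        k = joint.get(key, 0) + excess
        joint[key] = int(min(k, m[di], n[gi]))
        truth[f"{diseases[di]}|{genes[gi]}"] = excess
    table = CoCitationTable(
        int(n_docs),
        dict(zip(diseases, (int(v) for v in m))),
        dict(zip(genes, (int(v) for v in n))),
        joint,
    )
    return table, truth
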