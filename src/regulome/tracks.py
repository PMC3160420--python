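"""Genomic track data model and intersection statistics.

Tracks come in two geometries: *point tracks* (single genomic positions,
e.g. the TSSs of a transcription factor's predicted target genes, or
nucleosome centres) and *segment tracks* (half-open intervals, e.g. the
gene regions associated with one disease).  All coordinates are 0-based
half-open, following the BED convention.

The two statistics at the heart of the method are

* :func:`count_segments_hit` — the number of segments containing at least
  one point (the "genes with at least one binding location" statistic), and
* :func:`count_points_in_segments` — the total number of point-in-segment
  containments (used for histone-mark style point tracks around TSSs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np

Strand = Literal["+", "-", "."]

__all__ = [
    "GenomeSpec",
    "GenomicPoint",
    "GenomicSegment",
    "PointTrack",
    "SegmentTrack",
    "TrackSet",
    "read_genome_spec",
    "read_bed_points",
    "read_gene_table",
    "extend_segments",
    "tss_window",
    "count_segments_hit",
    "count_points_in_segments",
    "universe_positions",
]


class TrackError(ValueError):
    """Raised for malformed or inconsistent track data."""


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths; the coordinate frame for all tracks.

    Needed to validate coordinates and to clamp region extensions at
    chromosome boundaries.
    """

    chrom_lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise TrackError("genome must have at least one chromosome")
        for chrom, length in self.chrom_lengths.items():
            if int(length) <= 0:
                raise TrackError(f"chromosome {chrom!r} has non-positive length {length}")
        object.__setattr__(self, "chrom_lengths", dict(self.chrom_lengths))

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise TrackError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


@dataclass(frozen=True, order=True)
class GenomicPoint:
    chrom: str
    pos: int


@dataclass(frozen=True)
class GenomicSegment:
    chrom: str
    start: int
    end: int
    strand: Strand = "."
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise TrackError(
                f"invalid segment [{self.start}, {self.end}) on {self.chrom!r}"
            )
        if self.strand not in ("+", "-", "."):
            raise TrackError(f"invalid strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: start on '+', end-1 on '-'."""
        if self.strand == "+":
            return self.start
        if self.strand == "-":
            return self.end - 1
        raise TrackError(f"TSS undefined for unknown strand ({self.chrom}:{self.start})")


class PointTrack:
    """A named set of genomic positions bound to a genome.

    Duplicate positions are collapsed: a position either carries a binding
    location or it does not, matching the placement null in which binding
    locations are positions drawn from a universe of positions.
    """

    def __init__(self, name: str, points: Iterable[GenomicPoint], genome: GenomeSpec):
        self.name = name
        self.genome = genome
        by_chrom: dict[str, set[int]] = {}
        for p in points:
            length = genome.length_of(p.chrom)
            if not 0 <= p.pos < length:
                raise TrackError(
                    f"point {p.chrom}:{p.pos} outside chromosome of length {length}"
                )
            by_chrom.setdefault(p.chrom, set()).add(p.pos)
        self._by_chrom: dict[str, np.ndarray] = {
            chrom: np.fromiter(sorted(ps), dtype=np.int64, count=len(ps))
            for chrom, ps in sorted(by_chrom.items())
        }

    @property
    def n_points(self) -> int:
        return sum(a.size for a in self._by_chrom.values())

    def __len__(self) -> int:
        return self.n_points

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted unique positions on *chrom* (empty array if none)."""
        return self._by_chrom.get(chrom, np.empty(0, dtype=np.int64))

    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def __iter__(self) -> Iterator[GenomicPoint]:
        for chrom, arr in self._by_chrom.items():
            for pos in arr:
                yield GenomicPoint(chrom, int(pos))

    def as_set(self) -> frozenset[tuple[str, int]]:
        return frozenset((c, int(p)) for c, a in self._by_chrom.items() for p in a)

    def __repr__(self) -> str:
        return f"PointTrack({self.name!r}, n={self.n_points})"


class SegmentTrack:
    """A named list of genomic segments (e.g. one disease's gene regions).

    Overlapping segments are kept distinct: the segments-hit statistic counts
    gene regions, and each gene is an independent unit of association.
    """

    def __init__(self, name: str, segments: Iterable[GenomicSegment], genome: GenomeSpec):
        self.name = name
        self.genome = genome
        self.segments: list[GenomicSegment] = list(segments)
        labels = [s.label for s in self.segments if s.label is not None]
        if len(labels) != len(set(labels)):
            raise TrackError(f"duplicate segment labels in track {name!r}")
        for s in self.segments:
            if s.end > genome.length_of(s.chrom):
                raise TrackError(
                    f"segment {s.chrom}:{s.start}-{s.end} exceeds chromosome length"
                )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[GenomicSegment]:
        return iter(self.segments)

    @property
    def labels(self) -> list[str | None]:
        return [s.label for s in self.segments]

    def by_label(self) -> dict[str, GenomicSegment]:
        return {s.label: s for s in self.segments if s.label is not None}

    def __repr__(self) -> str:
        return f"SegmentTrack({self.name!r}, n={len(self.segments)})"


@dataclass
class TrackSet:
    """An ordered, named collection of tracks of homogeneous geometry."""

    label: str
    tracks: Sequence[PointTrack] | Sequence[SegmentTrack]

    def __post_init__(self) -> None:
        if not self.tracks:
            raise TrackError(f"track set {self.label!r} is empty")
        kinds = {type(t) for t in self.tracks}
        if len(kinds) > 1:
            raise TrackError("track set mixes point and segment geometry")
        names = [t.name for t in self.tracks]
        if len(names) != len(set(names)):
            raise TrackError(f"duplicate track names in set {self.label!r}")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.tracks]

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def __getitem__(self, name: str):
        for t in self.tracks:
            if t.name == name:
                return t
        raise KeyError(name)


# ---------------------------------------------------------------------------
# I/O


def read_genome_spec(path: str | Path) -> GenomeSpec:
    """Read a two-column chrom.sizes-style TSV (chrom, length)."""
    lengths: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise TrackError(f"{path}:{lineno}: expected two tab-separated columns")
        chrom, length = parts[0], parts[1]
        if chrom in lengths:
            raise TrackError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
        lengths[chrom] = int(length)
    return GenomeSpec(lengths)


_TRACK_NAME_RE = re.compile(r'\bname=(?:"([^"]*)"|(\S+))')


def read_bed_points(
    path: str | Path,
    genome: GenomeSpec,
    point_rule: Literal["strict", "midpoint"] = "midpoint",
    name: str | None = None,
) -> PointTrack:
    """Read a BED3+ file as a point track.

    Width-1 records map directly to points.  Wider records are an error
    under ``point_rule="strict"``; under ``"midpoint"`` (default) each
    interval is reduced to floor((start+end)/2), the convention used for
    nucleosome segments treated as points.  The track name is taken from a
    ``track name=...`` header line if present, else the file stem.
    """
    path = Path(path)
    track_name = name or path.stem
    points: list[GenomicPoint] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "browser")):
            continue
        if line.startswith("track"):
            m = _TRACK_NAME_RE.search(line)
            if m and name is None:
                track_name = m.group(1) or m.group(2)
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise TrackError(f"{path}:{lineno}: expected at least 3 BED columns")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise TrackError(f"{path}:{lineno}: non-integer coordinates") from None
        if chrom not in genome:
            raise TrackError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if start < 0 or end <= start:
            raise TrackError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        if end - start == 1:
            pos = start
        elif point_rule == "midpoint":
            pos = (start + end) // 2
        else:
            raise TrackError(
                f"{path}:{lineno}: interval wider than 1 bp with strict point rule"
            )
        if pos >= genome.length_of(chrom):
            raise TrackError(f"{path}:{lineno}: position {pos} out of bounds")
        points.append(GenomicPoint(chrom, pos))
    return PointTrack(track_name, points, genome)


def read_gene_table(
    path: str | Path, genome: GenomeSpec, name: str | None = None
) -> SegmentTrack:
    """Read a gene coordinate TSV with header ``gene chrom start end strand``."""
    path = Path(path)
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise TrackError(f"{path}: empty gene table")
    header = lines[0].rstrip("\n").split("\t")
    required = ["gene", "chrom", "start", "end", "strand"]
    try:
        idx = {col: header.index(col) for col in required}
    except ValueError:
        raise TrackError(f"{path}: header must contain columns {required}") from None
    segments: list[GenomicSegment] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        gene = parts[idx["gene"]]
        if gene in seen:
            raise TrackError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        chrom = parts[idx["chrom"]]
        start, end = int(parts[idx["start"]]), int(parts[idx["end"]])
        strand = parts[idx["strand"]]
        if chrom not in genome:
            raise TrackError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if start >= end:
            raise TrackError(f"{path}:{lineno}: start must be < end for gene {gene!r}")
        segments.append(GenomicSegment(chrom, start, end, strand, gene))  # type: ignore[arg-type]
    return SegmentTrack(name or path.stem, segments, genome)


# ---------------------------------------------------------------------------
# Region transforms


def extend_segments(
    track: SegmentTrack,
    upstream_bp: int,
    downstream_bp: int,
    genome: GenomeSpec | None = None,
    strand_aware: bool = True,
) -> SegmentTrack:
    """Grow each segment by flanks, clamped to chromosome bounds.

    With ``strand_aware``, ``upstream_bp`` grows the 5' side and
    ``downstream_bp`` the 3' side (so on the '-' strand upstream means the
    end coordinate).  Segments of unknown strand tolerate only symmetric
    flanks; asymmetric flanks without a strand are an error rather than a
    guess.  Typical uses: 150 bp upstream to absorb TSS-annotation
    inconsistencies between gene builds, or 5 kb symmetric flanks to catch
    nearby binding sites.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise TrackError("flanks must be non-negative")
    genome = genome or track.genome
    out: list[GenomicSegment] = []
    for s in track.segments:
        if strand_aware and s.strand == "+":
            left, right = upstream_bp, downstream_bp
        elif strand_aware and s.strand == "-":
            left, right = downstream_bp, upstream_bp
        else:
            if upstream_bp != downstream_bp:
                raise TrackError(
                    f"asymmetric flanks need a known strand (segment {s.label or s.chrom})"
                    if strand_aware
                    else "asymmetric flanks require strand_aware=True"
                )
            left = right = upstream_bp
        length = genome.length_of(s.chrom)
        out.append(
            replace(s, start=max(0, s.start - left), end=min(length, s.end + right))
        )
    return SegmentTrack(track.name, out, genome)


def tss_window(
    track: SegmentTrack, flank_bp: int, genome: GenomeSpec | None = None
) -> SegmentTrack:
    """Replace each gene by the window [TSS - flank, TSS + flank), clamped.

    Used for counting point-like chromatin features (e.g. nucleosome centres
    carrying a histone modification) around transcription start sites.
    Strands must be known for every gene.
    """
    if flank_bp <= 0:
        raise TrackError("flank_bp must be positive")
    genome = genome or track.genome
    out = []
    for s in track.segments:
        tss = s.tss  # raises for unknown strand
        length = genome.length_of(s.chrom)
        out.append(
            replace(s, start=max(0, tss - flank_bp), end=min(length, tss + flank_bp))
        )
    return SegmentTrack(track.name, out, genome)


# ---------------------------------------------------------------------------
# Intersection statistics


def count_segments_hit(segments: SegmentTrack, points: PointTrack) -> int:
    """Number of segments containing at least one point (half-open).

    This is the per-cell statistic of the main scheme: the number of a
    disease's gene regions holding at least one binding location of a TF.
    Overlapping segments each count once.
    """
    hit = 0
    for s in segments:
        arr = points.positions(s.chrom)
        lo = np.searchsorted(arr, s.start, side="left")
        hi = np.searchsorted(arr, s.end, side="left")
        if hi > lo:
            hit += 1
    return hit


def count_points_in_segments(segments: SegmentTrack, points: PointTrack) -> int:
    """Total number of (point, segment) containments.

    A point inside two overlapping segments contributes twice; used for the
    points-in-TSS-window counting mode.
    """
    total = 0
    for s in segments:
        arr = points.positions(s.chrom)
        lo = np.searchsorted(arr, s.start, side="left")
        hi = np.searchsorted(arr, s.end, side="left")
        total += int(hi - lo)
    return total


def universe_positions(tf_tracks: TrackSet) -> PointTrack:
    """Deduplicated union of positions across all point tracks in a set.

    This union is the sample space of both null models: under the null a
    TF's binding locations are positions drawn from the set of positions
    carrying a binding location for *any* TF.
    """
    first = tf_tracks.tracks[0]
    if not isinstance(first, PointTrack):
        raise TrackError("universe_positions requires a set of point tracks")
    genome = first.genome
    union: dict[str, set[int]] = {}
    for t in tf_tracks:
        if not isinstance(t, PointTrack):
            raise TrackError("universe_positions requires a set of point tracks")
        for chrom in t.chroms():
            union.setdefault(chrom, set()).update(int(p) for p in t.positions(chrom))
    pts = [GenomicPoint(c, p) for c, ps in union.items() for p in ps]
    return PointTrack("universe", pts, genome)
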