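"""Gene-level drill-down of a selected (TF, disease) cluster.

Given a rectangular cluster selection of TF rows and disease columns, a
gene's *hit count* is the number of selected pairs (t, d) for which the
gene belongs to disease d's list AND carries at least one binding location
of TF t in its (extended) region; the *hit rate* divides by the number of
selected pairs.  The top genes by hit rate (tie-inclusive at the cut) are
the cluster's contributing genes, and overlaps of such lists across several
clusters are summarised as an exact membership-pattern (Venn) partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import RegulomeMatrix
from .genelists import DiseaseCatalog
from .tracks import PointTrack, SegmentTrack, TrackSet

__all__ = [
    "ClusterSelection",
    "HitRateTable",
    "OverlapPartition",
    "derive_tf_gene_hits",
    "gene_hit_rates",
    "top_genes",
    "overlap_partition",
    "rank_diseases_by_effect",
    "combined_hit_rate",
]


@dataclass(frozen=True)
class ClusterSelection:
    tf_rows: frozenset[str]
    disease_cols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tf_rows or not self.disease_cols:
            raise ValueError("selection must include at least one TF and one disease")

    @property
    def n_pairs(self) -> int:
        return len(self.tf_rows) * len(self.disease_cols)


@dataclass
class HitRateTable:
    """Per-gene hit counts/rates for one cluster selection."""

    table: pd.DataFrame  # index gene; columns hit_count, hit_rate
    n_pairs: int

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def total_hits(self) -> int:
        return int(self.table["hit_count"].sum())

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["hit_rate"] = (out["hit_rate"] * 100).map(lambda v: f"{v:.1f}%")
        out.to_csv(path, sep="\t", index_label="gene")


@dataclass
class OverlapPartition:
    """Exact Venn partition of k gene sets by membership pattern.

    Patterns are bit-strings over ``set_labels`` ("110" = in the first two
    sets only); region sizes are disjoint and sum to the union size.
    """

    set_labels: list[str]
    memberships: dict[str, str]  # gene -> pattern
    region_sizes: dict[str, int]

    @property
    def union_size(self) -> int:
        return len(self.memberships)

    @property
    def in_all(self) -> int:
        return self.region_sizes.get("1" * len(self.set_labels), 0)

    @property
    def in_more_than_one_not_all(self) -> int:
        k = len(self.set_labels)
        return sum(
            size
            for pat, size in self.region_sizes.items()
            if 1 < pat.count("1") < k
        )


def derive_tf_gene_hits(
    tf_tracks: TrackSet, gene_regions: SegmentTrack
) -> dict[str, frozenset[str]]:
    """TF -> set of genes whose (extended) region holds >= 1 binding location.

    ``gene_regions`` must be labeled with gene identifiers and should carry
    the same extensions used when building the regulome, so hit rates agree
    with the count matrix.
    """
    hits: dict[str, frozenset[str]] = {}
    for tf in tf_tracks:
        assert isinstance(tf, PointTrack)
        genes = set()
        for s in gene_regions:
            if s.label is None:
                continue
            arr = tf.positions(s.chrom)
            lo = np.searchsorted(arr, s.start, side="left")
            hi = np.searchsorted(arr, s.end, side="left")
            if hi > lo:
                genes.add(s.label)
        hits[tf.name] = frozenset(genes)
    return hits


def _normalise_hits(
    tf_target_hits: Mapping,
) -> dict[str, frozenset[str]]:
    """Accept TF -> gene-set or (TF, gene) -> bool mappings."""
    sample = next(iter(tf_target_hits), None)
    if isinstance(sample, tuple):
        out: dict[str, set[str]] = {}
        for (tf, gene), hit in tf_target_hits.items():
            if hit:
                out.setdefault(tf, set()).add(gene)
        return {tf: frozenset(g) for tf, g in out.items()}
    return {tf: frozenset(genes) for tf, genes in tf_target_hits.items()}


def gene_hit_rates(
    sel: ClusterSelection,
    catalog: DiseaseCatalog,
    tf_target_hits: Mapping,
) -> HitRateTable:
    """Hit count and rate for every gene in the selected diseases' lists.

    hit_count(g) = |{(t, d) in sel : g in genelist(d) and t hits g}|;
    hit_rate = hit_count / (|tf_rows| * |disease_cols|).  Genes in none of
    the selected lists do not appear.
    """
    missing = [d for d in sel.disease_cols if d not in catalog.lists]
    if missing:
        raise KeyError(f"selection references unknown diseases: {sorted(missing)}")
    hits = _normalise_hits(tf_target_hits)
    missing_tf = [t for t in sel.tf_rows if t not in hits]
    if missing_tf:
        raise KeyError(f"selection references unknown TFs: {sorted(missing_tf)}")
    counts: dict[str, int] = {}
    for d in sel.disease_cols:
        genes_d = catalog.lists[d].genes
        for t in sel.tf_rows:
            hit_genes = hits[t]
            for g in genes_d:
                counts.setdefault(g, 0)
                if g in hit_genes:
                    counts[g] += 1
    n_pairs = sel.n_pairs
    df = pd.DataFrame({"hit_count": pd.Series(counts, dtype=int)})
    df.index.name = "gene"
    df["hit_rate"] = df["hit_count"] / n_pairs
    # deterministic: rate descending, then gene label ascending
    df = df.reset_index().sort_values(
        ["hit_count", "gene"], ascending=[False, True], kind="stable"
    ).set_index("gene")
    return HitRateTable(df, n_pairs)


def top_genes(table: HitRateTable, k: int = 100) -> list[str]:
    """Top k genes by hit rate, extended to include all ties with the k-th.

    Within equal rates the order is alphabetical, but the tie rule is
    applied to the rate only: every gene sharing the k-th gene's rate is
    included, so the returned list may exceed k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = table.table
    if len(df) <= k:
        return list(df.index)
    cutoff = df["hit_rate"].iloc[k - 1]
    return list(df.index[df["hit_rate"] >= cutoff])


def overlap_partition(
    gene_sets: Sequence[tuple[str, AbstractSet[str]]]
) -> OverlapPartition:
    """Exact membership-pattern partition of 2-6 labelled gene sets."""
    if not 2 <= len(gene_sets) <= 6:
        raise ValueError("overlap_partition takes between 2 and 6 sets")
    labels = [lab for lab, _ in gene_sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate set labels")
    union: set[str] = set()
    for _, genes in gene_sets:
        union |= set(genes)
    memberships: dict[str, str] = {}
    region_sizes: dict[str, int] = {}
    for g in sorted(union):
        pat = "".join("1" if g in genes else "0" for _, genes in gene_sets)
        memberships[g] = pat
        region_sizes[pat] = region_sizes.get(pat, 0) + 1
    return OverlapPartition(labels, memberships, region_sizes)


def rank_diseases_by_effect(
    sel: ClusterSelection,
    matrix: RegulomeMatrix,
    key: str = "effect",
) -> list[str]:
    """Diseases ranked by effect size over the selected TFs, descending.

    Effect size is the mean of (observed - expected) across the selected
    TFs — the over-/under-representation relative to the expected value for
    that disease.  ``key="z"`` ranks by mean z instead (NaN treated as 0).
    Ties break alphabetically.
    """
    rows = [matrix.row_names.index(t) for t in sorted(sel.tf_rows)]
    unknown = sel.disease_cols - set(matrix.col_names)
    if unknown:
        raise KeyError(f"unknown diseases: {sorted(unknown)}")
    scores = {}
    for d in sel.disease_cols:
        ci = matrix.col_names.index(d)
        if key == "effect":
            vals = matrix.counts.observed[rows, ci] - matrix.expected[rows, ci]
        elif key == "z":
            vals = np.nan_to_num(matrix.z[rows, ci], nan=0.0)
        else:
            raise ValueError(f"unknown ranking key {key!r}")
        scores[d] = float(vals.mean())
    return sorted(scores, key=lambda d: (-scores[d], d))


def combined_hit_rate(table: HitRateTable, genes: AbstractSet[str]) -> float:
    """Share of the table's total hit mass carried by a gene subset.

    Used to check whether a cluster's signal is concentrated in a few genes
    or scattered over many (a robustness diagnostic).
    """
    if table.table.empty:
        raise ValueError("empty hit-rate table")
    extra = set(genes) - set(table.table.index)
    if extra:
        raise KeyError(f"genes not in table: {sorted(extra)[:5]}")
    total = table.total_hits()
    if total == 0:
        return 0.0
    subset = int(table.table.loc[sorted(genes), "hit_count"].sum()) if genes else 0
    return subset / total
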