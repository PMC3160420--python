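"""Disease gene lists: curated input and literature co-citation construction.

A disease's gene list can either be curated (a plain term→gene table) or
derived from literature co-citation counts.  In the co-citation model, with
N documents in total, m mentioning disease term d and n mentioning gene g,
the number of documents mentioning both follows a hypergeometric
distribution under the null of no association.  Genes whose
Bonferroni-corrected upper-tail p-value falls below a threshold (default
0.02) form the disease's list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .tracks import SegmentTrack

logger = logging.getLogger(__name__)

__all__ = [
    "CoCitationTable",
    "GeneList",
    "DiseaseCatalog",
    "cocitation_pvalue",
    "build_gene_list",
    "filter_catalog",
    "genes_to_regions",
    "read_cocitation_table",
    "read_curated_lists",
]


@dataclass
class CoCitationTable:
    """Document counts for the co-citation association model.

    N: total documents; disease_counts[d] = m; gene_counts[g] = n;
    joint_counts[(d, g)] = k.  Pairs absent from joint_counts have k = 0.
    """

    N: int
    disease_counts: Mapping[str, int]
    gene_counts: Mapping[str, int]
    joint_counts: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("total document count N must be positive")
        for d, m in self.disease_counts.items():
            if not 0 <= m <= self.N:
                raise ValueError(f"disease count for {d!r} out of range: {m}")
        for g, n in self.gene_counts.items():
            if not 0 <= n <= self.N:
                raise ValueError(f"gene count for {g!r} out of range: {n}")
        for (d, g), k in self.joint_counts.items():
            m = self.disease_counts.get(d)
            n = self.gene_counts.get(g)
            if m is None or n is None:
                raise ValueError(f"joint count for unknown pair ({d!r}, {g!r})")
            if not 0 <= k <= min(m, n):
                raise ValueError(f"joint count {k} for ({d!r}, {g!r}) exceeds min(m, n)")

    @property
    def genes(self) -> list[str]:
        return list(self.gene_counts)

    @property
    def diseases(self) -> list[str]:
        return list(self.disease_counts)


@dataclass
class GeneList:
    term: str
    genes: frozenset[str]
    source: Literal["curated", "cocitation"]
    audit: pd.DataFrame | None = None  # gene, k, raw_p, corrected_p for cocitation lists

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class DiseaseCatalog:
    """All disease gene lists plus optional per-term literature citation counts."""

    lists: dict[str, GeneList]
    citation_counts: dict[str, int] | None = None

    @property
    def terms(self) -> list[str]:
        return list(self.lists)

    def __getitem__(self, term: str) -> GeneList:
        return self.lists[term]

    def __len__(self) -> int:
        return len(self.lists)


def cocitation_pvalue(N: int, m: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, m, n).

    X is the number of documents mentioning both the disease (m documents)
    and the gene (n documents) out of N in total, under independence.
    """
    if m > N or n > N:
        raise ValueError("m and n must not exceed N")
    if k < 0 or k > min(m, n):
        raise ValueError(f"k={k} outside [0, min(m, n)={min(m, n)}]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def build_gene_list(
    table: CoCitationTable,
    term: str,
    alpha: float = 0.02,
    universe_size: int | None = None,
) -> GeneList:
    """Genes significantly co-cited with *term* at Bonferroni-corrected p < alpha.

    The Bonferroni family defaults to the number of genes tested for this
    term (all genes in the count table); pass ``universe_size`` to use a
    different family, e.g. #genes x #diseases for a global correction.
    Strict inequality at the threshold.  The returned list carries an audit
    table with raw and corrected p per co-cited gene.
    """
    if term not in table.disease_counts:
        raise KeyError(f"unknown disease term {term!r}")
    m = table.disease_counts[term]
    tested = list(table.gene_counts)
    n_tests = universe_size if universe_size is not None else len(tested)
    if n_tests <= 0:
        raise ValueError("universe_size must be positive")
    rows = []
    selected = []
    for g in tested:
        k = table.joint_counts.get((term, g), 0)
        if k == 0:
            continue  # p = 1, never selected; keep the audit table small
        raw = cocitation_pvalue(table.N, m, table.gene_counts[g], k)
        corrected = min(1.0, raw * n_tests)
        rows.append((g, k, raw, corrected))
        if raw * n_tests < alpha:
            selected.append(g)
    audit = pd.DataFrame(rows, columns=["gene", "k", "raw_p", "corrected_p"])
    return GeneList(term, frozenset(selected), "cocitation", audit)


def filter_catalog(
    catalog: DiseaseCatalog, min_genes: int, min_citations: int | None = None
) -> DiseaseCatalog:
    """Keep terms with at least ``min_genes`` genes and, when citation counts
    are available, strictly more than ``min_citations`` literature citations.
    """
    kept: dict[str, GeneList] = {}
    for term, gl in catalog.lists.items():
        if len(gl.genes) < min_genes:
            continue
        if min_citations is not None and catalog.citation_counts is not None:
            if catalog.citation_counts.get(term, 0) <= min_citations:
                continue
        kept[term] = gl
    citations = (
        {t: c for t, c in catalog.citation_counts.items() if t in kept}
        if catalog.citation_counts is not None
        else None
    )
    return DiseaseCatalog(kept, citations)


def genes_to_regions(gene_list: GeneList, gene_table: SegmentTrack) -> SegmentTrack:
    """Map a gene list to a segment track of the genes' regions.

    Genes missing from the coordinate table are logged and dropped, so a
    list built from one annotation source degrades gracefully against a
    gene build that lacks some symbols.
    """
    lookup = gene_table.by_label()
    found = []
    missing = 0
    for g in sorted(gene_list.genes):
        seg = lookup.get(g)
        if seg is None:
            missing += 1
        else:
            found.append(seg)
    if missing:
        logger.warning(
            "%d/%d genes of %r not in gene table; dropped",
            missing,
            len(gene_list.genes),
            gene_list.term,
        )
    return SegmentTrack(gene_list.term, found, gene_table.genome)


# ---------------------------------------------------------------------------
# I/O

_SECTION_HEADERS = {"#diseases", "#genes", "#joint"}


def read_cocitation_table(path: str | Path) -> CoCitationTable:
    """Read the co-citation TSV dialect.

    First line ``#N=<int>``; then three sections introduced by ``#diseases``
    (term, m), ``#genes`` (gene, n) and ``#joint`` (term, gene, k).
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#N="):
        raise ValueError(f"{path}: first line must be '#N=<int>'")
    N = int(lines[0][3:])
    section = None
    disease_counts: dict[str, int] = {}
    gene_counts: dict[str, int] = {}
    joint: dict[tuple[str, str], int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line in _SECTION_HEADERS:
            section = line
            continue
        parts = line.split("\t")
        if section == "#diseases":
            disease_counts[parts[0]] = int(parts[1])
        elif section == "#genes":
            gene_counts[parts[0]] = int(parts[1])
        elif section == "#joint":
            joint[(parts[0], parts[1])] = int(parts[2])
        else:
            raise ValueError(f"{path}:{lineno}: data before a section header")
    return CoCitationTable(N, disease_counts, gene_counts, joint)


def write_cocitation_table(table: CoCitationTable, path: str | Path) -> None:
    out = [f"#N={table.N}", "#diseases"]
    out += [f"{d}\t{m}" for d, m in table.disease_counts.items()]
    out.append("#genes")
    out += [f"{g}\t{n}" for g, n in table.gene_counts.items()]
    out.append("#joint")
    out += [f"{d}\t{g}\t{k}" for (d, g), k in table.joint_counts.items()]
    Path(path).write_text("\n".join(out) + "\n")


def read_curated_lists(
    path: str | Path, citation_counts: Mapping[str, int] | None = None
) -> DiseaseCatalog:
    """Read a curated two-column TSV (term, gene) into a catalog."""
    by_term: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns (term, gene)")
        by_term.setdefault(parts[0], set()).add(parts[1])
    lists = {
        term: GeneList(term, frozenset(genes), "curated")
        for term, genes in by_term.items()
    }
    return DiseaseCatalog(lists, dict(citation_counts) if citation_counts else None)


def write_gene_lists(catalog: DiseaseCatalog, out_dir: str | Path) -> None:
    """One TSV per term plus a combined audit TSV for co-citation lists."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    audit_frames = []
    for term, gl in catalog.lists.items():
        safe = term.replace("/", "_").replace(" ", "_")
        (out_dir / f"{safe}.tsv").write_text(
            "\n".join(sorted(gl.genes)) + ("\n" if gl.genes else "")
        )
        if gl.audit is not None and not gl.audit.empty:
            frame = gl.audit.copy()
            frame.insert(0, "term", term)
            audit_frames.append(frame)
    if audit_frames:
        pd.concat(audit_frames).to_csv(out_dir / "audit.tsv", sep="\t", index=False)
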