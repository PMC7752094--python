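"""Deficiency-to-gene interval mapping and gene-group enrichment.

Deficiencies (chromosomal deletions) and gene models are both represented as
0-based half-open genomic intervals (the BED convention).  A gene is covered
by a deficiency when their intervals overlap by at least one base on the
same chromosome.  Covered-gene sets are tested against curated gene groups
with a one-sided (enrichment) Fisher exact test — the hypergeometric upper
tail P(X >= k) — and Benjamini–Hochberg FDR correction across the groups
scanned together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MappingError",
    "GenomicInterval",
    "DeficiencyRecord",
    "GeneModel",
    "GeneGroup",
    "EnrichmentResult",
    "map_df_to_genes",
    "known_modifier_coverage",
    "fisher_exact_2x2",
    "bh_adjust",
    "group_enrichment",
]

logger = logging.getLogger(__name__)


class MappingError(ValueError):
    """Invalid intervals, margins or gene sets."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; chromosome names are opaque labels."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise MappingError(f"negative start {self.start}")
        if self.end <= self.start:
            raise MappingError(f"end {self.end} must exceed start {self.start}")

    def overlaps(self, other: "GenomicInterval", min_fraction: float = 0.0) -> bool:
        if self.chrom != other.chrom:
            return False
        ov = min(self.end, other.end) - max(self.start, other.start)
        if ov <= 0:
            return False
        return ov >= min_fraction * (other.end - other.start)


@dataclass(frozen=True)
class DeficiencyRecord:
    df_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class GeneGroup:
    group_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise MappingError(f"group {self.group_id!r} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    group_id: str
    k_overlap: int
    n_query: int
    m_group: int
    N_universe: int
    p_value: float
    p_adjusted: float


# --- overlap mapping --------------------------------------------------------


def map_df_to_genes(
    dfs: list[DeficiencyRecord],
    genes: list[GeneModel],
    min_overlap_fraction: float = 0.0,
) -> dict[str, set[str]]:
    """Genes covered by each deficiency (>= 1 bp overlap by default).

    ``min_overlap_fraction`` optionally requires the overlap to span at
    least that fraction of the gene's length.
    """
    df_ids = [d.df_id for d in dfs]
    if len(set(df_ids)) != len(df_ids):
        raise MappingError("duplicate df_id in deficiency records")
    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise MappingError("duplicate gene_id in gene models")

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g
        )

    df_chroms = {d.interval.chrom for d in dfs}
    orphan = df_chroms - set(trees)
    if orphan:
        logger.warning(
            "deficiency chromosomes with no annotated genes: %s", sorted(orphan)
        )

    mapping: dict[str, set[str]] = {}
    for d in dfs:
        covered: set[str] = set()
        tree = trees.get(d.interval.chrom)
        if tree is not None:
            for hit in tree.overlap(d.interval.start, d.interval.end):
                gene: GeneModel = hit.data
                if gene.interval.overlaps(d.interval) and d.interval.overlaps(
                    gene.interval, min_overlap_fraction
                ):
                    covered.add(gene.gene_id)
        mapping[d.df_id] = covered
    return mapping


def known_modifier_coverage(
    df_genes: dict[str, set[str]], known: set[str]
) -> tuple[float, dict[str, bool]]:
    """Fraction of deficiencies covering at least one known-modifier gene.

    Returns the fraction and the per-Df boolean flags.
    """
    if not df_genes:
        raise MappingError("empty deficiency-to-gene mapping")
    if not known:
        logger.warning("empty known-modifier set; all deficiencies flagged False")
    flags = {df: bool(genes & known) for df, genes in df_genes.items()}
    return sum(flags.values()) / len(flags), flags


# --- enrichment statistics --------------------------------------------------


def fisher_exact_2x2(k: int, n_query: int, m_group: int, N: int) -> float:
    """One-sided (enrichment) Fisher exact p-value: P(X >= k) for
    X ~ Hypergeometric(N, m_group, n_query).

    Computed in log space from the exact hypergeometric distribution; no
    normal approximation.
    """
    if not (0 <= k <= min(n_query, m_group) <= max(n_query, m_group) <= N):
        raise MappingError(
            f"inconsistent margins k={k}, n_query={n_query}, "
            f"m_group={m_group}, N={N}"
        )
    return float(min(1.0, hypergeom.sf(k - 1, N, m_group, n_query)))


def bh_adjust(p: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise MappingError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return [float(q) for q in adjusted]


def group_enrichment(
    query_genes: set[str],
    universe: set[str],
    groups: list[GeneGroup],
) -> list[EnrichmentResult]:
    """Fisher enrichment of each gene group in the query set, BH-corrected
    across all groups in this scan, sorted by adjusted p (ties on group_id).

    Group members are intersected with the universe before testing; the
    query must be a subset of the universe.
    """
    stray = query_genes - universe
    if stray:
        raise MappingError(f"query genes not in universe: {sorted(stray)}")
    group_ids = [g.group_id for g in groups]
    if len(set(group_ids)) != len(group_ids):
        raise MappingError("duplicate group_id")

    N = len(universe)
    n_query = len(query_genes)
    rows: list[tuple[str, int, int, float]] = []
    for g in groups:
        members = g.members & universe
        k = len(query_genes & members)
        m = len(members)
        p = fisher_exact_2x2(k, n_query, m, N) if m else 1.0
        rows.append((g.group_id, k, m, p))

    adjusted = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(gid, k, n_query, m, N, p, q)
        for (gid, k, m, p), q in zip(rows, adjusted)
    ]
    return sorted(results, key=lambda r: (r.p_adjusted, r.p_value, r.group_id))
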