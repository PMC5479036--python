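"""Evaluation of predicted ortholog sets.

Three computations: set identity between two predictions for the same
query (Jaccard, as a percentage, with outgroup genes excluded), the
distribution of predicted orthologs over initial-search e-value ranks
within each genome, and the merging of overlapping per-query groups into
non-overlapping groups with its summary fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .orthology import OrthologSet
from .seqdata import Dataset
from .simsearch import SimilarityHit

__all__ = [
    "ComparisonReport",
    "MergeReport",
    "jaccard_identity",
    "compare_predictions",
    "rank_distribution",
    "merge_groups",
]


@dataclass
class ComparisonReport:
    """Per-query and summary %-identity between two sets of predictions."""

    per_query: dict[str, float | None]
    average_pct_identity: float | None
    pct_queries_identical: float
    pct_queries_ge90: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"query": list(self.per_query), "pct_identity": list(self.per_query.values())}
        )


@dataclass
class MergeReport:
    """Non-overlapping merged groups with the identity/rescue fractions."""

    groups: list[frozenset[str]]
    pct_identical: float
    pct_genes_rescued: float


def jaccard_identity(
    a: Iterable[str],
    b: Iterable[str],
    exclude_species: str | None = None,
    species_of: Callable[[str], str] | None = None,
) -> float | None:
    """Percent identity of two gene sets: ``100 * |a & b| / |a | b|``.

    When `exclude_species` is given (the outgroup-removal rule), members of
    that species are dropped from both sets first; `species_of` resolves a
    gene to its species. Returns None (undefined, reported as missing
    rather than zero) when both sets are empty after exclusion.
    """
    sa, sb = set(a), set(b)
    if exclude_species is not None:
        if species_of is None:
            raise ValueError("exclude_species requires a species_of resolver")
        sa = {g for g in sa if species_of(g) != exclude_species}
        sb = {g for g in sb if species_of(g) != exclude_species}
    union = sa | sb
    if not union:
        return None
    return 100.0 * len(sa & sb) / len(union)


def compare_predictions(
    a: Mapping[str, Iterable[str]],
    b: Mapping[str, Iterable[str]],
    exclude_species: str | None = None,
    species_of: Callable[[str], str] | None = None,
) -> ComparisonReport:
    """Compare two predictions (query -> gene set) over their common queries.

    Queries whose identity is undefined (both sets empty after outgroup
    exclusion) are excluded from the averages.
    """
    per_query: dict[str, float | None] = {}
    for q in sorted(set(a) & set(b)):
        per_query[q] = jaccard_identity(a[q], b[q], exclude_species, species_of)
    defined = [v for v in per_query.values() if v is not None]
    if not defined:
        return ComparisonReport(per_query, None, 0.0, 0.0)
    avg = sum(defined) / len(defined)
    pct100 = 100.0 * sum(v == 100.0 for v in defined) / len(defined)
    pct90 = 100.0 * sum(v >= 90.0 for v in defined) / len(defined)
    return ComparisonReport(per_query, avg, pct100, pct90)


def rank_distribution(
    orthosets: Sequence[OrthologSet],
    initial_hits: Mapping[str, Sequence[SimilarityHit]],
    dataset: Dataset,
    max_rank: int = 10,
) -> pd.DataFrame:
    """Distribution of predicted orthologs over within-genome e-value ranks.

    A predicted ortholog ranks 1 when it has the best initial-search
    e-value among the hits of its species; k other same-species genes with
    strictly better e-values give rank ``k + 1`` (exact ties share the best
    rank). Gene-level e-values are the best over the gene's isoforms.
    Orthologs absent from the query's hit list fall in the ``unranked``
    row. Fractions are percentages over all predicted orthologs; the frame
    also reports the total ortholog count.
    """
    counts: dict[str, int] = {str(r): 0 for r in range(1, max_rank + 1)}
    counts[f"{max_rank + 1}+"] = 0
    counts["unranked"] = 0
    total = 0
    for oset in orthosets:
        hits = initial_hits.get(oset.query_gene, [])
        gene_evalue: dict[str, float] = {}
        for h in hits:
            g = dataset.gene_of(h.subject_id)
            if g not in gene_evalue or h.evalue < gene_evalue[g]:
                gene_evalue[g] = h.evalue
        by_species: dict[str, list[tuple[float, str]]] = {}
        for g, e in gene_evalue.items():
            by_species.setdefault(dataset.species_of_gene(g), []).append((e, g))
        for gene in sorted(oset.orthologs):
            total += 1
            if gene not in gene_evalue:
                counts["unranked"] += 1
                continue
            sp = dataset.species_of_gene(gene)
            better = sum(
                1
                for (e, g) in by_species.get(sp, [])
                if e < gene_evalue[gene]
            )
            rank = 1 + better
            if rank <= max_rank:
                counts[str(rank)] += 1
            else:
                counts[f"{max_rank + 1}+"] += 1
    rows = list(counts)
    frac = [100.0 * counts[r] / total if total else 0.0 for r in rows]
    return pd.DataFrame({"rank": rows, "count": [counts[r] for r in rows], "percent": frac}).assign(
        total_orthologs=total
    )


def merge_groups(orthosets: Sequence[OrthologSet]) -> MergeReport:
    """Merge overlapping per-query ortholog groups into disjoint groups.

    Groups sharing at least one gene are unioned (transitively). The
    report gives the fraction of merged groups identical to at least one
    input group, and the fraction of queries whose merged group is such an
    identical group ("genes rescued").
    """
    if not orthosets:
        raise ValueError("need at least one ortholog set")
    g = nx.Graph()
    input_sets = [frozenset(o.orthologs) for o in orthosets]
    for s in input_sets:
        members = sorted(s)
        g.add_node(members[0])
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)
    groups = sorted(
        (frozenset(c) for c in nx.connected_components(g)), key=lambda c: min(c)
    )
    unique_inputs = set(input_sets)
    identical = [grp for grp in groups if grp in unique_inputs]
    pct_identical = 100.0 * len(identical) / len(groups)
    identical_set = set(identical)
    gene_to_group: dict[str, frozenset[str]] = {}
    for grp in groups:
        for gene in grp:
            gene_to_group[gene] = grp
    rescued = sum(
        1 for o in orthosets if gene_to_group[o.query_gene] in identical_set
    )
    pct_rescued = 100.0 * rescued / len(orthosets)
    return MergeReport(groups, pct_identical, pct_rescued)
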