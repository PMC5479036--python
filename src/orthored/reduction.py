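"""Screening of initial search hits into a per-query reduced dataset.

The reduction applies, in order: the e-value cutoff, a sequence-similarity
screen (by default the length-dependent identity threshold curve of Rost's
twilight-zone analysis), retention of at most *n* best-e-value genes per
species (all genes kept on an exact tie), and collapse of isoforms to the
single best-e-value representative per gene. The query's own sequence is
always part of the reduced dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqdata import Dataset, SequenceRecord, UnknownIdError
from .simsearch import DEFAULT_EVALUE_CUTOFF, SimilarityHit

__all__ = [
    "ScreenConfig",
    "rost_threshold",
    "screen_hits",
    "top_n_per_species",
    "collapse_isoforms_best",
    "reduce_for_query",
    "screening_log_tsv",
]

_ROST_L_MAX = 450


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of the hit screen.

    ``similarity_rule`` is either ``"rost_curve"`` (length-dependent %identity
    threshold) or ``"user_thresholds"`` with at least one of ``min_length`` /
    ``min_pident`` set.
    """

    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    n: int = 4
    similarity_rule: str = "rost_curve"
    min_length: int | None = None
    min_pident: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.similarity_rule not in ("rost_curve", "user_thresholds"):
            raise ValueError(f"unknown similarity_rule {self.similarity_rule!r}")
        if self.similarity_rule == "user_thresholds" and self.min_length is None and self.min_pident is None:
            raise ValueError("user_thresholds requires min_length and/or min_pident")


def rost_threshold(alignment_length: int) -> float:
    """Minimum %identity for an alignment of the given length to count as similar.

    100% for lengths up to 11; ``480 * L**(-0.32 * (1 + exp(-L/1000)))``
    for 11 < L <= 450; constant (the L=450 value, about 19.5%) beyond 450.
    """
    if alignment_length < 1:
        raise ValueError("alignment_length must be >= 1")
    L = min(alignment_length, _ROST_L_MAX)
    if L <= 11:
        return 100.0
    return min(100.0, 480.0 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0))))


def screen_hits(hits: Sequence[SimilarityHit], cfg: ScreenConfig) -> list[SimilarityHit]:
    """Apply the e-value cutoff and the similarity screen; order preserved."""
    kept = []
    for h in hits:
        if h.evalue >= cfg.evalue_cutoff:
            continue
        if cfg.similarity_rule == "rost_curve":
            if h.percent_identity < rost_threshold(h.alignment_length):
                continue
        else:
            if cfg.min_length is not None and h.alignment_length < cfg.min_length:
                continue
            if cfg.min_pident is not None and h.percent_identity < cfg.min_pident:
                continue
        kept.append(h)
    return kept


def top_n_per_species(
    hits: Sequence[SimilarityHit], dataset: Dataset, n: int
) -> list[SimilarityHit]:
    """Keep at most the `n` best-e-value subjects per species, ties included.

    Per species, the threshold is the n-th smallest e-value among its
    subjects; every subject at or below that threshold is kept, so an exact
    tie at the boundary retains all tied genes. Input order is preserved.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    by_species: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        sp = dataset.species_of(h.subject_id)  # raises UnknownIdError if absent
        by_species.setdefault(sp, []).append(h)
    keep_ids: set[str] = set()
    for sp, sp_hits in by_species.items():
        evalues = sorted(h.evalue for h in sp_hits)
        threshold = evalues[min(n, len(evalues)) - 1]
        keep_ids.update(h.subject_id for h in sp_hits if h.evalue <= threshold)
    return [h for h in hits if h.subject_id in keep_ids]


def collapse_isoforms_best(
    hits: Sequence[SimilarityHit], dataset: Dataset
) -> list[SimilarityHit]:
    """Keep one isoform per gene: the best e-value, ties to the smallest seq_id.

    A no-op when the dataset carries no isoform map.
    """
    if not dataset.isoform_map:
        return list(hits)
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        gene = dataset.gene_of(h.subject_id)
        prev = best.get(gene)
        if prev is None or (h.evalue, h.subject_id) < (prev.evalue, prev.subject_id):
            best[gene] = h
    keep_ids = {h.subject_id for h in best.values()}
    return [h for h in hits if h.subject_id in keep_ids]


def reduce_for_query(
    query: SequenceRecord,
    hits: Sequence[SimilarityHit],
    dataset: Dataset,
    cfg: ScreenConfig,
) -> tuple[list[SimilarityHit], Dataset]:
    """Full Step-2 reduction: screen, top-n, isoform collapse, query inclusion.

    Returns the surviving hits and the reduced dataset (always containing
    the query's own record).
    """
    kept = screen_hits(hits, cfg)
    kept = top_n_per_species(kept, dataset, cfg.n)
    kept = collapse_isoforms_best(kept, dataset)
    ids = {h.subject_id for h in kept}
    ids.add(query.seq_id)
    if query.seq_id in dataset:
        reduced = dataset.subset(ids)
    else:
        reduced = Dataset(
            [query] + [dataset.get(s) for s in sorted(ids - {query.seq_id})],
            isoform_map={
                g: grp & ids for g, grp in dataset.isoform_map.items() if grp & ids
            },
        )
    return kept, reduced


def screening_log_tsv(
    hits: Sequence[SimilarityHit], kept: Iterable[SimilarityHit], dataset: Dataset
) -> str:
    """TSV log: subject, species, evalue, kept/removed."""
    kept_ids = {h.subject_id for h in kept}
    lines = ["subject\tspecies\tevalue\tstatus"]
    for h in hits:
        try:
            sp = dataset.species_of(h.subject_id)
        except UnknownIdError:
            sp = "?"
        status = "kept" if h.subject_id in kept_ids else "removed"
        lines.append(f"{h.subject_id}\t{sp}\t{h.evalue:.3g}\t{status}")
    return "\n".join(lines) + "\n"
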