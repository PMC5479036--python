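"""Per-query orchestration of the full orthology prediction pipeline.

For each gene of interest: similarity search against the dataset, hit
screening into a reduced dataset, all-vs-all search, Markov clustering,
alignment and tree inference for the cluster of interest, rooting
(outgroup RT rule or midpoint), long-branch pruning, event labeling, and
ortholog clade extraction with isoform reintroduction. Each query is
processed independently, so any subset of a dataset's genes can be
analyzed without touching the rest.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

from . import mcl as mcl_mod
from . import orthology, reduction, simsearch, treebuild
from .orthology import OrthologSet
from .seqdata import Dataset, SequenceRecord, write_fasta

__all__ = ["RunConfig", "RunArtifacts", "run_single_query", "run_batch", "BatchResult"]

logger = logging.getLogger("orthored")

MIN_TREE_SEQUENCES = 4  # clusters smaller than this skip tree building


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters; the defaults are the tool's standard settings."""

    engine: str = "internal"
    evalue_cutoff: float = 1e-3
    fill_evalue: float = 9e-1
    n: int = 4
    similarity_rule: str = "rost_curve"
    min_length: int | None = None
    min_pident: float | None = None
    inflation: float = 1.2
    branch_cutoff: float = 2.0
    alignment_mode: str = "auto"
    alignment_switch: int = 200
    alignment_engine: str = "internal"
    tree_engine: str = "internal"
    outgroup: str | None = None
    seed: int = 0

    def screen_config(self) -> reduction.ScreenConfig:
        return reduction.ScreenConfig(
            evalue_cutoff=self.evalue_cutoff,
            n=self.n,
            similarity_rule=self.similarity_rule,
            min_length=self.min_length,
            min_pident=self.min_pident,
        )


@dataclass
class RunArtifacts:
    """Intermediate products of one query's run, for inspection or dumping."""

    hits: list = field(default_factory=list)
    reduced: Dataset | None = None
    matrix: simsearch.SimilarityMatrix | None = None
    clustering: mcl_mod.Clustering | None = None
    cluster: frozenset | None = None
    alignment: treebuild.Alignment | None = None
    tree: object | None = None
    labeled_tree: object | None = None

    def write(self, outdir: str, query_id: str) -> None:
        safe = query_id.replace("|", "_").replace("/", "_")
        os.makedirs(outdir, exist_ok=True)
        if self.hits:
            with open(os.path.join(outdir, f"{safe}.hits.tsv"), "w") as fh:
                fh.write(simsearch.hits_to_tsv(self.hits))
        if self.reduced is not None:
            write_fasta(self.reduced, os.path.join(outdir, f"{safe}.reduced.faa"))
        if self.alignment is not None:
            with open(os.path.join(outdir, f"{safe}.aln.faa"), "w") as fh:
                fh.write(self.alignment.to_fasta())
        if self.tree is not None:
            with open(os.path.join(outdir, f"{safe}.nwk"), "w") as fh:
                fh.write(treebuild.write_newick(self.tree) + "\n")
        if self.labeled_tree is not None:
            with open(os.path.join(outdir, f"{safe}.labeled.nwk"), "w") as fh:
                fh.write(orthology.annotated_newick(self.labeled_tree) + "\n")


def _attach_provenance(oset: OrthologSet, hits, dataset: Dataset) -> None:
    """Record, per member gene, its best initial e-value and within-species rank."""
    gene_evalue: dict[str, float] = {}
    for h in hits:
        g = dataset.gene_of(h.subject_id)
        if g not in gene_evalue or h.evalue < gene_evalue[g]:
            gene_evalue[g] = h.evalue
    by_species: dict[str, list[float]] = {}
    for g, e in gene_evalue.items():
        by_species.setdefault(dataset.species_of_gene(g), []).append(e)
    for gene in oset.orthologs:
        if gene not in gene_evalue:
            continue
        sp = dataset.species_of_gene(gene)
        rank = 1 + sum(1 for e in by_species[sp] if e < gene_evalue[gene])
        oset.provenance[gene] = {"rank": rank, "evalue": gene_evalue[gene]}


def run_single_query(
    query: SequenceRecord,
    dataset: Dataset,
    cfg: RunConfig | None = None,
    keep_artifacts: bool = False,
) -> tuple[OrthologSet, RunArtifacts]:
    """Predict the orthologs of one query gene.

    Returns the gene-level :class:`OrthologSet` plus the intermediate
    artifacts. A query with no hits besides itself yields the singleton
    set with a warning, not an error. Deterministic with the internal
    engines for a fixed configuration.
    """
    cfg = cfg or RunConfig()
    if cfg.outgroup is not None and query.species_id == cfg.outgroup:
        raise ValueError(
            f"query {query.seq_id!r} belongs to the outgroup species; the gene tree "
            "is rooted by the outgroup, so outgroup queries cannot be analyzed"
        )
    art = RunArtifacts()

    hits = simsearch.search_one_vs_all(query, dataset, cfg.engine, cfg.evalue_cutoff)
    art.hits = hits
    kept, reduced = reduction.reduce_for_query(query, hits, dataset, cfg.screen_config())
    art.reduced = reduced
    logger.debug("query %s: %d hits, reduced dataset of %d", query.seq_id, len(hits), len(reduced))

    if len(reduced) == 1:
        oset = OrthologSet(query_gene=dataset.gene_of(query.seq_id) if query.seq_id in dataset else query.gene_id,
                           orthologs=set(), seq_members={query.seq_id})
        oset.warnings.append("no significant hits besides the query itself")
        oset = orthology.reintroduce_isoforms(oset, dataset) if query.seq_id in dataset else oset
        _attach_provenance(oset, hits, dataset)
        return oset, art

    matrix = simsearch.all_vs_all_matrix(reduced, cfg.engine, cfg.evalue_cutoff, cfg.fill_evalue)
    art.matrix = matrix
    graph = mcl_mod.graph_from_matrix(matrix)
    clustering = mcl_mod.mcl_cluster(graph, inflation=cfg.inflation)
    art.clustering = clustering
    cluster = mcl_mod.cluster_of_interest(clustering, query.seq_id)
    art.cluster = cluster

    if len(cluster) < MIN_TREE_SEQUENCES:
        # too small for a meaningful tree: report the cluster itself
        genes = {reduced.gene_of(s) for s in cluster}
        oset = OrthologSet(
            query_gene=reduced.gene_of(query.seq_id),
            orthologs=genes,
            seq_members=set(cluster),
        )
        oset.warnings.append("cluster of interest too small for tree building")
        if dataset.outgroup_species is not None:
            flagged = {
                reduced.gene_of(s)
                for s in cluster
                if reduced.species_of(s) == dataset.outgroup_species
            }
            if flagged:
                oset.flags["outgroup"] = flagged
    else:
        members = [reduced.get(s) for s in sorted(cluster)]
        aln = treebuild.align_cluster(
            members, mode=cfg.alignment_mode, engine=cfg.alignment_engine, switch=cfg.alignment_switch
        )
        art.alignment = aln
        tree = treebuild.infer_tree(aln, engine=cfg.tree_engine, seed=cfg.seed)
        art.tree = tree
        rooted = None
        if cfg.outgroup is not None:
            rooted = orthology.root_rt(tree, query.seq_id, cfg.outgroup, reduced)
        if rooted is None:
            rooted = orthology.root_midpoint(tree)
        rooted = orthology.prune_long_branches(
            rooted, query.seq_id, cfg.branch_cutoff, dataset=reduced, outgroup_species=cfg.outgroup
        )
        if not rooted.is_tip():
            orthology.label_events(rooted, reduced)
        art.labeled_tree = rooted
        oset = orthology.extract_orthologs(rooted, query.seq_id, dataset)

    oset = orthology.reintroduce_isoforms(oset, dataset)
    _attach_provenance(oset, hits, dataset)
    return oset, art


@dataclass
class BatchResult:
    """Per-query results of a batch run plus batch-level post-analyses."""

    orthosets: list[OrthologSet]
    failures: dict[str, str]
    initial_hits: dict[str, list]


def run_batch(
    queries: Sequence[SequenceRecord],
    dataset: Dataset,
    cfg: RunConfig | None = None,
) -> BatchResult:
    """Run the pipeline for each query independently.

    One failing query is recorded and does not abort the batch. Results
    are identical to per-query :func:`run_single_query` calls.
    """
    cfg = cfg or RunConfig()
    orthosets: list[OrthologSet] = []
    failures: dict[str, str] = {}
    initial_hits: dict[str, list] = {}
    for query in queries:
        try:
            oset, art = run_single_query(query, dataset, cfg)
        except Exception as exc:  # pragma: no cover - per-query isolation
            failures[query.seq_id] = str(exc)
            logger.warning("query %s failed: %s", query.seq_id, exc)
            continue
        orthosets.append(oset)
        initial_hits[oset.query_gene] = art.hits
    return BatchResult(orthosets, failures, initial_hits)
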