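"""Gene-tree rooting, long-branch pruning, and species-overlap orthology calls.

The final stages of the pipeline interpret the gene tree:

* **Rooting** uses a user-declared outgroup species when one of its genes is
  in the tree (RT rule: root on the outgroup gene whose rooting gives the
  outgroup-free subtree containing the query with the most ingroup species;
  ties go to the outgroup gene most distant from the query, then to
  alphanumeric order), and midpoint rooting otherwise.
* **Pruning** cuts every branch longer than a cutoff (default 2
  substitutions/site) and keeps the connected component containing the
  query, re-rooting if the cut removed the root.
* **Event labeling** walks the rooted tree: an internal node whose subtree
  spans a single species is a single-species-gene node (treated as one gene
  with unlabeled isoforms); otherwise the node is a duplication when its
  child clades share at least one species and a speciation when they do
  not. Every speciation ancestor of a duplication node is overwritten to a
  duplication.
* **Extraction** returns the leaves of the daughter clade of the most
  recent duplication on the query's root-ward path (the whole tree when no
  duplication lies on it), then reintroduces unsampled isoforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from skbio import TreeNode

from .seqdata import Dataset, UnknownIdError

__all__ = [
    "OrthologSet",
    "EVENT_SPECIATION",
    "EVENT_DUPLICATION",
    "EVENT_SINGLE_SPECIES",
    "root_rt",
    "root_midpoint",
    "prune_long_branches",
    "label_events",
    "extract_orthologs",
    "reintroduce_isoforms",
    "annotated_newick",
    "orthologs_tsv",
]

EVENT_SPECIATION = "speciation"
EVENT_DUPLICATION = "duplication"
EVENT_SINGLE_SPECIES = "single_species_gene"

DEFAULT_BRANCH_CUTOFF = 2.0


@dataclass
class OrthologSet:
    """Predicted orthologs of one query gene, at gene level.

    ``orthologs`` always contains the query gene. ``seq_members`` are the
    sequence IDs backing the prediction (isoform representatives from the
    tree, expanded by :func:`reintroduce_isoforms`). ``flags`` carries
    per-member annotations such as ``outgroup`` membership;
    ``provenance`` maps member genes to initial-search rank and e-value.
    """

    query_gene: str
    orthologs: set[str]
    seq_members: set[str] = field(default_factory=set)
    flags: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.orthologs = set(self.orthologs)
        self.orthologs.add(self.query_gene)


def _species_sets(tree: TreeNode, dataset: Dataset) -> dict[int, set[str]]:
    """Species spanned by each node's subtree, by node id."""
    out: dict[int, set[str]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            try:
                out[id(node)] = {dataset.species_of(node.name)}
            except UnknownIdError:
                raise UnknownIdError(f"tree leaf {node.name!r} is not in the dataset") from None
        else:
            out[id(node)] = set().union(*(out[id(c)] for c in node.children))
    return out


def _tip(tree: TreeNode, name: str) -> TreeNode:
    for t in tree.tips():
        if t.name == name:
            return t
    raise KeyError(f"leaf {name!r} not in tree")


def _root_at_tip_branch(tree: TreeNode, tip_name: str) -> TreeNode:
    """Root on the pendant branch of a tip (at its midpoint)."""
    tip = _tip(tree, tip_name)
    half = (tip.length or 0.0) / 2.0
    rooted = tree.root_at(tip, above=half, reset=True)
    return rooted


def root_rt(
    t: TreeNode,
    query: str,
    outgroup_species: str,
    dataset: Dataset,
) -> TreeNode | None:
    """Root with the outgroup gene maximizing the query's outgroup-free subtree.

    For every leaf of the outgroup species, the tree is rooted on that
    leaf's pendant branch, and the largest query-containing subtree with no
    outgroup gene is measured by its number of ingroup species. The
    candidate with the highest count wins; ties go to the candidate most
    distant from the query by branch length, remaining ties to the
    alphanumerically smallest seq_id. Returns None when the tree carries no
    outgroup leaf (the caller then falls back to midpoint rooting).
    """
    candidates = sorted(
        tip.name for tip in t.tips() if dataset.species_of(tip.name) == outgroup_species
    )
    if not candidates:
        return None
    query_tip = _tip(t, query)

    scored: list[tuple[int, float, str]] = []
    for cand in candidates:
        rooted = _root_at_tip_branch(t, cand)
        sp = _species_sets(rooted, dataset)
        node = _tip(rooted, query)
        best = node
        while node.parent is not None:
            node = node.parent
            if outgroup_species in sp[id(node)]:
                break
            best = node
        count = len(sp[id(best)] - {outgroup_species})
        dist = query_tip.distance(_tip(t, cand))
        scored.append((count, float(dist), cand))
    # most species first, then most distant, then smallest id
    scored.sort(key=lambda s: (-s[0], -s[1], s[2]))
    winner = scored[0][2]
    return _root_at_tip_branch(t, winner)


def root_midpoint(t: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    With all branch lengths zero the midpoint is undefined; the tree is
    then rooted at the parent of the alphanumerically smallest leaf, with a
    warning.
    """
    tips = sorted(t.tips(), key=lambda n: n.name)
    if len(tips) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    dm = t.tip_tip_distances()
    best_pair: tuple[str, str] | None = None
    best_d = -1.0
    names = sorted(dm.ids)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = dm[a, b]
            if d > best_d:
                best_d, best_pair = d, (a, b)
    if best_d <= 0:
        warnings.warn("all branch lengths are zero; rooting at an arbitrary internal node")
        anchor = _tip(t, names[0]).parent
        return t.root_at(anchor, reset=True) if anchor is not None else t
    a_name, b_name = best_pair
    a, b = _tip(t, a_name), _tip(t, b_name)
    lca = t.lowest_common_ancestor([a, b])
    up: list[TreeNode] = []  # edges ascending from a (edge = its child node)
    node = a
    while node is not lca:
        up.append(node)
        node = node.parent
    down: list[TreeNode] = []  # edges descending toward b
    node = b
    while node is not lca:
        down.append(node)
        node = node.parent
    down.reverse()
    target = best_d / 2.0
    cum = 0.0
    for edge in up:
        length = edge.length or 0.0
        if cum + length >= target:
            return t.root_at(edge, above=target - cum, reset=True)
        cum += length
    for edge in down:
        length = edge.length or 0.0
        if cum + length >= target:
            # entering this edge from its parent side
            return t.root_at(edge, above=length - (target - cum), reset=True)
        cum += length
    # numerically at the far end; root on b's pendant branch
    return _root_at_tip_branch(t, b_name)


def _iterative_cut(
    adjacency: dict[int, dict[int, float]], query_node: int, leaves: set[int], cutoff: float
) -> tuple[set[int], dict[int, int]]:
    """Cut/contract fixpoint on an undirected weighted tree.

    Repeatedly removes edges longer than `cutoff`, keeps the query's
    component, and contracts the degree-2 junctions left behind (their two
    edge lengths add, which can create new over-long edges). Returns the
    surviving node set and the final degree of each survivor.
    """
    adj = {u: dict(nbrs) for u, nbrs in adjacency.items()}
    while True:
        long_edges = [
            (u, v) for u, nbrs in adj.items() for v, w in nbrs.items() if u < v and w > cutoff
        ]
        if not long_edges:
            break
        for u, v in long_edges:
            del adj[u][v]
            del adj[v][u]
        # component of the query
        seen = {query_node}
        stack = [query_node]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        adj = {u: {v: w for v, w in nbrs.items() if v in seen} for u, nbrs in adj.items() if u in seen}
        # drop dangling internal stubs (their leaves were all cut), then
        # contract degree-2 internal junctions (never leaves)
        changed = True
        while changed:
            changed = False
            for u in list(adj):
                if u in leaves:
                    continue
                if len(adj[u]) <= 1:
                    for nb in list(adj[u]):
                        del adj[nb][u]
                    del adj[u]
                    changed = True
                elif len(adj[u]) == 2:
                    (a, wa), (b, wb) = adj[u].items()
                    del adj[u]
                    del adj[a][u]
                    del adj[b][u]
                    adj[a][b] = wa + wb
                    adj[b][a] = wa + wb
                    changed = True
    return set(adj), {u: len(nbrs) for u, nbrs in adj.items()}


def prune_long_branches(
    t: TreeNode,
    query: str,
    cutoff: float = DEFAULT_BRANCH_CUTOFF,
    dataset: Dataset | None = None,
    outgroup_species: str | None = None,
) -> TreeNode:
    """Cut all branches longer than `cutoff`; keep the query's component.

    Cutting operates on the unrooted topology: suppressed degree-2
    junctions concatenate their branches, which can itself create an
    over-long branch, so cutting repeats to a fixpoint (making the
    operation idempotent and independent of where the root happens to
    sit). The surviving leaves are then sheared out of the original tree.
    If the cuts removed the original root, the retained subtree is
    re-rooted — with the RT rule when an outgroup leaf survives (requires
    `dataset` and `outgroup_species`), at midpoint otherwise.
    """
    adjacency: dict[int, dict[int, float]] = {id(n): {} for n in t.traverse(include_self=True)}
    for n in t.traverse(include_self=False):
        w = float(n.length or 0.0)
        adjacency[id(n)][id(n.parent)] = w
        adjacency[id(n.parent)][id(n)] = w
    tips = {id(n): n.name for n in t.tips()}
    query_node = next(nid for nid, name in tips.items() if name == query)

    surviving, degrees = _iterative_cut(adjacency, query_node, set(tips), cutoff)
    retained = sorted(name for nid, name in tips.items() if nid in surviving)
    if retained == sorted(tips.values()):
        return t
    if len(retained) == 1:
        single = TreeNode(name=None)
        single.append(TreeNode(name=query, length=0.0))
        return single
    sheared = t.shear(retained)
    root_ok = degrees.get(id(t), 0) >= 2
    if root_ok:
        return sheared
    rerooted = None
    if outgroup_species is not None and dataset is not None:
        has_outgroup = any(dataset.species_of(name) == outgroup_species for name in retained)
        if has_outgroup and dataset.species_of(query) != outgroup_species:
            rerooted = root_rt(sheared, query, outgroup_species, dataset)
    if rerooted is None:
        rerooted = root_midpoint(sheared)
    return rerooted


def label_events(t: TreeNode, dataset: Dataset) -> dict[int, str]:
    """Label every internal node speciation / duplication / single-species.

    Nodes are annotated in place (``node.event``) and the mapping from
    ``id(node)`` to event is returned. Single-species subtrees never count
    as duplications: such a clade behaves as one gene with several isoforms
    and contributes a single species upward. After the species-overlap
    pass, every speciation ancestor of any duplication node is overwritten
    to a duplication.
    """
    sp = _species_sets(t, dataset)
    events: dict[int, str] = {}
    for node in t.postorder(include_self=True):
        if node.is_tip():
            node.event = None
            continue
        if len(sp[id(node)]) == 1:
            event = EVENT_SINGLE_SPECIES
        else:
            child_sets = [sp[id(c)] for c in node.children]
            overlap = any(
                child_sets[i] & child_sets[j]
                for i in range(len(child_sets))
                for j in range(i + 1, len(child_sets))
            )
            event = EVENT_DUPLICATION if overlap else EVENT_SPECIATION
        node.event = event
        events[id(node)] = event
    # ancestral overwrite: duplications propagate root-ward over speciations
    for node in t.postorder(include_self=True):
        if getattr(node, "event", None) != EVENT_DUPLICATION:
            continue
        anc = node.parent
        while anc is not None and anc.event == EVENT_SPECIATION:
            anc.event = EVENT_DUPLICATION
            events[id(anc)] = EVENT_DUPLICATION
            anc = anc.parent
    return events


def extract_orthologs(t: TreeNode, query: str, dataset: Dataset) -> OrthologSet:
    """Leaves of the daughter clade under the query's most recent duplication.

    Walking from the query leaf toward the root, the first duplication node
    encountered defines the ortholog clade: its child on the query's side.
    When no duplication lies on the path, the whole leaf set is returned.
    Members are reported at gene level; surviving outgroup genes are kept
    but flagged.
    """
    tip = _tip(t, query)
    if getattr(t, "event", None) is None and not t.is_tip():
        label_events(t, dataset)
    node = tip
    clade: TreeNode | None = None
    while node.parent is not None:
        if node.parent.event == EVENT_DUPLICATION:
            clade = node
            break
        node = node.parent
    if clade is None:
        members = [l.name for l in t.tips()]
    elif clade.is_tip():
        members = [clade.name]
    else:
        members = [l.name for l in clade.tips()]
    oset = OrthologSet(
        query_gene=dataset.gene_of(query),
        orthologs={dataset.gene_of(s) for s in members},
        seq_members=set(members) | {query},
    )
    out_sp = dataset.outgroup_species
    if out_sp is not None:
        flagged = {dataset.gene_of(s) for s in members if dataset.species_of(s) == out_sp}
        if flagged:
            oset.flags["outgroup"] = flagged
    return oset


def reintroduce_isoforms(o: OrthologSet, dataset: Dataset) -> OrthologSet:
    """Add every isoform of each member gene back into the sequence-level set."""
    seq_members = set(o.seq_members)
    for gene in o.orthologs:
        seq_members |= dataset.isoforms_of(gene)
    return OrthologSet(
        query_gene=o.query_gene,
        orthologs=set(o.orthologs),
        seq_members=seq_members,
        flags=dict(o.flags),
        provenance=dict(o.provenance),
        warnings=list(o.warnings),
    )


def annotated_newick(t: TreeNode) -> str:
    """Newick with NHX-style event comments on internal nodes."""
    def render(node: TreeNode) -> str:
        if node.is_tip():
            label = node.name or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            label = f"({inner})"
            event = getattr(node, "event", None)
            if event:
                label += f"[&event={event}]"
        if node.length is not None:
            label += f":{node.length:.10g}"
        return label

    return render(t) + ";"


def orthologs_tsv(o: OrthologSet, dataset: Dataset) -> str:
    """One row per predicted member: query, member seq, species, rank, e-value, flags."""
    lines = ["query\tmember\tspecies\trank\tevalue\tflags"]
    outgroup = o.flags.get("outgroup", set())
    for seq_id in sorted(o.seq_members):
        gene = dataset.gene_of(seq_id)
        prov = o.provenance.get(gene, {})
        rank = prov.get("rank", "")
        ev = prov.get("evalue", "")
        flags = "outgroup" if gene in outgroup else ""
        lines.append(
            f"{o.query_gene}\t{seq_id}\t{dataset.species_of(seq_id)}\t{rank}\t{ev}\t{flags}"
        )
    return "\n".join(lines) + "\n"
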