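"""Synthetic gene families with a known duplication/speciation history.

A gene family is grown along a species tree by a birth-death process
(duplication and loss rates per lineage per unit branch length), a random
root protein is evolved along the resulting gene tree by per-site
substitution, and optional isoforms are added as lightly edited copies.
Because every internal node of the simulated gene tree carries its true
event, the family provides an algorithm-independent pairwise orthology
oracle: two genes are true orthologs exactly when their most recent common
ancestor in the gene tree is a speciation event.

An ``ancient_duplication`` switch plants one duplication before the species
root with an adjustable stem length, producing two gene copies whose
inter-copy divergence dominates the intra-copy divergence — the classic
hard case a tree-based predictor must resolve that similarity ranking
alone cannot.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from skbio import TreeNode

from .seqdata import Dataset, SequenceRecord

__all__ = [
    "FamilyTruth",
    "DEFAULT_SPECIES_TREE",
    "simulate_family",
    "true_orthologs",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# Five-species tree, tip depth 0.15 substitutions/site at unit rate.
DEFAULT_SPECIES_TREE = (
    "((S01:0.06,S02:0.06):0.06,(S03:0.08,(S04:0.05,S05:0.05):0.03):0.04):0.03;"
)


@dataclass
class FamilyTruth:
    """A simulated family: species tree, true gene tree, sequences, truth oracle."""

    species_tree: TreeNode
    gene_tree: TreeNode | None
    records: list[SequenceRecord]
    isoform_map: dict[str, set[str]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    extinct: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return sorted({r.gene_id for r in self.records})

    def to_dataset(self, outgroup: str | None = None) -> Dataset:
        return Dataset(
            list(self.records),
            outgroup_species=outgroup,
            isoform_map={g: set(s) for g, s in self.isoform_map.items()} or None,
        )

    def true_orthologs(self, gene: str) -> set[str]:
        return true_orthologs(self, gene)


def _read_tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


def simulate_family(
    species_tree: str | TreeNode | None = None,
    dup_rate: float = 0.0,
    loss_rate: float = 0.0,
    sub_rate: float = 1.0,
    root_length: int = 200,
    isoforms: bool = False,
    seed: int = 0,
    ancient_duplication: bool = False,
    ancient_stem: float = 0.3,
) -> FamilyTruth:
    """Simulate one gene family along a species tree.

    ``dup_rate`` and ``loss_rate`` are events per lineage per unit branch
    length; ``sub_rate`` is expected substitutions per site per unit branch
    length. ``root_length`` is the ancestral protein length (>= 50). With
    ``ancient_duplication`` the family starts from a duplication above the
    species root whose two copies are separated by ``2 * ancient_stem``
    extra branch length. Deterministic for a fixed seed; a family whose
    lineages all die is returned empty with ``extinct=True``.
    """
    if dup_rate < 0 or loss_rate < 0 or sub_rate < 0:
        raise ValueError("rates must be non-negative")
    if root_length < 50:
        raise ValueError("root_length must be >= 50")
    rng = np.random.default_rng(seed)
    if species_tree is None:
        sp_tree = _read_tree(DEFAULT_SPECIES_TREE)
    elif isinstance(species_tree, str):
        sp_tree = _read_tree(species_tree)
    else:
        sp_tree = species_tree.copy()

    counter = [0]

    def new_leaf(species: str, length: float) -> TreeNode:
        counter[0] += 1
        leaf = TreeNode(name=f"{species}|g{counter[0]:03d}", length=length)
        leaf.event = None
        return leaf

    def evolve_branch(sp_node: TreeNode, remaining: float, accrued: float) -> TreeNode | None:
        """One gene lineage along the remainder of a species-tree branch.

        Returns the subtree rooted where this lineage enters the branch
        (branch length = accrued + time to next event), or None if every
        descendant lineage dies.
        """
        total_rate = dup_rate + loss_rate
        wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
        if wait >= remaining:
            return at_branch_end(sp_node, accrued + remaining)
        if rng.random() < loss_rate / total_rate:
            return None  # loss
        # duplication: two sub-lineages continue along the rest of the branch
        left = evolve_branch(sp_node, remaining - wait, 0.0)
        right = evolve_branch(sp_node, remaining - wait, 0.0)
        live = [c for c in (left, right) if c is not None]
        if not live:
            return None
        if len(live) == 1:
            child = live[0]
            child.length += accrued + wait
            return child
        node = TreeNode(length=accrued + wait)
        node.event = "duplication"
        node.extend(live)
        return node

    def at_branch_end(sp_node: TreeNode, accrued: float) -> TreeNode | None:
        if sp_node.is_tip():
            return new_leaf(sp_node.name, accrued)
        children = []
        for sp_child in sp_node.children:
            sub = evolve_branch(sp_child, sp_child.length or 0.0, 0.0)
            if sub is not None:
                children.append(sub)
        if not children:
            return None
        if len(children) == 1:
            child = children[0]
            child.length += accrued
            return child
        node = TreeNode(length=accrued)
        node.event = "speciation"
        node.extend(children)
        return node

    root_branch = sp_tree.length or 0.0
    if ancient_duplication:
        copies = []
        for _ in range(2):
            sub = evolve_branch(sp_tree, root_branch, 0.0)
            if sub is not None:
                sub.length += ancient_stem
                copies.append(sub)
        if not copies:
            gene_tree = None
        elif len(copies) == 1:
            gene_tree = copies[0]
            gene_tree.length = 0.0
        else:
            gene_tree = TreeNode(length=0.0)
            gene_tree.event = "duplication"
            gene_tree.extend(copies)
    else:
        gene_tree = evolve_branch(sp_tree, root_branch, 0.0)
        if gene_tree is not None:
            gene_tree.length = 0.0

    params = dict(
        dup_rate=dup_rate,
        loss_rate=loss_rate,
        sub_rate=sub_rate,
        root_length=root_length,
        seed=seed,
        ancient_duplication=ancient_duplication,
        ancient_stem=ancient_stem,
    )
    if gene_tree is None:
        return FamilyTruth(sp_tree, None, [], params=params, extinct=True)

    # evolve sequences down the gene tree
    root_seq = rng.choice(AMINO_ACIDS, size=root_length)
    seqs: dict[int, np.ndarray] = {id(gene_tree): _mutate(root_seq, gene_tree.length or 0.0, sub_rate, rng)}
    for node in gene_tree.preorder(include_self=False):
        parent_seq = seqs[id(node.parent)]
        seqs[id(node)] = _mutate(parent_seq, node.length or 0.0, sub_rate, rng)

    records: list[SequenceRecord] = []
    isoform_map: dict[str, set[str]] = {}
    tips = [gene_tree] if gene_tree.is_tip() else list(gene_tree.tips())
    for tip in tips:
        species = tip.name.split("|")[0]
        seq = "".join(seqs[id(tip)])
        records.append(
            SequenceRecord(seq_id=tip.name, species_id=species, residues=seq, gene_id=tip.name)
        )
        if isoforms:
            n_iso = int(rng.integers(0, 3))
            if n_iso:
                group = {tip.name}
                for k in range(1, n_iso + 1):
                    iso_id = f"{tip.name}.i{k}"
                    group.add(iso_id)
                    records.append(
                        SequenceRecord(
                            seq_id=iso_id,
                            species_id=species,
                            residues=_isoform_edit(seq, rng),
                            gene_id=tip.name,
                        )
                    )
                isoform_map[tip.name] = group

    return FamilyTruth(sp_tree, gene_tree, records, isoform_map, params=params)


def _mutate(seq: np.ndarray, branch_length: float, sub_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution: each site changes with p = 1 - exp(-rate * t)."""
    out = seq.copy()
    p = 1.0 - np.exp(-sub_rate * branch_length)
    if p <= 0:
        return out
    hit = rng.random(len(seq)) < p
    for i in np.nonzero(hit)[0]:
        choices = AMINO_ACIDS[AMINO_ACIDS != out[i]]
        out[i] = rng.choice(choices)
    return out


def _isoform_edit(seq: str, rng: np.random.Generator, max_edit_frac: float = 0.05) -> str:
    """An isoform: a copy with a few point edits and an optional short deletion."""
    arr = np.array(list(seq))
    n_edits = int(rng.integers(0, max(1, int(len(arr) * max_edit_frac)) + 1))
    for _ in range(n_edits):
        i = int(rng.integers(0, len(arr)))
        choices = AMINO_ACIDS[AMINO_ACIDS != arr[i]]
        arr[i] = rng.choice(choices)
    if rng.random() < 0.5 and len(arr) > 70:
        span = int(rng.integers(3, 11))
        start = int(rng.integers(1, len(arr) - span - 1))
        arr = np.concatenate([arr[:start], arr[start + span :]])
    return "".join(arr)


def true_orthologs(ft: FamilyTruth, gene: str) -> set[str]:
    """All genes whose MRCA with `gene` in the true gene tree is a speciation.

    This is the field-standard pairwise orthology definition, independent
    of any prediction algorithm; the gene itself is included.
    """
    if ft.gene_tree is None:
        raise KeyError(f"empty family has no gene {gene!r}")
    tips = {t.name: t for t in ([ft.gene_tree] if ft.gene_tree.is_tip() else ft.gene_tree.tips())}
    if gene not in tips:
        raise KeyError(f"unknown gene {gene!r}")
    result = {gene}
    for other, tip in tips.items():
        if other == gene:
            continue
        mrca = ft.gene_tree.lca([tips[gene], tip])
        if getattr(mrca, "event", None) == "speciation":
            result.add(other)
    return result
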