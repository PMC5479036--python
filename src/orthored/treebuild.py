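"""Multiple sequence alignment and gene-tree inference.

Two engines are offered for each step. Alignment: an internal deterministic
center-star aligner (pairwise semi-global alignments to the sequence with
the best total pairwise score, merged into one master gap pattern) and an
adapter to an external ``mafft`` binary. Tree inference: an internal
distance engine — neighbor joining on corrected protein distances for the
topology, followed by a second pass fitting branch lengths to the full
distance matrix by non-negative least squares — mirroring the
topology-first, lengths-second scheme of maximum-likelihood workflows
without their cost.

The mode switch for alignment follows the usual accuracy/speed recommendation:
accuracy-oriented settings below 200 sequences, speed-oriented at 200 or more.
"""

from __future__ import annotations

import io
import math
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.optimize import nnls
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .seqdata import SequenceRecord, write_fasta
from .simsearch import _aligner

__all__ = [
    "Alignment",
    "NewickParseError",
    "MAFFT_ACCURATE_ARGS",
    "MAFFT_FAST_ARGS",
    "ALIGNMENT_MODE_SWITCH",
    "MAX_PROTEIN_DISTANCE",
    "select_alignment_mode",
    "align_cluster",
    "alignment_distances",
    "pairwise_distances",
    "tree_from_distances",
    "infer_tree",
    "read_newick",
    "write_newick",
]

ALIGNMENT_MODE_SWITCH = 200  # sequences at or above this use the fast mode
MAFFT_ACCURATE_ARGS = ["--localpair", "--retree", "2", "--maxiterate", "1000"]
MAFFT_FAST_ARGS = ["--6merpair", "--retree", "2", "--maxiterate", "1000"]
MAX_PROTEIN_DISTANCE = 10.0  # substitutions/site cap near saturation


class NewickParseError(ValueError):
    """A newick string could not be parsed."""


@dataclass
class Alignment:
    """Equal-length gapped rows over an ordered list of sequence IDs."""

    seq_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.seq_ids) != len(self.rows):
            raise ValueError("seq_ids and rows differ in length")
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("alignment rows differ in length")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def ungapped(self, seq_id: str) -> str:
        return self.rows[self.seq_ids.index(seq_id)].replace("-", "")

    def to_fasta(self) -> str:
        return "".join(f">{s}\n{r}\n" for s, r in zip(self.seq_ids, self.rows))


def select_alignment_mode(n_sequences: int, switch: int = ALIGNMENT_MODE_SWITCH) -> str:
    """'accurate' below the switch point, 'fast' at or above it."""
    return "accurate" if n_sequences < switch else "fast"


def align_cluster(
    records: Sequence[SequenceRecord],
    mode: str = "auto",
    engine: str = "internal",
    switch: int = ALIGNMENT_MODE_SWITCH,
) -> Alignment:
    """Align the sequences of one cluster.

    In ``auto`` mode the accuracy-oriented settings are chosen for fewer
    than `switch` sequences and the speed-oriented settings otherwise; the
    distinction only affects the external mafft adapter — the internal
    center-star aligner has a single behavior.
    """
    if not records:
        raise ValueError("no sequences to align")
    if len(records) == 1:
        warnings.warn("aligning a single sequence: trivial one-row alignment")
        return Alignment([records[0].seq_id], [records[0].residues])
    if mode == "auto":
        mode = select_alignment_mode(len(records), switch)
    if mode not in ("accurate", "fast"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    if engine == "internal":
        return _center_star_align(records)
    if engine == "mafft":
        return _mafft_align(records, mode)
    raise ValueError(f"unknown alignment engine {engine!r}")


def _pairwise_global(a: str, b: str, mode: str = "semiglobal") -> tuple[float, list[tuple[int | None, int | None]]]:
    """Pairwise full-length alignment; returns score and aligned index pairs."""
    aligner = _aligner(mode, "BLOSUM62", 11.0, 1.0)
    aln = aligner.align(a, b)[0]
    pairs: list[tuple[int | None, int | None]] = []
    # walk the two coordinate arrays column by column
    ta, qa = aln.coordinates
    prev_a, prev_b = ta[0], qa[0]
    for ca, cb in zip(ta[1:], qa[1:]):
        step_a, step_b = ca - prev_a, cb - prev_b
        n = max(step_a, step_b)
        for k in range(n):
            ia = prev_a + k if step_a else None
            ib = prev_b + k if step_b else None
            pairs.append((ia, ib))
        prev_a, prev_b = ca, cb
    return float(aln.score), pairs


def _center_star_align(records: Sequence[SequenceRecord]) -> Alignment:
    """Deterministic center-star MSA.

    The center is the sequence with the highest total pairwise alignment
    score (ties to the smallest seq_id); every other sequence is aligned to
    the center and the pairwise gaps are merged into one master pattern of
    insertions relative to center coordinates.
    """
    seqs = [r.residues for r in records]
    ids = [r.seq_id for r in records]
    k = len(seqs)
    aligner = _aligner("semiglobal", "BLOSUM62", 11.0, 1.0)
    totals = np.zeros(k)
    for i, j in combinations(range(k), 2):
        s = aligner.score(seqs[i], seqs[j])
        totals[i] += s
        totals[j] += s
    center = min(range(k), key=lambda i: (-totals[i], ids[i]))
    c_seq = seqs[center]
    Lc = len(c_seq)

    # For each non-center sequence: ins[i] = residues of that sequence
    # inserted before center position i (i == Lc: after the last position),
    # matched[i] = residue aligned to center position i.
    others = [i for i in range(k) if i != center]
    per_seq_ins: dict[int, dict[int, list[int]]] = {}
    per_seq_matched: dict[int, dict[int, int]] = {}
    master_ins = [0] * (Lc + 1)
    for idx in others:
        _, pairs = _pairwise_global(c_seq, seqs[idx])
        ins: dict[int, list[int]] = {}
        matched: dict[int, int] = {}
        next_c = 0
        for ia, ib in pairs:
            if ia is None:
                ins.setdefault(next_c, []).append(ib)  # insertion before next_c
            else:
                if ib is not None:
                    matched[ia] = ib
                next_c = ia + 1
        per_seq_ins[idx] = ins
        per_seq_matched[idx] = matched
        for pos, block in ins.items():
            master_ins[pos] = max(master_ins[pos], len(block))

    def build_center_row() -> str:
        out = []
        for i in range(Lc):
            out.append("-" * master_ins[i])
            out.append(c_seq[i])
        out.append("-" * master_ins[Lc])
        return "".join(out)

    def build_other_row(idx: int) -> str:
        seq = seqs[idx]
        ins = per_seq_ins[idx]
        matched = per_seq_matched[idx]
        out = []
        for i in range(Lc + 1):
            block = ins.get(i, [])
            out.append("".join(seq[b] for b in block))
            out.append("-" * (master_ins[i] - len(block)))
            if i < Lc:
                out.append(seq[matched[i]] if i in matched else "-")
        return "".join(out)

    rows_by_index: dict[int, str] = {center: build_center_row()}
    for idx in others:
        rows_by_index[idx] = build_other_row(idx)
    rows = [rows_by_index[i] for i in range(k)]
    aln = Alignment(list(ids), rows)
    for r, rec in zip(aln.rows, records):  # sanity: ungapping restores inputs
        assert r.replace("-", "") == rec.residues
    return aln


def _mafft_align(records: Sequence[SequenceRecord], mode: str) -> Alignment:
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH; use engine='internal'")
    args = MAFFT_ACCURATE_ARGS if mode == "accurate" else MAFFT_FAST_ARGS
    with tempfile.NamedTemporaryFile("w", suffix=".faa", delete=False) as fh:
        write_fasta(records, fh)
        path = fh.name
    out = subprocess.run(
        ["mafft", *args, "--anysymbol", path],
        check=True,
        capture_output=True,
        text=True,
    )
    ids, rows, cur = [], [], []
    for line in out.stdout.splitlines():
        if line.startswith(">"):
            if cur:
                rows.append("".join(cur))
                cur = []
            ids.append(line[1:].split()[0])
        else:
            cur.append(line.strip())
    if cur:
        rows.append("".join(cur))
    order = {r.seq_id: i for i, r in enumerate(records)}
    pairs = sorted(zip(ids, rows), key=lambda p: order[p[0]])
    return Alignment([p[0] for p in pairs], [p[1].upper() for p in pairs])


def alignment_distances(aln: Alignment) -> np.ndarray:
    """Corrected pairwise protein distances from an alignment.

    Per pair, the per-site mismatch fraction p over columns where both rows
    are ungapped, corrected as ``d = -(19/20) ln(1 - (20/19) p)`` and capped
    at 10 substitutions/site near saturation. Pairs with no shared ungapped
    column get the cap, with a warning.
    """
    k = len(aln)
    arr = np.array([list(r) for r in aln.rows])
    gap = arr == "-"
    d = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        shared = ~gap[i] & ~gap[j]
        n_shared = int(shared.sum())
        if n_shared == 0:
            warnings.warn(
                f"{aln.seq_ids[i]} and {aln.seq_ids[j]} share no aligned columns; "
                "distance set to the saturation cap"
            )
            dist = MAX_PROTEIN_DISTANCE
        else:
            p = float((arr[i, shared] != arr[j, shared]).mean())
            x = 1.0 - (20.0 / 19.0) * p
            dist = MAX_PROTEIN_DISTANCE if x <= 1e-9 else min(
                MAX_PROTEIN_DISTANCE, -(19.0 / 20.0) * math.log(x)
            )
        d[i, j] = d[j, i] = dist
    return d


def pairwise_distances(aln: Alignment) -> np.ndarray:
    """Corrected protein distances from direct pairwise alignments.

    Each pair of (ungapped) sequences is re-aligned globally (end gaps
    penalized, so unrelated sequences cannot hide behind a short overlap)
    and the mismatch fraction is taken over columns where both sequences
    have a residue, with the same saturation-capped correction as
    :func:`alignment_distances`. Unlike distances read off a single MSA,
    pairwise distances are insensitive to a poorly chosen alignment anchor
    when a cluster mixes dissimilar sequences, so the tree engine uses
    these.
    """
    k = len(aln)
    seqs = [r.replace("-", "") for r in aln.rows]
    d = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        if seqs[i] == seqs[j]:
            continue
        _, pairs = _pairwise_global(seqs[i], seqs[j], mode="global")
        both = [(ia, ib) for ia, ib in pairs if ia is not None and ib is not None]
        if not both:
            d[i, j] = d[j, i] = MAX_PROTEIN_DISTANCE
            continue
        mism = sum(1 for ia, ib in both if seqs[i][ia] != seqs[j][ib])
        p = mism / len(both)
        x = 1.0 - (20.0 / 19.0) * p
        dist = MAX_PROTEIN_DISTANCE if x <= 1e-9 else min(
            MAX_PROTEIN_DISTANCE, -(19.0 / 20.0) * math.log(x)
        )
        d[i, j] = d[j, i] = dist
    return d


def _ols_branch_lengths(tree: TreeNode, dm: DistanceMatrix) -> None:
    """Second pass: fit non-negative branch lengths to the distance matrix.

    Minimizes the least-squares error between tree path lengths and the
    input distances over all leaf pairs, with lengths constrained >= 0.
    """
    edges = [n for n in tree.traverse(include_self=False)]
    tips = list(tree.tips())
    names = [t.name for t in tips]
    # leaf set below each edge
    below: dict[int, set[str]] = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            below[id(node)] = {node.name}
        else:
            below[id(node)] = set().union(*(below[id(c)] for c in node.children))
    pairs = list(combinations(range(len(tips)), 2))
    A = np.zeros((len(pairs), len(edges)))
    b = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        b[row] = dm[names[i], names[j]]
        for col, e in enumerate(edges):
            s = below[id(e)]
            if (names[i] in s) != (names[j] in s):
                A[row, col] = 1.0
    lengths, _ = nnls(A, b)
    for e, l in zip(edges, lengths):
        e.length = float(l)


def tree_from_distances(d: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Distance-based tree: NJ topology, then non-negative least-squares lengths.

    IDs are processed in sorted order so the result is independent of the
    input ordering.
    """
    d = np.asarray(d, dtype=float)
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    dm = DistanceMatrix(d[np.ix_(order, order)], [ids[i] for i in order])
    tree = nj(dm, neg_as_zero=True)
    _ols_branch_lengths(tree, dm)
    return tree


def infer_tree(aln: Alignment, engine: str = "internal", seed: int = 0) -> TreeNode:
    """Infer an unrooted gene tree over the alignment's sequences.

    The internal engine determines the topology by neighbor joining on
    corrected protein distances and then re-estimates all branch lengths by
    non-negative least squares against the same distances (topology first,
    lengths second). Deterministic for a given alignment.
    """
    if len(aln) < 2:
        raise ValueError("tree inference needs at least 2 sequences")
    if engine != "internal":
        raise ValueError(f"unknown tree engine {engine!r}")
    d = pairwise_distances(aln)
    if len(aln) == 2:
        a, b = aln.seq_ids
        half = d[0, 1] / 2.0
        return read_newick(f"({a}:{half:.10g},{b}:{half:.10g});")
    if not d.any():
        # all rows identical: star tree with zero lengths
        inner = ",".join(f"{s}:0.0" for s in aln.seq_ids)
        return read_newick(f"({inner});")
    return tree_from_distances(d, aln.seq_ids)


def read_newick(text: str) -> TreeNode:
    """Parse a newick string into a tree, with positional error reporting."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise NewickParseError(f"{depth} unclosed '(' in newick string")
    if ";" not in text:
        raise NewickParseError("newick string lacks terminating ';'")
    try:
        return TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises several parser error types
        raise NewickParseError(str(exc)) from exc


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()
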