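"""Protein similarity search.

The default engine is an internal deterministic Smith-Waterman search
(BLOSUM62, affine gaps) whose e-values come from Karlin-Altschul statistics
with standard gapped parameters. An adapter to an external NCBI ``blastp``
binary is available for users who want BLAST numerics; the two engines share
one tabular hit model.

E-values here are comparable and monotone in score, which is all the
downstream screening, clustering, and ranking steps require; reproducing
BLAST's exact numerics (composition-based statistics, SEG masking) is not
attempted.
"""

from __future__ import annotations

import math
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqdata import Dataset, SequenceRecord, write_fasta

__all__ = [
    "SimilarityHit",
    "SimilarityMatrix",
    "EngineUnavailableError",
    "local_align",
    "evalue_from_score",
    "search_one_vs_all",
    "all_vs_all_matrix",
    "NcbiBlastEngine",
    "hits_to_tsv",
]

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1).
KARLIN_K = 0.041
KARLIN_LAMBDA = 0.267

DEFAULT_EVALUE_CUTOFF = 1e-3
FILL_EVALUE = 9e-1  # assigned to all-vs-all pairs with no significant hit
_MIN_EVALUE = 1e-180


class EngineUnavailableError(RuntimeError):
    """An external search engine was requested but its binary is missing."""


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise search result (best alignment per subject)."""

    query_id: str
    subject_id: str
    evalue: float
    percent_identity: float
    alignment_length: int
    score: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must be in [0, 100]")

    @property
    def bitscore(self) -> float:
        return (KARLIN_LAMBDA * self.score - math.log(KARLIN_K)) / math.log(2.0)


class SimilarityMatrix:
    """All-vs-all e-value matrix over an ordered set of sequence IDs.

    Every ordered pair of IDs has a value: a real e-value for significant
    pairs, `fill_value` (default 9e-1) otherwise, so downstream graph
    construction is total.
    """

    def __init__(self, ids: Sequence[str], evalues: np.ndarray, fill_value: float = FILL_EVALUE):
        ids = list(ids)
        evalues = np.asarray(evalues, dtype=float)
        if evalues.shape != (len(ids), len(ids)):
            raise ValueError("evalue matrix shape does not match ids")
        if not np.all(evalues > 0):
            raise ValueError("all e-values must be positive")
        self.ids = ids
        self._index = {s: i for i, s in enumerate(ids)}
        self.evalues = evalues
        self.fill_value = fill_value

    def evalue(self, query_id: str, subject_id: str) -> float:
        return float(self.evalues[self._index[query_id], self._index[subject_id]])

    def __len__(self) -> int:
        return len(self.ids)


@lru_cache(maxsize=8)
def _aligner(mode: str, matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    """Cached aligner; mode is 'local', 'global', or 'semiglobal' (free end gaps)."""
    a = Align.PairwiseAligner()
    a.mode = "global" if mode == "semiglobal" else mode
    a.substitution_matrix = substitution_matrices.load(matrix_name)
    a.open_gap_score = -abs(gap_open)
    a.extend_gap_score = -abs(gap_extend)
    if mode == "semiglobal":
        # free end gaps so length differences are not penalized
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    return a


def _sanitize(residues: str, alphabet: frozenset = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")) -> str:
    s = residues.upper()
    if all(c in alphabet for c in s):
        return s
    return "".join(c if c in alphabet else "X" for c in s)


def local_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[float, int, int]:
    """Optimal Smith-Waterman local alignment of two residue strings.

    Returns ``(raw_score, alignment_length, identities)`` where the length
    counts all alignment columns (including internal gaps). A score of zero
    means no positively scoring local alignment exists; length and
    identities are then zero.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    aligner = _aligner("local", matrix, gap_open, gap_extend)
    a, b = _sanitize(a), _sanitize(b)
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, 0, 0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.internal_gaps
    return float(score), int(length), int(counts.identities)


def evalue_from_score(score: float, query_len: int, db_len: int) -> float:
    """Karlin-Altschul e-value ``K * m * n * exp(-lambda * S)``."""
    e = KARLIN_K * query_len * db_len * math.exp(-KARLIN_LAMBDA * score)
    return max(e, _MIN_EVALUE)


def _internal_hit(query: SequenceRecord, subject: SequenceRecord, db_len: int) -> SimilarityHit | None:
    score, length, ident = local_align(query.residues, subject.residues)
    if length == 0:
        return None
    return SimilarityHit(
        query_id=query.seq_id,
        subject_id=subject.seq_id,
        evalue=evalue_from_score(score, len(query), db_len),
        percent_identity=100.0 * ident / length,
        alignment_length=length,
        score=score,
    )


def search_one_vs_all(
    query: SequenceRecord,
    dataset: Dataset,
    engine: str | "NcbiBlastEngine" = "internal",
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[SimilarityHit]:
    """Search `query` against every dataset sequence.

    Only hits with e-value strictly below `evalue_cutoff` are returned,
    sorted by ascending e-value (subject ID breaking ties), one best hit
    per subject.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    engine_obj = _resolve_engine(engine)
    if engine_obj is not None:
        hits = engine_obj.one_vs_all(query, dataset, evalue_cutoff)
    else:
        db_len = dataset.total_residues()
        hits = []
        for subject in dataset:
            hit = _internal_hit(query, subject, db_len)
            if hit is not None and hit.evalue < evalue_cutoff:
                hits.append(hit)
    hits.sort(key=lambda h: (h.evalue, h.subject_id))
    return hits


def all_vs_all_matrix(
    reduced: Dataset,
    engine: str | "NcbiBlastEngine" = "internal",
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    fill_value: float = FILL_EVALUE,
) -> SimilarityMatrix:
    """All-vs-all search on the reduced dataset.

    Pairs (in either direction) without a significant hit carry
    `fill_value` so every ordered pair has a value. The diagonal carries
    the self-hit e-value. With the internal engine the alignment score of
    a pair is computed once (Smith-Waterman is symmetric) while the two
    directional e-values differ through the query length.
    """
    if len(reduced) == 0:
        raise ValueError("reduced dataset is empty")
    records = list(reduced)
    ids = [r.seq_id for r in records]
    n = len(records)
    ev = np.full((n, n), fill_value, dtype=float)
    engine_obj = _resolve_engine(engine)
    if engine_obj is not None:
        index = {s: i for i, s in enumerate(ids)}
        for rec in records:
            for hit in engine_obj.one_vs_all(rec, reduced, evalue_cutoff):
                ev[index[rec.seq_id], index[hit.subject_id]] = hit.evalue
    else:
        db_len = reduced.total_residues()
        for i in range(n):
            for j in range(i, n):
                score, length, _ = local_align(records[i].residues, records[j].residues)
                if length == 0:
                    continue
                e_ij = evalue_from_score(score, len(records[i]), db_len)
                e_ji = evalue_from_score(score, len(records[j]), db_len)
                if i == j or e_ij < evalue_cutoff:
                    ev[i, j] = e_ij
                if i != j and e_ji < evalue_cutoff:
                    ev[j, i] = e_ji
    return SimilarityMatrix(ids, ev, fill_value=fill_value)


def _resolve_engine(engine):
    """Map an engine choice to an adapter object, or None for internal."""
    if engine is None or engine == "internal":
        return None
    if isinstance(engine, str):
        if engine in ("ncbi-blast", "blastp", "ncbi"):
            return NcbiBlastEngine()
        raise EngineUnavailableError(
            f"unknown engine {engine!r}; use 'internal' or 'ncbi-blast'"
        )
    return engine


class NcbiBlastEngine:
    """Thin adapter around external ``makeblastdb``/``blastp`` binaries.

    Default flags follow the word-size-3 / threshold-11 / Smith-Waterman
    traceback search configuration; database soft masking is not applied
    (it would require a separate masking pass when the database is built).
    """

    def __init__(self, extra_args: Sequence[str] = ("-word_size", "3", "-threshold", "11", "-use_sw_tback")):
        self.extra_args = list(extra_args)

    def _require_binaries(self) -> None:
        for binary in ("makeblastdb", "blastp"):
            if shutil.which(binary) is None:
                raise EngineUnavailableError(
                    f"{binary} not found on PATH; use the internal engine instead"
                )

    def one_vs_all(
        self, query: SequenceRecord, dataset: Dataset, evalue_cutoff: float
    ) -> list[SimilarityHit]:
        self._require_binaries()
        with tempfile.TemporaryDirectory() as tmp:
            db_path = os.path.join(tmp, "db.faa")
            q_path = os.path.join(tmp, "query.faa")
            write_fasta(dataset, db_path)
            write_fasta([query], q_path)
            subprocess.run(
                ["makeblastdb", "-in", db_path, "-dbtype", "prot"],
                check=True,
                capture_output=True,
            )
            out = subprocess.run(
                [
                    "blastp",
                    "-query",
                    q_path,
                    "-db",
                    db_path,
                    "-evalue",
                    str(evalue_cutoff),
                    "-outfmt",
                    "6 qseqid sseqid pident length evalue bitscore",
                    *self.extra_args,
                ],
                check=True,
                capture_output=True,
                text=True,
            )
        best: dict[str, SimilarityHit] = {}
        for line in out.stdout.splitlines():
            q, s, pident, length, evalue, bits = line.split("\t")
            hit = SimilarityHit(
                query_id=q,
                subject_id=s,
                evalue=max(float(evalue), _MIN_EVALUE),
                percent_identity=float(pident),
                alignment_length=int(length),
                score=float(bits),
            )
            prev = best.get(s)
            if prev is None or hit.evalue < prev.evalue:
                best[s] = hit
        return [h for h in best.values() if h.evalue < evalue_cutoff]


def hits_to_tsv(hits: Iterable[SimilarityHit]) -> str:
    """BLAST outfmt-6 compatible TSV (qseqid sseqid pident length evalue bitscore)."""
    lines = [
        "\t".join(
            (
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:.2f}",
                str(h.alignment_length),
                f"{h.evalue:.3g}",
                f"{h.bitscore:.1f}",
            )
        )
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
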