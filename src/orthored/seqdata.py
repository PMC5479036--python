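"""Species-labeled protein sequence datasets: data model, FASTA I/O, CDS translation.

Every sequence in a dataset carries three identities: a unique ``seq_id``
(the FASTA header token), a ``species_id`` extracted from the header by a
pluggable naming rule (default: everything before the first ``|``), and a
``gene_id`` that equals ``seq_id`` unless an isoform map groups several
sequences (splice variants) under one gene.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "SequenceRecord",
    "Dataset",
    "DatasetError",
    "FastaParseError",
    "UniquenessError",
    "UnknownIdError",
    "default_species_parser",
    "regex_species_parser",
    "load_dataset",
    "read_isoform_map",
    "write_fasta",
    "translate_cds",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class DatasetError(Exception):
    """Base class for dataset construction errors."""


class FastaParseError(DatasetError):
    """A FASTA file could not be parsed."""


class UniquenessError(DatasetError):
    """A sequence ID appeared more than once."""


class UnknownIdError(DatasetError):
    """A reference to a sequence ID that is not in the dataset."""


@dataclass
class SequenceRecord:
    """One amino-acid sequence with species, gene, and isoform identity."""

    seq_id: str
    species_id: str
    residues: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise DatasetError("seq_id must be non-empty")
        if not self.species_id:
            raise DatasetError(f"{self.seq_id}: species_id must be non-empty")
        if not self.residues:
            raise DatasetError(f"{self.seq_id}: residues must be non-empty")
        self.residues = self.residues.upper()
        if not self.gene_id:
            self.gene_id = self.seq_id

    def __len__(self) -> int:
        return len(self.residues)


def default_species_parser(header: str) -> str:
    """``SPECIES|SEQID`` convention: species is the part before the first ``|``."""
    token = header.split()[0]
    return token.split("|")[0]


def regex_species_parser(pattern: str) -> Callable[[str], str]:
    """Build a naming rule extracting group 1 of `pattern` from the header."""
    rx = re.compile(pattern)

    def parse(header: str) -> str:
        m = rx.search(header)
        if m is None or not m.group(1):
            raise FastaParseError(f"header {header!r} does not match species pattern {pattern!r}")
        return m.group(1)

    return parse


class Dataset:
    """An ordered collection of :class:`SequenceRecord` with optional
    outgroup species and isoform map.

    The isoform map sends each ``gene_id`` to the set of its isoform
    ``seq_id``s; isoform groups must be disjoint and reference known IDs.
    """

    def __init__(
        self,
        records: Iterable[SequenceRecord],
        outgroup_species: str | None = None,
        isoform_map: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        self._records: dict[str, SequenceRecord] = {}
        for rec in records:
            if rec.seq_id in self._records:
                raise UniquenessError(f"duplicate seq_id {rec.seq_id!r}")
            self._records[rec.seq_id] = rec
        self.outgroup_species = outgroup_species
        self.isoform_map: dict[str, frozenset[str]] = {}
        if isoform_map:
            seen: set[str] = set()
            for gene, seq_ids in isoform_map.items():
                group = frozenset(seq_ids)
                for sid in group:
                    if sid not in self._records:
                        raise UnknownIdError(f"isoform map references unknown seq_id {sid!r}")
                    if sid in seen:
                        raise DatasetError(f"seq_id {sid!r} appears in two isoform groups")
                    seen.add(sid)
                    self._records[sid].gene_id = gene
                self.isoform_map[gene] = group
        if outgroup_species is not None and not any(
            r.species_id == outgroup_species for r in self._records.values()
        ):
            raise DatasetError(f"no record carries outgroup species {outgroup_species!r}")

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records.values())

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._records

    @property
    def seq_ids(self) -> list[str]:
        return list(self._records)

    def get(self, seq_id: str) -> SequenceRecord:
        try:
            return self._records[seq_id]
        except KeyError:
            raise UnknownIdError(f"unknown seq_id {seq_id!r}") from None

    def species_of(self, seq_id: str) -> str:
        return self.get(seq_id).species_id

    def gene_of(self, seq_id: str) -> str:
        return self.get(seq_id).gene_id

    def isoforms_of(self, gene_id: str) -> frozenset[str]:
        """All seq_ids of a gene (the gene's own seq_id if unmapped)."""
        return self.isoform_map.get(gene_id, frozenset({gene_id}))

    def species_of_gene(self, gene_id: str) -> str:
        """Species of a gene: the species of any of its isoform sequences."""
        if gene_id in self._records:
            return self._records[gene_id].species_id
        for sid in self.isoforms_of(gene_id):
            if sid in self._records:
                return self._records[sid].species_id
        raise UnknownIdError(f"unknown gene_id {gene_id!r}")

    def species(self) -> set[str]:
        return {r.species_id for r in self}

    def total_residues(self) -> int:
        return sum(len(r) for r in self)

    def subset(self, seq_ids: Iterable[str]) -> "Dataset":
        """A new dataset restricted to `seq_ids` (isoform map restricted too)."""
        wanted = set(seq_ids)
        recs = [self._records[s] for s in self._records if s in wanted]
        iso = {
            g: group & wanted
            for g, group in self.isoform_map.items()
            if group & wanted
        }
        out = self.outgroup_species
        if out is not None and not any(r.species_id == out for r in recs):
            out = None
        return Dataset(recs, outgroup_species=out, isoform_map=iso)


def _check_fasta_shape(path: str) -> None:
    """Reject files whose first content line is not a FASTA header."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected FASTA header line, got {stripped[:30]!r}"
                )
            return
    raise FastaParseError(f"{path}: empty file")


def load_dataset(
    fasta_paths: Sequence[str | os.PathLike],
    species_parser: Callable[[str], str] = default_species_parser,
    isoform_map_path: str | os.PathLike | None = None,
    outgroup: str | None = None,
) -> Dataset:
    """Read one or more protein FASTA files into a :class:`Dataset`.

    Each header's first whitespace-separated token becomes the ``seq_id``;
    `species_parser` maps the header to the species label. Duplicate IDs
    across files are rejected.
    """
    records: list[SequenceRecord] = []
    for path in fasta_paths:
        path = os.fspath(path)
        if not os.path.exists(path):
            raise FastaParseError(f"{path}: no such file")
        _check_fasta_shape(path)
        for entry in SeqIO.parse(path, "fasta"):
            header = entry.description or entry.id
            seq = str(entry.seq)
            if not seq:
                raise FastaParseError(f"{path}: record {entry.id!r} has an empty sequence")
            records.append(
                SequenceRecord(
                    seq_id=entry.id,
                    species_id=species_parser(header),
                    residues=seq,
                )
            )
    isoform_map = read_isoform_map(isoform_map_path) if isoform_map_path else None
    return Dataset(records, outgroup_species=outgroup, isoform_map=isoform_map)


def read_isoform_map(path: str | os.PathLike) -> dict[str, set[str]]:
    """Parse a tab-separated ``gene_id<TAB>seq_id`` file into a map."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DatasetError(f"{path}:{lineno}: expected 'gene<TAB>seq_id'")
            gene, sid = parts
            mapping.setdefault(gene, set()).add(sid)
    return mapping


def write_fasta(dataset: Dataset | Iterable[SequenceRecord], path_or_handle, width: int = 60) -> None:
    """Write records as FASTA, one header token per record (the seq_id)."""
    own = isinstance(path_or_handle, (str, os.PathLike))
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        for rec in dataset:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
    finally:
        if own:
            fh.close()


_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


def _translate_codon(codon: str) -> str | None:
    """One codon to one residue; None for a stop; 'X' for ambiguity."""
    if codon in _STOP_CODONS:
        return None
    return _CODON_TABLE.get(codon, "X")


def translate_cds(
    nucleotide_records: Iterable[SequenceRecord],
    max_x_fraction: float = 0.5,
) -> tuple[Dataset, list[tuple[str, str]]]:
    """Translate coding sequences (frame 1, standard code) into a protein dataset.

    A sequence is rejected (returned in the second element with a reason)
    when its gap-stripped length is not a multiple of three ("ambiguous
    reading frame"), when a stop codon occurs before the final codon
    ("premature stop codon"), or when more than `max_x_fraction` of the
    translated residues are ambiguous ('X'). A single trailing stop codon
    is stripped; codons containing N translate to X. Not starting with a
    start codon is *not* a rejection criterion.
    """
    kept: list[SequenceRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in nucleotide_records:
        nt = rec.residues.upper().replace("-", "")
        if len(nt) % 3 != 0:
            rejected.append((rec.seq_id, "ambiguous reading frame (length not a multiple of 3)"))
            continue
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        protein: list[str] = []
        bad = None
        for idx, codon in enumerate(codons):
            aa = _translate_codon(codon)
            if aa is None:
                if idx == len(codons) - 1:
                    break  # trailing stop stripped
                bad = "premature stop codon"
                break
            protein.append(aa)
        if bad is None and not protein:
            bad = "translates to an empty protein"
        if bad is None and protein.count("X") / len(protein) > max_x_fraction:
            bad = "too many ambiguous residues"
        if bad is not None:
            rejected.append((rec.seq_id, bad))
            continue
        kept.append(
            SequenceRecord(
                seq_id=rec.seq_id,
                species_id=rec.species_id,
                residues="".join(protein),
                gene_id=rec.gene_id,
            )
        )
    return Dataset(kept), rejected
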