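"""Sequence data model, FASTA I/O, and the packaged decarboxylase catalog.

The central objects are :class:`SequenceRecord` (one protein sequence with an
optional TDC/TYDC class label) and :class:`SequenceSet` (an id-unique
collection).  The module also ships, as package data, the catalog of 42 plant
aromatic L-amino-acid decarboxylase accessions (14 TDC from 10 species, 28
TYDC from 13 species) that the signature analysis was derived from.

Class labels travel through FASTA headers as a ``class=<LABEL>`` token in the
description; FASTA itself has no metadata slot, so this is a documented
convention of this package, not a standard.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: ``X`` is tolerated as a database ambiguity code; ``-`` appears in aligned rows.
ALPHABET = frozenset(AMINO_ACIDS) | {"X"}
GAP = "-"

TDC = "TDC"
TYDC = "TYDC"
UNKNOWN = "UNKNOWN"
CLASS_LABELS = (TDC, TYDC, UNKNOWN)


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside the amino-acid alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with an optional decarboxylase class label.

    ``residues`` is an uppercase string over the 20 standard amino acids plus
    ``X``; aligned records may additionally contain the gap character ``-``.
    """

    id: str
    residues: str
    description: str = ""
    class_label: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"record {self.id!r}: class_label must be one of {CLASS_LABELS}"
            )
        allowed = ALPHABET | {GAP}
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise SequenceValidationError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def degapped(self) -> "SequenceRecord":
        if GAP not in self.residues:
            return self
        return replace(self, residues=self.ungapped)


class SequenceSet:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    def __init__(self, records: Iterable[SequenceRecord] = ()) -> None:
        self._records: list[SequenceRecord] = []
        self._index: dict[str, int] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SequenceRecord) -> None:
        if rec.id in self._index:
            raise ValueError(f"duplicate record id {rec.id!r}")
        self._index[rec.id] = len(self._records)
        self._records.append(rec)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records)

    def __getitem__(self, key: int | str) -> SequenceRecord:
        if isinstance(key, str):
            return self._records[self._index[key]]
        return self._records[key]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self._records]


def _split_class_token(description: str) -> tuple[str, str]:
    """Extract the ``class=`` token from a description; returns (rest, label)."""
    label = UNKNOWN
    kept: list[str] = []
    for token in description.split():
        if token.startswith("class="):
            value = token[len("class="):].upper()
            if value in CLASS_LABELS:
                label = value
                continue
        kept.append(token)
    return " ".join(kept), label


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a (possibly aligned) protein FASTA file into a :class:`SequenceSet`.

    A ``class=TDC`` / ``class=TYDC`` header token sets the record's class
    label; anything else yields ``UNKNOWN``.  An empty file yields an empty
    set.  Sequence data before the first header is a parse error.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
    records = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        desc, label = _split_class_token(desc)
        records.add(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                description=desc,
                class_label=label,
            )
        )
    return records


def write_fasta(records: SequenceSet | Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, re-encoding class labels as ``class=`` tokens."""
    out = []
    for rec in records:
        desc = rec.description
        if rec.class_label != UNKNOWN:
            desc = f"{desc} class={rec.class_label}".strip()
        out.append(SeqRecord(Seq(rec.residues), id=rec.id, description=desc))
    with open(path, "w") as handle:
        SeqIO.write(out, handle, "fasta")


def percent_identity(a: str, b: str) -> float:
    """Percent identity between two equal-length (possibly gapped) strings.

    The denominator is the number of columns where at least one string has a
    non-gap character; columns where both are gaps are skipped.  ``X`` never
    counts as a match.  Returned rounded to two decimals, as identities are
    conventionally reported.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    scored = 0
    same = 0
    for ca, cb in zip(a, b):
        if ca == GAP and cb == GAP:
            continue
        scored += 1
        if ca == cb and ca != GAP and ca != "X":
            same += 1
    if scored == 0:
        raise ValueError("no scored columns (both strings all gaps)")
    return round(100.0 * same / scored, 2)


@dataclass(frozen=True)
class CatalogEntry:
    """One accession from the packaged plant TDC/TYDC catalog."""

    species: str
    accession: str
    class_label: str


def load_catalog() -> list[CatalogEntry]:
    """Load the packaged catalog of 42 plant TDC/TYDC accessions.

    The catalog records, per accession, the source species and the database
    annotation (14 TDC entries across 10 species, 28 TYDC across 13).
    """
    text = (
        importlib.resources.files("tdckit.data").joinpath("catalog.tsv").read_text()
    )
    entries: list[CatalogEntry] = []
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    assert header == ["species", "accession", "class"], "catalog fixture corrupt"
    for line in lines[1:]:
        species, accession, label = line.split("\t")
        entries.append(CatalogEntry(species=species, accession=accession, class_label=label))
    return entries


def orf_protein_length(cds_start_nt: int, cds_end_nt: int) -> int:
    """Number of residues encoded by an ORF spanning transcript coordinates.

    ``cds_start_nt``..``cds_end_nt`` are 1-based inclusive nucleotide positions
    covering the full ORF including the stop codon.  For example an ORF from
    nt 70 to nt 1572 spans 1503 nt = 501 codons, whose last codon is the stop,
    encoding a 500-residue protein.
    """
    span = cds_end_nt - cds_start_nt + 1
    if span <= 0 or span % 3 != 0:
        raise ValueError(f"ORF span {span} nt is not a positive multiple of 3")
    return span // 3 - 1
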