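"""Sequence records, FASTA input/output and coding-sequence translation.

Every downstream analysis in this package operates on :class:`ProteinRecord`
objects (plain one-letter residue strings over the 20 standard amino acids).
This module reads and writes multi-record FASTA, validates alphabets, and
translates a cloned cDNA into the protein it encodes so that a transcript
sequence is all a user needs to start a characterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_ALPHABET = frozenset("ACGT")

#: Codon -> one-letter residue, standard genetic code.
_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)


class AlphabetError(ValueError):
    """A sequence contains a character outside the permitted alphabet."""


class NoStartCodonError(ValueError):
    """No ATG found at or after the requested frame offset."""


class NoStopCodonWarning(UserWarning):
    """Translation ran off the end of the transcript without hitting a stop.

    The full read-through product is still returned; the warning flags that
    the open reading frame is not terminated within the given sequence.
    """


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier and free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NucleotideRecord:
    """A DNA sequence (U is folded to T on construction by readers)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"nucleotide record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """An ordered collection of protein records with unique identifiers."""

    records: list[ProteinRecord]
    source_tag: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in proteome: {dupes}")

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _validate(seq: str, alphabet: frozenset[str], rec_id: str,
              on_illegal: Literal["error", "mask"]) -> str:
    bad = next(((i, c) for i, c in enumerate(seq) if c not in alphabet), None)
    if bad is None:
        return seq
    if on_illegal == "error":
        raise AlphabetError(
            f"record {rec_id!r}: illegal character {bad[1]!r} at position {bad[0]}"
        )
    # permissive mode: mask every illegal character as X (protein) / N (DNA)
    mask = "X" if alphabet is PROTEIN_ALPHABET else "N"
    return "".join(c if c in alphabet else mask for c in seq)


def read_fasta(path: str | Path, *, alphabet: Literal["protein", "nucleotide"] = "protein",
               on_illegal: Literal["error", "mask"] = "error",
               ) -> list[ProteinRecord] | list[NucleotideRecord]:
    """Read a multi-record FASTA file.

    Headers are split at the first whitespace into id and description; wrapped
    sequence lines are joined, whitespace stripped, and residues uppercased.
    ``on_illegal`` selects strict mode (default: raise :class:`AlphabetError`
    naming the record and offending position) or permissive masking to X/N.
    """
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise ValueError(f"{path}: no FASTA records found")
    out: list = []
    for rec in raw:
        seq = str(rec.seq).upper().replace(" ", "")
        if alphabet == "nucleotide":
            seq = seq.replace("U", "T")
            out.append(NucleotideRecord(rec.id, _validate(seq, NUCLEOTIDE_ALPHABET,
                                                          rec.id, on_illegal),
                                        _description(rec)))
        else:
            out.append(ProteinRecord(rec.id, _validate(seq, PROTEIN_ALPHABET,
                                                       rec.id, on_illegal),
                                     _description(rec)))
    return out


def _description(rec: SeqRecord) -> str:
    desc = rec.description
    if desc.startswith(rec.id):
        desc = desc[len(rec.id):].strip()
    return desc


def write_fasta(records: Iterable[ProteinRecord | NucleotideRecord],
                path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width`` columns."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def translate_cds(cdna: NucleotideRecord, frame: int = 0, *,
                  start_offset: int | None = None) -> ProteinRecord:
    """Translate a cDNA into the protein its open reading frame encodes.

    Translation begins at the first ATG at or after the frame offset (or at
    an explicit ``start_offset`` for non-ATG-initiated frames) and stops at,
    and excludes, the first in-frame stop codon.  A trailing partial codon is
    ignored.  If no in-frame stop is found a :class:`NoStopCodonWarning` is
    emitted and the full read-through product returned.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = cdna.sequence
    if len(seq) - frame < 3:
        raise ValueError("sequence shorter than one codon after frame offset")
    illegal = set(seq) - NUCLEOTIDE_ALPHABET
    if illegal:
        raise AlphabetError(
            f"record {cdna.id!r}: ambiguous or illegal bases {sorted(illegal)}"
        )
    if start_offset is None:
        # the first ATG at/after the offset anchors the reading frame
        start = seq.find("ATG", frame)
        if start == -1:
            raise NoStartCodonError(f"record {cdna.id!r}: no ATG at/after offset {frame}")
    else:
        start = start_offset
    residues: list[str] = []
    stopped = False
    for i in range(start, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if codon in _STOP_CODONS:
            stopped = True
            break
        residues.append(_CODON_TABLE[codon])
    if not stopped:
        warnings.warn(
            f"record {cdna.id!r}: no in-frame stop codon; returning read-through product",
            NoStopCodonWarning,
            stacklevel=2,
        )
    if not residues:
        raise ValueError(f"record {cdna.id!r}: empty translation product")
    return ProteinRecord(cdna.id, "".join(residues),
                         (cdna.description + " [translated]").strip())
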