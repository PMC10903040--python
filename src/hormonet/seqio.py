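"""Protein sequence input, validation and filtering.

Sequences enter the pipeline as FASTA. Before encoding, the inclusion
rules applied when the benchmark datasets were curated are enforced:
sequences shorter than 50 residues or containing ambiguity codes
(``X`` and, by default, the other non-canonical letters) are dropped
with a machine-readable reason.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino-acid one-letter codes, alphabetical.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Letters rejected by default: the ambiguity/non-canonical codes whose
#: physicochemical property values are undefined in the 20-residue scales.
DEFAULT_FORBIDDEN = frozenset("XBZUO*")


class FastaParseError(ValueError):
    """Raised when a FASTA file is empty or malformed."""


class DuplicateIdError(ValueError):
    """Raised when one id maps to two different sequences."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein chain: an id plus an uppercase residue string."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def is_canonical(self) -> bool:
        return all(c in CANONICAL_AA for c in self.sequence)


@dataclass(frozen=True)
class DroppedRecord:
    """A filtered-out record together with the rule that removed it."""

    record: ProteinRecord
    reason: str


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, in file order.

    Sequences are uppercased.  Duplicate ids with identical sequences are
    deduplicated (first occurrence kept); conflicting sequences under one
    id raise :class:`DuplicateIdError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, str] = {}
    with open(path) as handle:
        first = handle.read(1)
        if not first:
            raise FastaParseError(f"{path}: empty file")
        if first != ">":
            raise FastaParseError(f"{path}: line 1 does not start with '>'")
        handle.seek(0)
        for bio in _BioSeqIO.parse(handle, "fasta"):
            seq = str(bio.seq).upper()
            if not seq:
                raise FastaParseError(f"{path}: entry {bio.id!r} has no sequence")
            if bio.id in seen:
                if seen[bio.id] != seq:
                    raise DuplicateIdError(
                        f"{path}: id {bio.id!r} occurs with two different sequences"
                    )
                continue
            seen[bio.id] = seq
            records.append(
                ProteinRecord(id=bio.id, sequence=seq, description=bio.description)
            )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (inverse of :func:`read_fasta`)."""
    bio_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        _BioSeqIO.write(bio_records, handle, "fasta")


def filter_sequences(
    records: Iterable[ProteinRecord],
    min_len: int = 50,
    forbidden: frozenset[str] | set[str] = DEFAULT_FORBIDDEN,
) -> tuple[list[ProteinRecord], list[DroppedRecord]]:
    """Partition records into (kept, dropped-with-reason).

    A record is kept iff its length is >= ``min_len`` (strict "smaller
    than" reading: length exactly ``min_len`` is kept) and it contains
    none of the ``forbidden`` letters.  Length is checked first, so a
    short sequence with a forbidden residue reports ``too_short``.
    """
    forbidden = frozenset(c.upper() for c in forbidden)
    kept: list[ProteinRecord] = []
    dropped: list[DroppedRecord] = []
    for rec in records:
        if len(rec) < min_len:
            dropped.append(DroppedRecord(rec, "too_short"))
        elif any(c in forbidden for c in rec.sequence):
            dropped.append(DroppedRecord(rec, "forbidden_residue"))
        else:
            kept.append(rec)
    return kept, dropped


def write_dropped_report(dropped: Iterable[DroppedRecord], path: str | Path) -> None:
    """TSV report of filtered-out records: columns id, reason."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["id", "reason"])
        for d in dropped:
            writer.writerow([d.record.id, d.reason])
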