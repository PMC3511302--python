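"""Reading and writing the standard formats (FASTA, FASTQ) via Biopython."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class ReadRecord:
    """One sequencing read: id, sequence and per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.qualities and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    @property
    def mean_quality(self) -> float:
        if not self.qualities:
            return 0.0
        return sum(self.qualities) / len(self.qualities)


def read_fastq(path: str | os.PathLike) -> list[ReadRecord]:
    """Parse a Phred+33 FASTQ file into ReadRecords.

    Raises ValueError with the failing record index on malformed input.
    """
    reads: list[ReadRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            reads.append(
                ReadRecord(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ at record {len(reads)}: {exc}") from exc
    return reads


def write_fastq(path: str | os.PathLike, reads: Iterable[ReadRecord]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def iter_fasta(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()


def write_fasta(path: str | os.PathLike, entries: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in entries),
        str(path),
        "fasta",
    )
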