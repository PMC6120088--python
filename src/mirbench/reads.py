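"""Read sets and FASTQ input/output.

A :class:`ReadSet` stores single-end reads column-wise (parallel lists of
ids, sequences and quality strings) so that multi-million-read simulated
libraries stay cheap to hold and to subsample.  Records are exposed as
named tuples for ergonomic iteration.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from .errors import InvalidArgumentError


class ReadRecord(NamedTuple):
    read_id: str
    sequence: str
    quality: str


@dataclass
class ReadSet:
    ids: list[str] = field(default_factory=list)
    sequences: list[str] = field(default_factory=list)
    qualities: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.sequences) == len(self.qualities)):
            raise InvalidArgumentError("ReadSet columns must have equal length")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[ReadRecord]:
        return map(ReadRecord, self.ids, self.sequences, self.qualities)

    def __getitem__(self, i: int) -> ReadRecord:
        return ReadRecord(self.ids[i], self.sequences[i], self.qualities[i])

    def append(self, read_id: str, sequence: str, quality: str) -> None:
        if len(quality) != len(sequence):
            raise InvalidArgumentError(
                f"{read_id}: quality length {len(quality)} != "
                f"sequence length {len(sequence)}"
            )
        self.ids.append(read_id)
        self.sequences.append(sequence)
        self.qualities.append(quality)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "ReadSet":
        rs = cls()
        for rid, seq, qual in records:
            rs.append(rid, seq, qual)
        return rs

    def select(self, indices: Iterable[int]) -> "ReadSet":
        """New ReadSet holding the records at ``indices`` (in given order)."""
        idx = list(indices)
        return ReadSet(
            [self.ids[i] for i in idx],
            [self.sequences[i] for i in idx],
            [self.qualities[i] for i in idx],
        )


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    """Write standard 4-line FASTQ; gzip if the path ends in .gz."""
    with _open_text(path, "w") as fh:
        for rid, seq, qual in zip(reads.ids, reads.sequences, reads.qualities):
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> ReadSet:
    """Read FASTQ (plain or gzip) into a ReadSet."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    rs = ReadSet()
    with _open_text(path, "r") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            rs.append(title.split()[0], seq, qual)
    return rs
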