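"""Sequencing-read containers and FASTQ I/O.

A :class:`ReadRecord` is the unit that flows through every analysis stage:
an identifier, its bases over ``{A, C, G, T, N}``, and per-base Phred
quality scores. FASTQ files (Sanger/Phred+33 encoding, optionally gzipped)
are parsed with Biopython's fast FASTQ iterator; malformed records raise
:class:`FastqParseError` carrying the zero-based record index.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqParseError(ValueError):
    """A FASTQ record could not be parsed; ``record_index`` is zero-based."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


@dataclass
class ReadRecord:
    """One sequencing read.

    Parameters
    ----------
    read_id:
        Identifier (FASTA/FASTQ title line without the leading ``@``).
    bases:
        DNA string over ``{A, C, G, T, N}``.
    qualities:
        Per-base Phred scores; must match ``bases`` in length.
    """

    read_id: str
    bases: str
    qualities: Sequence[int] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.qualities:
            # convenience default for tests / constructed reads
            self.qualities = tuple([30] * len(self.bases))
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, stop: int) -> "ReadRecord":
        return ReadRecord(
            self.read_id, self.bases[start:stop], tuple(self.qualities[start:stop])
        )

    def reverse_complement(self) -> "ReadRecord":
        return ReadRecord(
            self.read_id,
            reverse_complement(self.bases),
            tuple(reversed(self.qualities)),
        )

    def quality_string(self) -> str:
        return "".join(chr(q + PHRED_OFFSET) for q in self.qualities)


PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: PathLike) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` objects from a FASTQ(.gz) file in order.

    Raises
    ------
    FastqParseError
        If a record is malformed (missing ``+`` line, truncated record, or
        sequence/quality length mismatch), naming the failing record index.
    """
    with _open_text(path, "r") as handle:
        index = 0
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(str(exc), index) from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"sequence length {len(seq)} != quality length {len(qual)}", index
                )
            yield ReadRecord(
                title.split()[0] if title else f"read{index}",
                seq.upper(),
                tuple(ord(c) - PHRED_OFFSET for c in qual),
            )
            index += 1


def write_fastq(reads: Iterable[ReadRecord], path: PathLike) -> int:
    """Write reads as Sanger-encoded FASTQ (gzipped if path ends in .gz).

    Returns the number of records written.
    """
    n = 0
    with _open_text(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{read.quality_string()}\n")
            n += 1
    return n
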