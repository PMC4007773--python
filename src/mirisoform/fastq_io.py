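"""FASTQ input/output.

The only module that touches raw sequence files. Reads and writes 4-line
FASTQ, plain or gzip-compressed, with Phred+33 quality encoding. Sequences
are canonicalized to the uppercase DNA alphabet at ingest (lowercase raised,
U converted to T) so every downstream comparison happens in one alphabet.

Phred+64 input is *not* auto-detected and will fail loudly downstream
(qualities decode to implausible values); silently guessing the offset is a
corruption risk we refuse to take.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
_VALID_BASES = frozenset("ACGTN")
_CANONICAL = str.maketrans("acgtunU", "ACGTTNT")

PathLike = Union[str, Path]


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ records; message names the record index."""


@dataclass(frozen=True)
class Read:
    """One sequencing read: identifier, DNA sequence and per-base Phred scores.

    Invariants: ``len(sequence) == len(qualities)`` and the sequence is drawn
    from the uppercase alphabet {A, C, G, T, N}.
    """

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if not _VALID_BASES.issuperset(self.sequence):
            bad = set(self.sequence) - _VALID_BASES
            raise ValueError(
                f"read {self.read_id!r}: invalid bases {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def decode_qualities(quality_string: str) -> tuple[int, ...]:
    """Decode a Phred+33 quality string to integer scores."""
    return tuple(ord(c) - PHRED_OFFSET for c in quality_string)


def encode_qualities(qualities: Iterable[int]) -> str:
    """Encode integer Phred scores as a Phred+33 string."""
    return "".join(chr(q + PHRED_OFFSET) for q in qualities)


def _is_gzip(path: Path) -> bool:
    if path.suffix == ".gz":
        return True
    try:
        with open(path, "rb") as fh:
            return fh.read(2) == b"\x1f\x8b"
    except OSError:
        return False


def _open_text(path: Path, mode: str) -> IO[str]:
    if "r" in mode:
        if _is_gzip(path):
            return gzip.open(path, "rt")
        return open(path, "r")
    if path.suffix == ".gz":
        return _GzipTextWriter(path)
    return open(path, mode)


class _GzipTextWriter(io.TextIOWrapper):
    """Gzip text writer with mtime pinned to 0 so identical content gives
    byte-identical files."""

    def __init__(self, path: Path):
        self._raw = open(path, "wb")
        gz = gzip.GzipFile(filename="", mode="wb", fileobj=self._raw,
                           compresslevel=4, mtime=0)
        super().__init__(gz, encoding="ascii")

    def close(self) -> None:
        try:
            super().close()
        finally:
            if not self._raw.closed:
                self._raw.close()


def canonicalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T."""
    return seq.translate(_CANONICAL)


def read_fastq(path: PathLike) -> Iterator[Read]:
    """Yield :class:`Read` records from a FASTQ file in file order.

    Gzip is detected by magic bytes or a ``.gz`` suffix. Malformed records
    (missing ``@`` header, sequence/quality length mismatch) raise
    :class:`FastqFormatError` naming the 0-based record index.
    """
    path = Path(path)
    index = 0
    with _open_text(path, "r") as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"{path}: malformed FASTQ at record index {index}: {exc}"
                ) from exc
            seq = canonicalize_sequence(seq)
            try:
                yield Read(title, seq, decode_qualities(qual))
            except ValueError as exc:
                raise FastqFormatError(
                    f"{path}: invalid record at index {index}: {exc}"
                ) from exc
            index += 1


def write_fastq(reads: Iterable[Read], path: PathLike) -> int:
    """Write reads as 4-line Phred+33 FASTQ; gzip if path ends in ``.gz``.

    Returns the number of records written. Round-trips with
    :func:`read_fastq`: ``list(read_fastq(p)) == reads`` for valid input.
    """
    path = Path(path)
    n = 0
    with _open_text(path, "w") as handle:
        for read in reads:
            handle.write(
                f"@{read.read_id}\n{read.sequence}\n+\n"
                f"{encode_qualities(read.qualities)}\n"
            )
            n += 1
    return n
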