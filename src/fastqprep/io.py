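"""Streaming FASTQ/FASTA input and output with explicit quality encodings.

FASTQ records are strictly four lines: ``@header``, sequence, ``+``
(optionally repeating the header), and one quality character per base.
Wrapped (multi-line) FASTQ is rejected. Quality characters map to integer
Phred scores by subtracting a fixed ASCII offset -- 33 for Sanger/modern
Illumina, 64 for legacy Illumina pipelines. Parsing is lazy: records are
yielded one at a time so arbitrarily large files are processed in constant
memory.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

Source = Union[str, Path, IO[str]]

#: Highest Phred score representable in printable ASCII (126 - offset).
MAX_PHRED = {"sanger": 93, "illumina": 62}


class FastqParseError(ValueError):
    """A structurally malformed FASTQ record; carries the 1-based record index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


class EncodingError(ValueError):
    """A quality character outside the active encoding's valid range."""


@dataclass(frozen=True)
class QualityEncoding:
    """Named ASCII-offset scheme mapping quality characters to Phred scores."""

    name: str
    offset: int

    @classmethod
    def from_name(cls, name: str) -> "QualityEncoding":
        try:
            return _ENCODINGS[name.lower()]
        except KeyError:
            raise ValueError(
                f"unknown quality encoding {name!r}; expected 'sanger' or 'illumina'"
            ) from None

    def decode_char(self, ch: str) -> int:
        """Phred score of a single quality character."""
        q = ord(ch) - self.offset
        if q < 0:
            other = "illumina" if self.name == "sanger" else "sanger"
            raise EncodingError(
                f"quality character {ch!r} (ASCII {ord(ch)}) is below the "
                f"{self.name} offset {self.offset}; the file may use the "
                f"{other} encoding"
            )
        return q

    def decode(self, quality: str) -> list[int]:
        return [self.decode_char(ch) for ch in quality]

    def encode(self, scores: Iterable[int]) -> str:
        """Quality string for integer Phred scores (inverse of :meth:`decode`)."""
        chars = []
        hi = MAX_PHRED[self.name]
        for q in scores:
            if not 0 <= q <= hi:
                raise EncodingError(
                    f"Phred score {q} outside [0, {hi}] for {self.name} encoding"
                )
            chars.append(chr(q + self.offset))
        return "".join(chars)


SANGER = QualityEncoding("sanger", 33)
ILLUMINA = QualityEncoding("illumina", 64)
_ENCODINGS = {"sanger": SANGER, "illumina": ILLUMINA}


@dataclass(frozen=True)
class FastqRecord:
    """One four-line FASTQ entry.

    ``header`` and ``plus_line`` hold the text after the leading ``@`` / ``+``
    marker; ``plus_line`` is preserved verbatim so output can round-trip
    byte-for-byte. Sequence and quality are equal-length strings.
    """

    header: str
    sequence: str
    quality: str
    plus_line: str = ""

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"sequence length {len(self.sequence)} != quality length "
                f"{len(self.quality)} for read {self.header!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_seq(self, sequence: str, quality: str) -> "FastqRecord":
        return replace(self, sequence=sequence, quality=quality)


def _open_text(source: Source, mode: str = "rt") -> tuple[IO[str], bool]:
    """Open a path (gzip-aware via the .gz extension) or pass a stream through."""
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.suffix == ".gz":
            return gzip.open(p, mode, encoding="ascii"), True
        return open(p, mode, encoding="ascii", newline=""), True
    return source, False


def read_fastq(source: Source, encoding: QualityEncoding = SANGER) -> Iterator[FastqRecord]:
    """Lazily parse four-line FASTQ records from a path or text stream.

    Records are validated as they are yielded: the ``@``/``+`` markers must be
    present, sequence and quality must have equal length, the sequence must be
    non-empty, and every quality character must decode to a non-negative Phred
    score under *encoding*. Errors name the 1-based record index.

    Raises
    ------
    FastqParseError
        On a malformed or truncated record.
    EncodingError
        On a quality character below the encoding's offset (the message
        suggests the other encoding).
    """
    stream, owned = _open_text(source)
    try:
        idx = 0
        it = iter(stream)
        while True:
            head = next(it, None)
            if head is None:
                return
            head = head.rstrip("\r\n")
            if head == "" :
                # tolerate a trailing blank line at EOF only
                if next(it, None) is None:
                    return
                idx += 1
                raise FastqParseError("blank line where '@' header expected", idx)
            idx += 1
            if not head.startswith("@"):
                raise FastqParseError(
                    f"header line does not start with '@': {head[:30]!r}", idx
                )
            lines = []
            for what in ("sequence", "'+' separator", "quality"):
                line = next(it, None)
                if line is None:
                    raise FastqParseError(f"truncated record: missing {what} line", idx)
                lines.append(line.rstrip("\r\n"))
            seq, plus, qual = lines
            if not plus.startswith("+"):
                raise FastqParseError(
                    f"third line does not start with '+': {plus[:30]!r}", idx
                )
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"sequence length {len(seq)} != quality length {len(qual)}", idx
                )
            if not seq:
                raise FastqParseError("empty sequence", idx)
            for ch in qual:
                q = ord(ch) - encoding.offset
                if q < 0:
                    other = "illumina" if encoding.name == "sanger" else "sanger"
                    raise EncodingError(
                        f"record {idx}: quality character {ch!r} (ASCII {ord(ch)}) "
                        f"is below the {encoding.name} offset {encoding.offset}; "
                        f"the file may use the {other} encoding"
                    )
            yield FastqRecord(header=head[1:], sequence=seq, quality=qual, plus_line=plus[1:])
    finally:
        if owned:
            stream.close()


def write_fastq(records: Iterable[FastqRecord], sink: Source) -> int:
    """Write records as four-line FASTQ; returns the number written.

    Output uses UNIX newlines and preserves each record's ``plus_line``
    verbatim, so a read/write cycle is a byte-level round trip.
    """
    stream, owned = _open_text(sink, "wt")
    try:
        n = 0
        for rec in records:
            stream.write(f"@{rec.header}\n{rec.sequence}\n+{rec.plus_line}\n{rec.quality}\n")
            n += 1
        return n
    finally:
        if owned:
            stream.close()


def write_fasta(records: Iterable[FastqRecord], sink: Source) -> int:
    """Write records as two-line FASTA (``>header`` then the unwrapped sequence).

    Quality information is discarded. Returns the number of records written.
    """
    stream, owned = _open_text(sink, "wt")
    try:
        n = 0
        for rec in records:
            stream.write(f">{rec.header}\n{rec.sequence}\n")
            n += 1
        return n
    finally:
        if owned:
            stream.close()
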