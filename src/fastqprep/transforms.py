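"""Whole-file representation changes: reverse complement, DNA->RNA, FASTA export.

Each transform produces a new output rather than modifying the filter chain's
single filtered file. Reverse complementing reverses the quality string too,
so every base keeps its own quality score. IUPAC ambiguity codes are
complemented (R<->Y, K<->M, B<->V, D<->H; S, W, N map to themselves) and case
is preserved throughout.
"""

from __future__ import annotations

from typing import Iterable

from fastqprep.io import FastqRecord, Source, write_fasta

_COMPLEMENT = {}
for _a, _b in [
    ("A", "T"), ("C", "G"), ("G", "C"), ("T", "A"), ("U", "A"),
    ("R", "Y"), ("Y", "R"), ("S", "S"), ("W", "W"), ("K", "M"), ("M", "K"),
    ("B", "V"), ("V", "B"), ("D", "H"), ("H", "D"), ("N", "N"),
]:
    _COMPLEMENT[_a] = _b
    _COMPLEMENT[_a.lower()] = _b.lower()


def reverse_complement(record: FastqRecord) -> FastqRecord:
    """Reverse-complement the sequence and reverse the quality string."""
    try:
        comp = "".join(_COMPLEMENT[ch] for ch in record.sequence)
    except KeyError as exc:
        raise ValueError(
            f"read {record.header!r}: no complement defined for character "
            f"{exc.args[0]!r}"
        ) from None
    return record.with_seq(comp[::-1], record.quality[::-1])


def to_rna(record: FastqRecord) -> FastqRecord:
    """Transcribe DNA to RNA: T->U (t->u); quality unchanged."""
    return record.with_seq(
        record.sequence.replace("T", "U").replace("t", "u"), record.quality
    )


def export_fasta(records: Iterable[FastqRecord], sink: Source) -> int:
    """Write records as two-line FASTA; returns the count written."""
    return write_fasta(records, sink)
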