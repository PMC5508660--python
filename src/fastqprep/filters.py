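"""Read-level removal predicates.

Each filter consumes a read iterable and returns a :class:`FilterOutcome`
holding the kept records (input order preserved) and a count of removals
keyed by filter name. Thresholds are strict-below: a read exactly at the
quality or length threshold is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from fastqprep.io import FastqRecord, QualityEncoding, SANGER
from fastqprep.metrics import read_stats

_ACGT = frozenset("ACGTacgt")


@dataclass
class FilterOutcome:
    """Kept reads plus per-filter removal counts; counts reconcile with input size."""

    kept: list[FastqRecord]
    removed_counts: dict[str, int] = field(default_factory=dict)

    @property
    def removed_total(self) -> int:
        return sum(self.removed_counts.values())


def _split(records: Iterable[FastqRecord], keep_pred, name: str) -> FilterOutcome:
    kept, removed = [], 0
    for rec in records:
        if keep_pred(rec):
            kept.append(rec)
        else:
            removed += 1
    return FilterOutcome(kept=kept, removed_counts={name: removed})


def filter_by_quality(
    records: Iterable[FastqRecord],
    min_q: float,
    encoding: QualityEncoding = SANGER,
) -> FilterOutcome:
    """Remove reads whose mean Phred score is strictly below *min_q*."""
    if min_q < 0:
        raise ValueError(f"quality threshold must be >= 0, got {min_q}")
    return _split(
        records,
        lambda r: read_stats(r, encoding).mean_phred >= min_q,
        "quality",
    )


def filter_by_length(records: Iterable[FastqRecord], min_len: int) -> FilterOutcome:
    """Remove reads strictly shorter than *min_len* bases."""
    if min_len < 1:
        raise ValueError(f"length threshold must be >= 1, got {min_len}")
    return _split(records, lambda r: len(r.sequence) >= min_len, "length")


def remove_duplicates(records: Iterable[FastqRecord]) -> FilterOutcome:
    """Keep the first occurrence of each distinct sequence (case-insensitive).

    Later reads with an identical sequence are removed regardless of header
    or quality. Uses an in-memory set of seen sequences, so memory grows with
    the number of distinct reads.
    """
    seen: set[str] = set()
    kept, removed = [], 0
    for rec in records:
        key = rec.sequence.upper()
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(rec)
    return FilterOutcome(kept=kept, removed_counts={"duplicate": removed})


def remove_ambiguous(records: Iterable[FastqRecord]) -> FilterOutcome:
    """Remove reads containing any base other than A, C, G, or T.

    N, IUPAC ambiguity codes, gaps -- anything outside A/C/G/T (either case)
    triggers removal of the whole read.
    """
    return _split(
        records,
        lambda r: all(ch in _ACGT for ch in r.sequence),
        "ambiguous",
    )
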