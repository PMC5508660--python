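"""End trimming and anchored adapter stripping.

Fixed-count trims remove bases from the left or right end, keeping the
quality string in lockstep. Adapter stripping is anchored: only the terminal
window of exactly the adapter's length is compared, once, under a Hamming
mismatch budget. A 3-base adapter TAG with one allowed mismatch matches a
read starting TAG, AAG, TAA, or any of the nine single-substitution
variants; internal occurrences and partial overhangs are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

from fastqprep.io import FastqRecord

_BASES = "ACGT"


@dataclass(frozen=True)
class AdapterSpec:
    """Adapter sequence, the read end it anchors to, and the mismatch budget."""

    sequence: str
    side: str  # "left" or "right"
    max_mismatch: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("adapter sequence must be non-empty")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if not 0 <= self.max_mismatch < len(self.sequence):
            raise ValueError(
                f"max_mismatch must be in [0, {len(self.sequence) - 1}], "
                f"got {self.max_mismatch}"
            )


def trim_left(record: FastqRecord, n: int) -> FastqRecord:
    """Drop min(n, length) bases and quality characters from the left end."""
    if n < 0:
        raise ValueError(f"trim count must be >= 0, got {n}")
    if n == 0:
        return record
    return record.with_seq(record.sequence[n:], record.quality[n:])


def trim_right(record: FastqRecord, n: int) -> FastqRecord:
    """Drop min(n, length) bases and quality characters from the right end."""
    if n < 0:
        raise ValueError(f"trim count must be >= 0, got {n}")
    if n == 0:
        return record
    keep = max(len(record.sequence) - n, 0)
    return record.with_seq(record.sequence[:keep], record.quality[:keep])


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatched positions between equal-length strings, case-insensitive."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a.upper(), b.upper()))


def enumerate_mismatch_variants(adapter: str, k: int) -> set[str]:
    """All A/C/G/T strings at Hamming distance exactly *k* from *adapter*.

    The result has C(len, k) * 3^k elements. k=0 returns the (upper-cased)
    adapter itself.
    """
    if not 0 <= k < len(adapter):
        raise ValueError(f"k must be in [0, {len(adapter) - 1}], got {k}")
    adapter = adapter.upper()
    out: set[str] = set()
    for positions in combinations(range(len(adapter)), k):
        alternatives = [[b for b in _BASES if b != adapter[p]] for p in positions]
        for subs in product(*alternatives):
            chars = list(adapter)
            for p, b in zip(positions, subs):
                chars[p] = b
            out.add("".join(chars))
    return out


def strip_adapter(record: FastqRecord, spec: AdapterSpec) -> tuple[FastqRecord, bool]:
    """Strip an anchored adapter from one end if it matches within budget.

    The terminal window of length ``len(spec.sequence)`` at ``spec.side`` is
    compared to the adapter exactly once; if its Hamming distance is at most
    ``spec.max_mismatch`` the window (sequence and quality) is removed.
    Reads shorter than the adapter never match. An N in the read counts as a
    mismatch against every adapter base.

    Returns the (possibly shortened) record and whether a match occurred.
    """
    alen = len(spec.sequence)
    if len(record.sequence) < alen:
        return record, False
    if spec.side == "left":
        window = record.sequence[:alen]
    else:
        window = record.sequence[-alen:]
    if hamming_distance(window, spec.sequence) > spec.max_mismatch:
        return record, False
    if spec.side == "left":
        return record.with_seq(record.sequence[alen:], record.quality[alen:]), True
    keep = len(record.sequence) - alen
    return record.with_seq(record.sequence[:keep], record.quality[:keep]), True
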