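"""Per-read metrics and before/after summary statistics.

The Phred score Q of a base call and its error probability P are related by
Q = -10*log10(P), equivalently P = 10^(-Q/10). Per read we report length,
GC%, the arithmetic mean of per-base Q, and the arithmetic mean of per-base
P. Note the two means differ: averaging P over bases and then converting
back to Q gives a lower score than averaging Q directly (Jensen's
inequality for the convex map Q -> 10^(-Q/10)); the quality filter uses the
mean of Q, matching the usual "average Phred score" reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from fastqprep.io import FastqRecord, QualityEncoding, SANGER


def phred_to_error(q: float) -> float:
    """Base-calling error probability P = 10^(-q/10) for Phred score q >= 0."""
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def error_to_phred(p: float) -> float:
    """Phred score Q = -10*log10(p) for error probability 0 < p <= 1."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"error probability must be in (0, 1], got {p}")
    return -10.0 * math.log10(p)


def gc_percent(sequence: str) -> float:
    """Percentage of G/C bases; ambiguous characters count in the denominator only."""
    if not sequence:
        raise ValueError("GC% is undefined for an empty sequence")
    gc = sum(1 for ch in sequence if ch in "GgCc")
    return 100.0 * gc / len(sequence)


@dataclass(frozen=True)
class ReadStats:
    """Metrics for one read: length, GC%, mean Phred, mean error probability."""

    length: int
    gc_percent: float
    mean_phred: float
    mean_error_prob: float


def read_stats(record: FastqRecord, encoding: QualityEncoding = SANGER) -> ReadStats:
    """Compute :class:`ReadStats` for one record.

    ``mean_error_prob`` averages the per-base probabilities 10^(-Q_i/10);
    it is *not* 10^(-mean_Q/10).
    """
    scores = encoding.decode(record.quality)
    n = len(scores)
    mean_q = sum(scores) / n
    mean_p = sum(10.0 ** (-q / 10.0) for q in scores) / n
    return ReadStats(
        length=n,
        gc_percent=gc_percent(record.sequence),
        mean_phred=mean_q,
        mean_error_prob=mean_p,
    )


@dataclass(frozen=True)
class MetricSummary:
    min: float
    max: float
    avg: float


@dataclass(frozen=True)
class SummaryTable:
    """Min/max/mean of each per-read metric over a read set.

    Averages are unweighted over reads (a short read counts as much as a
    long one). All metric fields are ``None`` when the set is empty.
    """

    read_count: int
    length: Optional[MetricSummary] = None
    gc_percent: Optional[MetricSummary] = None
    mean_phred: Optional[MetricSummary] = None
    mean_error_prob: Optional[MetricSummary] = None


def summarize(
    records: Iterable[FastqRecord], encoding: QualityEncoding = SANGER
) -> SummaryTable:
    """Single-pass summary of length, GC%, mean Phred, and mean error probability."""
    n = 0
    lo = [math.inf] * 4
    hi = [-math.inf] * 4
    tot = [0.0] * 4
    for rec in records:
        s = read_stats(rec, encoding)
        vals = (s.length, s.gc_percent, s.mean_phred, s.mean_error_prob)
        for i, v in enumerate(vals):
            if v < lo[i]:
                lo[i] = v
            if v > hi[i]:
                hi[i] = v
            tot[i] += v
        n += 1
    if n == 0:
        return SummaryTable(read_count=0)
    ms = [MetricSummary(lo[i], hi[i], tot[i] / n) for i in range(4)]
    return SummaryTable(
        read_count=n,
        length=ms[0],
        gc_percent=ms[1],
        mean_phred=ms[2],
        mean_error_prob=ms[3],
    )


_ROWS = (
    ("reads", "read_count", None),
    ("length min", "length", "min"),
    ("length max", "length", "max"),
    ("length avg", "length", "avg"),
    ("GC% min", "gc_percent", "min"),
    ("GC% max", "gc_percent", "max"),
    ("GC% avg", "gc_percent", "avg"),
    ("Phred min", "mean_phred", "min"),
    ("Phred max", "mean_phred", "max"),
    ("Phred avg", "mean_phred", "avg"),
    ("error prob min", "mean_error_prob", "min"),
    ("error prob max", "mean_error_prob", "max"),
    ("error prob avg", "mean_error_prob", "avg"),
)


def _cell(table: SummaryTable, attr: str, part: Optional[str]) -> str:
    if part is None:
        return str(table.read_count)
    metric = getattr(table, attr)
    if metric is None:
        return "NA"
    v = getattr(metric, part)
    if attr == "mean_error_prob":
        return f"{v:.3g}"  # probabilities span orders of magnitude
    return f"{v:.2f}"


def render_summary(before: SummaryTable, after: SummaryTable, sep: Optional[str] = None) -> str:
    """Two-column before/after table as text.

    Lengths, GC%, and Phred means print with 2 decimals; error probabilities
    with 3 significant digits. Empty-set cells print as ``NA``. With *sep*
    set (e.g. ``"\\t"``) the table is emitted as machine-parseable delimited
    text instead of aligned columns.
    """
    rows = [("metric", "unfiltered", "filtered")]
    for label, attr, part in _ROWS:
        rows.append((label, _cell(before, attr, part), _cell(after, attr, part)))
    if sep is not None:
        return "\n".join(sep.join(r) for r in rows)
    widths = [max(len(r[i]) for r in rows) for i in range(3)]
    lines = []
    for i, r in enumerate(rows):
        lines.append(
            f"{r[0]:<{widths[0]}}  {r[1]:>{widths[1]}}  {r[2]:>{widths[2]}}"
        )
        if i == 0:
            lines.append("-" * (sum(widths) + 4))
    return "\n".join(lines)
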