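"""Seeded synthetic FASTQ generator with a planted ground-truth manifest.

Reads are random A/C/G/T sequences with per-position Phred scores drawn
around a linear (typically decreasing) positional mean, emulating the
quality decay of real short-read data. Three features can be planted
explicitly: exact duplicate reads (copies appended after their originals),
reads carrying at least one N, and an adapter prefixed/suffixed to a chosen
fraction of reads. Planting is constructive, not probabilistic: the manifest
lists per read which features it carries, so a filter's output can be
compared to ground truth exactly.

To keep ground truth unambiguous the planted features are disjoint where
interaction would blur counts: N bases are never planted into a read that is
a duplicate source or copy, and reads not selected for the adapter are
rejection-sampled so their terminal window does not match the adapter within
the mismatch budget.

The generator does not emulate platform error processes (no substitution or
indel errors tied to the quality scores, no instrument-specific noise);
passing tests demonstrate correctness of the filtering logic, not robustness
to real-world artefacts.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from fastqprep.io import FastqRecord, QualityEncoding, SANGER, write_fastq
from fastqprep.trimming import AdapterSpec, hamming_distance

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic read set.

    Quality at position i (0-based) is drawn as a Gaussian around
    ``q_start + q_slope * i``, rounded and clamped to ``[q_min, q_max]``.
    The defaults mimic a typical Illumina-style profile: high quality
    (Q~38) at the 5' end decaying along the read, lengths 25-100 bases.
    """

    n_reads: int
    length_range: tuple[int, int] = (25, 100)
    q_start: float = 38.0
    q_slope: float = -0.08
    q_spread: float = 3.0
    q_min: int = 2
    q_max: int = 40
    duplicate_rate: float = 0.0
    n_rate: float = 0.0
    adapter: Optional[AdapterSpec] = None
    adapter_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid length_range {self.length_range}")
        for name in ("duplicate_rate", "n_rate", "adapter_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.duplicate_rate > 0 and self.n_reads < 2:
            raise ValueError("duplicate planting needs at least 2 reads")
        if self.adapter_fraction > 0 and self.adapter is None:
            raise ValueError("adapter_fraction > 0 requires an adapter")


@dataclass(frozen=True)
class ManifestEntry:
    """Planted ground truth for one read."""

    header: str
    duplicate_of: Optional[str]  # header of the original, None if not a copy
    has_n: bool
    has_adapter: bool
    true_mean_q: float


def _positional_q(spec: FixtureSpec, pos: int, rng: random.Random) -> int:
    mu = spec.q_start + spec.q_slope * pos
    q = round(rng.gauss(mu, spec.q_spread))
    return min(max(q, spec.q_min), spec.q_max)


def _random_read(spec: FixtureSpec, rng: random.Random) -> tuple[str, list[int]]:
    length = rng.randint(*spec.length_range)
    seq = "".join(rng.choice(_BASES) for _ in range(length))
    quals = [_positional_q(spec, i, rng) for i in range(length)]
    return seq, quals


def _avoid_adapter_end(seq: str, spec: FixtureSpec, rng: random.Random) -> str:
    """Resample the terminal window until it no longer matches the adapter."""
    ad = spec.adapter
    assert ad is not None
    alen = len(ad.sequence)
    if len(seq) < alen:
        return seq
    while True:
        window = seq[:alen] if ad.side == "left" else seq[-alen:]
        if hamming_distance(window, ad.sequence) > ad.max_mismatch:
            return seq
        fresh = "".join(rng.choice(_BASES) for _ in range(alen))
        seq = fresh + seq[alen:] if ad.side == "left" else seq[:-alen] + fresh


def generate_records(
    spec: FixtureSpec, encoding: QualityEncoding = SANGER
) -> tuple[list[FastqRecord], list[ManifestEntry]]:
    """Generate reads and their ground-truth manifest in memory.

    Counts are exact: ``round(duplicate_rate * n_reads)`` duplicate copies,
    ``round(n_rate * n_originals)`` N-carrying originals, and
    ``round(adapter_fraction * n_originals)`` adapter-carrying originals
    (duplicate copies inherit the N/adapter state of their source). The same
    spec always yields the same reads.
    """
    rng = random.Random(spec.seed)
    n_dup = int(round(spec.duplicate_rate * spec.n_reads))
    n_orig = spec.n_reads - n_dup
    if spec.n_reads > 0 and n_orig < 1:
        raise ValueError(
            f"duplicate_rate {spec.duplicate_rate} leaves no original reads"
        )

    # distinct original sequences (collision resampling keeps dedup exact)
    seen: set[str] = set()
    seqs: list[str] = []
    quals: list[list[int]] = []
    for _ in range(n_orig):
        while True:
            seq, q = _random_read(spec, rng)
            if spec.adapter is not None:
                seq = _avoid_adapter_end(seq, spec, rng)
            if seq not in seen:
                break
        seen.add(seq)
        seqs.append(seq)
        quals.append(q)

    n_with_n = int(round(spec.n_rate * n_orig))
    n_with_adapter = int(round(spec.adapter_fraction * n_orig))
    dup_sources = rng.sample(range(n_orig), min(n_dup, n_orig)) if n_dup else []
    # N bases never go into duplicated reads, so dedup/no_n counts stay disjoint
    n_candidates = [i for i in range(n_orig) if i not in set(dup_sources)]
    if n_with_n > len(n_candidates):
        raise ValueError(
            "n_rate and duplicate_rate together exceed the available reads"
        )
    n_targets = set(rng.sample(n_candidates, n_with_n))
    adapter_targets = set(rng.sample(range(n_orig), n_with_adapter))

    for i in n_targets:
        seq = list(seqs[i])
        k = rng.randint(1, min(3, len(seq)))
        for pos in rng.sample(range(len(seq)), k):
            seq[pos] = "N"
        seqs[i] = "".join(seq)

    if spec.adapter is not None:
        ad = spec.adapter
        for i in adapter_targets:
            extra_q = [
                _positional_q(spec, 0, rng) for _ in range(len(ad.sequence))
            ]
            if ad.side == "left":
                seqs[i] = ad.sequence + seqs[i]
                quals[i] = extra_q + quals[i]
            else:
                seqs[i] = seqs[i] + ad.sequence
                quals[i] = quals[i] + extra_q

    records: list[FastqRecord] = []
    manifest: list[ManifestEntry] = []

    def _emit(idx: int, src_idx: int, duplicate_of: Optional[str]):
        header = f"sim_{idx}"
        q = quals[src_idx]
        records.append(
            FastqRecord(
                header=header,
                sequence=seqs[src_idx],
                quality=encoding.encode(q),
            )
        )
        manifest.append(
            ManifestEntry(
                header=header,
                duplicate_of=duplicate_of,
                has_n=src_idx in n_targets,
                has_adapter=src_idx in adapter_targets,
                true_mean_q=sum(q) / len(q),
            )
        )

    for i in range(n_orig):
        _emit(i, i, None)
    # exact copies of randomly chosen originals, appended after all originals
    for j, src in enumerate(dup_sources + [rng.choice(range(n_orig)) for _ in range(max(0, n_dup - n_orig))]):
        _emit(n_orig + j, src, f"sim_{src}")
    return records, manifest


def write_manifest(manifest: list[ManifestEntry], path: Union[str, Path]) -> None:
    """Write the ground-truth manifest as tab-separated text."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write("header\tduplicate_of\thas_n\thas_adapter\ttrue_mean_q\n")
        for e in manifest:
            fh.write(
                f"{e.header}\t{e.duplicate_of or '-'}\t{int(e.has_n)}\t"
                f"{int(e.has_adapter)}\t{e.true_mean_q:.6f}\n"
            )


def read_manifest(path: Union[str, Path]) -> list[ManifestEntry]:
    out = []
    with open(path, encoding="ascii") as fh:
        next(fh)  # header row
        for line in fh:
            h, dup, has_n, has_ad, mq = line.rstrip("\n").split("\t")
            out.append(
                ManifestEntry(
                    header=h,
                    duplicate_of=None if dup == "-" else dup,
                    has_n=bool(int(has_n)),
                    has_adapter=bool(int(has_ad)),
                    true_mean_q=float(mq),
                )
            )
    return out


def generate(
    spec: FixtureSpec,
    fastq_path: Union[str, Path],
    manifest_path: Optional[Union[str, Path]] = None,
    encoding: QualityEncoding = SANGER,
) -> list[ManifestEntry]:
    """Write a synthetic FASTQ file (and optionally its manifest); returns the manifest."""
    records, manifest = generate_records(spec, encoding)
    write_fastq(records, fastq_path)
    if manifest_path is not None:
        write_manifest(manifest, manifest_path)
    return manifest
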