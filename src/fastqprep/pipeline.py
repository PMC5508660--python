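"""Pipeline orchestration: chain filters into one filtered file, then transforms.

All enabled filter stages run in a single streaming pass over the input, in
a fixed canonical order:

    1. strip adapter, left end        5. drop reads with non-ACGT bases
    2. strip adapter, right end       6. mean-quality filter
    3. fixed left trim                7. minimum-length filter
    4. fixed right trim               8. duplicate removal

Trimming happens before the quality and length tests so those tests apply
to the read that survives to downstream use, and duplicate removal sees
final (post-trim) sequences. Reads trimmed to zero length are dropped and
counted. Transforms (FASTA export, reverse complement, RNA) each write
their own new file from the filtered output and never feed back into the
chain.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from fastqprep.io import (
    FastqRecord,
    QualityEncoding,
    read_fastq,
    write_fasta,
    write_fastq,
)
from fastqprep.metrics import SummaryTable, read_stats, render_summary, summarize
from fastqprep.transforms import reverse_complement, to_rna
from fastqprep.trimming import AdapterSpec, strip_adapter, trim_left, trim_right

#: Stage names in canonical execution order (used for logging).
STAGE_ORDER = (
    "adapter_left",
    "adapter_right",
    "trim_left",
    "trim_right",
    "zero_length",
    "ambiguous",
    "quality",
    "length",
    "duplicate",
)


@dataclass
class PipelineConfig:
    """Resolved user options; one field per command-line flag."""

    lib: str  # quality encoding name: "sanger" or "illumina"
    input_name: str
    path: str = "."
    smry: bool = False
    qf: Optional[float] = None
    lf: Optional[int] = None
    trim_l: Optional[int] = None
    trim_r: Optional[int] = None
    adpt_l: Optional[str] = None
    adpt_r: Optional[str] = None
    mis_l: int = 0
    mis_r: int = 0
    dup: bool = False
    no_n: bool = False
    fasta: bool = False
    rev_comp: bool = False
    rna: bool = False
    clean: bool = False

    def __post_init__(self):
        if self.lib not in ("sanger", "illumina"):
            raise ValueError(f"lib must be 'sanger' or 'illumina', got {self.lib!r}")
        if self.mis_l and self.adpt_l is None:
            raise ValueError("mis_l requires adpt_l")
        if self.mis_r and self.adpt_r is None:
            raise ValueError("mis_r requires adpt_r")

    @property
    def encoding(self) -> QualityEncoding:
        return QualityEncoding.from_name(self.lib)

    @property
    def input_path(self) -> Path:
        return Path(self.path) / self.input_name

    def has_filters(self) -> bool:
        return any(
            (
                self.qf is not None,
                self.lf is not None,
                self.trim_l is not None,
                self.trim_r is not None,
                self.adpt_l is not None,
                self.adpt_r is not None,
                self.dup,
                self.no_n,
            )
        )


@dataclass
class PipelineResult:
    """Outputs of one run: file paths, per-stage counts, optional summaries."""

    config: PipelineConfig
    filtered_path: Path
    transform_paths: dict[str, Path] = field(default_factory=dict)
    input_count: int = 0
    output_count: int = 0
    stage_counts: dict[str, int] = field(default_factory=dict)
    adapter_matches: dict[str, int] = field(default_factory=dict)
    before: Optional[SummaryTable] = None
    after: Optional[SummaryTable] = None
    temp_paths: list[Path] = field(default_factory=list)


def _filter_stream(config: PipelineConfig, result: PipelineResult) -> Iterator[FastqRecord]:
    """Yield surviving reads in input order, updating counters as a side effect."""
    enc = config.encoding
    counts = result.stage_counts
    matches = result.adapter_matches
    ad_l = (
        AdapterSpec(config.adpt_l, "left", config.mis_l)
        if config.adpt_l is not None
        else None
    )
    ad_r = (
        AdapterSpec(config.adpt_r, "right", config.mis_r)
        if config.adpt_r is not None
        else None
    )
    seen: set[str] = set()
    for rec in read_fastq(config.input_path, enc):
        result.input_count += 1
        if ad_l is not None:
            rec, hit = strip_adapter(rec, ad_l)
            matches["left"] = matches.get("left", 0) + hit
        if ad_r is not None:
            rec, hit = strip_adapter(rec, ad_r)
            matches["right"] = matches.get("right", 0) + hit
        if config.trim_l:
            rec = trim_left(rec, config.trim_l)
        if config.trim_r:
            rec = trim_right(rec, config.trim_r)
        if len(rec) == 0:
            counts["zero_length"] = counts.get("zero_length", 0) + 1
            continue
        if config.no_n and any(ch not in "ACGTacgt" for ch in rec.sequence):
            counts["ambiguous"] = counts.get("ambiguous", 0) + 1
            continue
        if config.qf is not None and read_stats(rec, enc).mean_phred < config.qf:
            counts["quality"] = counts.get("quality", 0) + 1
            continue
        if config.lf is not None and len(rec) < config.lf:
            counts["length"] = counts.get("length", 0) + 1
            continue
        if config.dup:
            key = rec.sequence.upper()
            if key in seen:
                counts["duplicate"] = counts.get("duplicate", 0) + 1
                continue
            seen.add(key)
        result.output_count += 1
        yield rec


def run_pipeline(config: PipelineConfig, log=None) -> PipelineResult:
    """Execute the configured stages and return paths, counts, and summaries.

    The filter chain streams the input once into ``<stem>.filtered.fastq``.
    Each requested transform then writes its own file from the filtered
    output. With ``smry`` set, summaries of the input and the filtered file
    are computed and the rendered table is written to *log*'s stdout
    counterpart by the CLI (the tables are returned either way).
    """
    in_path = config.input_path
    if not in_path.exists():
        raise FileNotFoundError(f"input file not found: {in_path}")
    stem = in_path.name
    for suffix in (".fastq", ".fq", ".fastq.gz", ".fq.gz"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    out_dir = in_path.parent
    filtered_path = out_dir / f"{stem}.filtered.fastq"
    result = PipelineResult(config=config, filtered_path=filtered_path)

    write_fastq(_filter_stream(config, result), filtered_path)

    # the filtered file is a mere intermediate when it only feeds transforms
    any_transform = config.fasta or config.rev_comp or config.rna
    if any_transform and not config.has_filters():
        result.temp_paths.append(filtered_path)

    enc = config.encoding
    if config.fasta:
        p = out_dir / f"{stem}.fasta"
        write_fasta(read_fastq(filtered_path, enc), p)
        result.transform_paths["fasta"] = p
    if config.rev_comp:
        p = out_dir / f"{stem}.revcomp.fastq"
        write_fastq(
            (reverse_complement(r) for r in read_fastq(filtered_path, enc)), p
        )
        result.transform_paths["rev_comp"] = p
    if config.rna:
        p = out_dir / f"{stem}.rna.fastq"
        write_fastq((to_rna(r) for r in read_fastq(filtered_path, enc)), p)
        result.transform_paths["rna"] = p

    if config.smry:
        result.before = summarize(read_fastq(in_path, enc), enc)
        result.after = summarize(read_fastq(filtered_path, enc), enc)

    if log is not None:
        for stage in STAGE_ORDER:
            if stage in result.stage_counts:
                print(f"{stage}: removed {result.stage_counts[stage]}", file=log)
        for side, n in result.adapter_matches.items():
            print(f"adapter_{side}: matched {n}", file=log)
        print(
            f"reads in: {result.input_count}, reads out: {result.output_count}",
            file=log,
        )

    if config.clean:
        cleanup_temp(result, log=log)
    return result


def cleanup_temp(result: PipelineResult, log=None) -> list[Path]:
    """Delete intermediate files recorded on *result*; never inputs or outputs.

    Returns the list of files actually removed; failures warn rather than
    abort. Idempotent: a second call finds nothing left to remove. With the
    ``clean`` flag unset this is a no-op returning an empty list.
    """
    removed = []
    if not result.config.clean:
        return removed
    for p in list(result.temp_paths):
        if p == result.config.input_path or p in result.transform_paths.values():
            continue
        try:
            if p.exists():
                p.unlink()
                removed.append(p)
            result.temp_paths.remove(p)
        except OSError as exc:  # pragma: no cover - unusual FS state
            print(f"warning: could not remove {p}: {exc}", file=log or sys.stderr)
    return removed
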