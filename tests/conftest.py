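import pytest

from fastqprep.io import FastqRecord, SANGER
from fastqprep.simulate import FixtureSpec, generate_records


def rec(seq: str, quals=None, header: str = "r", plus: str = "") -> FastqRecord:
    """Build a record; quals may be a quality string, an int list, or a constant Q."""
    if quals is None:
        quals = [40] * len(seq)
    if isinstance(quals, int):
        quals = [quals] * len(seq)
    if isinstance(quals, list):
        quals = SANGER.encode(quals)
    return FastqRecord(header=header, sequence=seq, quality=quals, plus_line=plus)


@pytest.fixture(scope="session")
def plain_reads():
    """1000 clean synthetic reads (no duplicates, no N, no adapter)."""
    records, _ = generate_records(FixtureSpec(n_reads=1000, seed=11))
    return records


@pytest.fixture
def fastq_file(tmp_path, plain_reads):
    from fastqprep.io import write_fastq

    p = tmp_path / "reads.fastq"
    write_fastq(plain_reads, p)
    return p
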