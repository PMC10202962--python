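import numpy as np
import pytest

from atacircle.alignment_io import ReadTable
from atacircle.simulator import Reference


@pytest.fixture(scope="session")
def small_reference():
    """A 2x1.2 Mb seeded random genome with one N run per contig."""
    return Reference.synthetic(
        seed=42,
        contig_lengths={"chr1": 1_200_000, "chr2": 1_200_000},
        n_runs_per_contig=1,
        n_run_length=2000,
    )


class SamBuilder:
    """Write small hand-specified SAM files for alignment_io tests."""

    def __init__(self, tmp_path, contig_lengths=None):
        self.tmp_path = tmp_path
        self.contig_lengths = contig_lengths or {"chr1": 100_000, "chr2": 100_000}
        self.records = []

    def add(
        self,
        name,
        contig="chr1",
        pos=1000,
        mapq=30,
        cigar="100M",
        flag=None,
        reverse=False,
        duplicate=False,
        paired=True,
        read2=False,
        mate_contig="=",
        mate_pos=None,
        tlen=0,
        secondary=False,
        unmapped=False,
    ):
        if flag is None:
            flag = 0
            if paired:
                flag |= 1
            if unmapped:
                flag |= 4
            if reverse:
                flag |= 16
            if read2:
                flag |= 128
            elif paired:
                flag |= 64
            if secondary:
                flag |= 256
            if duplicate:
                flag |= 1024
        mate_pos = pos if mate_pos is None else mate_pos
        self.records.append(
            (name, flag, contig, pos, mapq, cigar, mate_contig, mate_pos, tlen)
        )
        return self

    def write(self, name="sample.sam", sort=True):
        path = self.tmp_path / name
        records = self.records
        if sort:
            order = {c: i for i, c in enumerate(self.contig_lengths)}
            records = sorted(records, key=lambda r: (order.get(r[2], 99), r[3]))
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            for contig, length in self.contig_lengths.items():
                fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
            for name_, flag, contig, pos, mapq, cigar, mc, mp, tlen in records:
                seq_len = sum(
                    int(n)
                    for n, op in _cigar_items(cigar)
                    if op in "MIS=X"
                )
                seq = "A" * seq_len
                qual = "I" * seq_len
                fh.write(
                    f"{name_}\t{flag}\t{contig}\t{pos + 1}\t{mapq}\t{cigar}"
                    f"\t{mc}\t{mp + 1}\t{tlen}\t{seq}\t{qual}\n"
                )
        return str(path)


def _cigar_items(cigar):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


@pytest.fixture
def sam_builder(tmp_path):
    return lambda **kw: SamBuilder(tmp_path, **kw)


def make_table(reads, contig_lengths=None):
    """Build a ReadTable from (rid, contig, start, end, reverse, tlen,
    mate_contig, clip_left, clip_right) tuples."""
    contig_lengths = contig_lengths or {"chr1": 1_000_000, "chr2": 1_000_000}
    contigs = list(contig_lengths)
    tid_of = {c: i for i, c in enumerate(contigs)}
    n = len(reads)
    cols = dict(
        rid=np.array([r[0] for r in reads], dtype=np.int64),
        tid=np.array([tid_of[r[1]] for r in reads], dtype=np.int32),
        start=np.array([r[2] for r in reads], dtype=np.int64),
        end=np.array([r[3] for r in reads], dtype=np.int64),
        reverse=np.array([r[4] for r in reads], dtype=bool),
        mapq=np.full(n, 60, dtype=np.int16),
        tlen=np.array([r[5] for r in reads], dtype=np.int64),
        mate_tid=np.array(
            [tid_of[r[6]] if r[6] is not None else -1 for r in reads], dtype=np.int32
        ),
        mate_start=np.zeros(n, dtype=np.int64),
        clip_left=np.array([r[7] for r in reads], dtype=np.int32),
        clip_right=np.array([r[8] for r in reads], dtype=np.int32),
        is_read2=np.zeros(n, dtype=bool),
    )
    return ReadTable(contigs, contig_lengths, **cols).sort_by_coordinate()
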