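"""Mock ecDNA generation and circular-template read simulation.

The simulator draws non-overlapping reference segments, ligates them (with
random orientations) into a circular template, samples paired-end fragments
uniformly on the circle, and maps every read back to reference coordinates
("perfect alignment"), so the full detection pipeline can run without an
external aligner.  A uniform linear background emulates the bulk ATAC-seq
library the circles are blended into.

A read that crosses a ligation junction is emitted as a primary alignment of
its longer reference-consistent part with the remainder soft-clipped —
provided the aligned part reaches ``min_align`` bases (real aligners need a
seed match; this is what makes short reads lose clipped-read evidence).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .alignment_io import GenomicInterval, ReadTable
from .circle_search import OrientedSegment

__all__ = [
    "Reference",
    "MockEcDNA",
    "SimulatedReadPair",
    "FragmentModel",
    "generate_mock_ecdna",
    "circular_sequence",
    "simulate_fragments",
    "simulate_reads",
    "simulate_background",
    "place_pairs",
    "background_pairs",
    "pairs_to_table",
    "merge_tables",
    "perfect_align",
    "write_sam",
    "write_fastq",
    "write_truth_json",
    "load_truth_json",
]

logger = logging.getLogger(__name__)

#: minimum reference-consistent bases a junction-crossing read needs to be
#: reported as a (clipped) alignment; shorter remainders go unmapped, which
#: is what an aligner's minimum seed length does to short reads
DEFAULT_MIN_ALIGN = 30

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Reference:
    """A small in-memory reference genome (uint8 byte arrays per contig)."""

    def __init__(self, seqs: dict[str, np.ndarray]):
        self._seqs = seqs

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self._seqs.items()}

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    def sequence(self, contig: str, start: int = 0, end: Optional[int] = None) -> str:
        arr = self._seqs[contig]
        end = len(arr) if end is None else end
        if start < 0 or end > len(arr):
            raise ValueError(f"segment {contig}:{start}-{end} outside contig")
        return arr[start:end].tobytes().decode("ascii")

    def n_free_intervals(self, contig: str) -> list[tuple[int, int]]:
        arr = self._seqs[contig]
        mask = arr != ord("N")
        if not mask.any():
            return []
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        return list(zip(edges[0::2].tolist(), edges[1::2].tolist()))

    def is_n_free(self, contig: str, start: int, end: int) -> bool:
        arr = self._seqs[contig]
        return not bool((arr[start:end] == ord("N")).any())

    @classmethod
    def synthetic(
        cls,
        seed: int = 0,
        contig_lengths: Optional[dict[str, int]] = None,
        n_runs_per_contig: int = 2,
        n_run_length: int = 3000,
    ) -> "Reference":
        """A seeded random genome with a few implanted N runs per contig."""
        if contig_lengths is None:
            contig_lengths = {f"chr{i + 1}": 5_500_000 for i in range(4)}
        rng = np.random.default_rng(seed)
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs = {}
        for contig, length in contig_lengths.items():
            arr = alphabet[rng.integers(0, 4, size=length)]
            for _ in range(n_runs_per_contig):
                pos = int(rng.integers(0, max(1, length - n_run_length)))
                arr[pos : pos + n_run_length] = ord("N")
            seqs[contig] = arr
        return cls(seqs)

    @classmethod
    def from_fasta(cls, path: str) -> "Reference":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        seqs = {
            name: np.frombuffer(str(fa[name][:]).encode("ascii"), dtype=np.uint8).copy()
            for name in fa.keys()
        }
        return cls(seqs)

    def write_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for contig, arr in self._seqs.items():
                fh.write(f">{contig}\n")
                raw = arr.tobytes().decode("ascii")
                for i in range(0, len(raw), width):
                    fh.write(raw[i : i + width] + "\n")


@dataclass
class MockEcDNA:
    """Ground-truth circle: ordered, oriented, reference-anchored segments."""

    id: str
    segments: list[OrientedSegment]

    def __post_init__(self) -> None:
        for a in self.segments:
            for b in self.segments:
                if a is not b and a.interval.overlaps(b.interval):
                    raise ValueError("mock segments must not overlap on the reference")

    @property
    def circle_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def boundaries(self) -> np.ndarray:
        """Circle coordinates of segment starts, plus the total length."""
        return np.concatenate(([0], np.cumsum([s.length for s in self.segments])))

    def junction_coordinates(self) -> list[tuple[int, int]]:
        """Per junction i (segments i -> i+1): the two reference breakpoints.

        The first element is the exit coordinate of segment i, the second the
        entry coordinate of segment i+1 (both 0-based; an exit from a '+'
        segment is its end, from a '-' segment its start).
        """
        out = []
        k = len(self.segments)
        for i in range(k):
            a = self.segments[i]
            b = self.segments[(i + 1) % k]
            exit_a = a.interval.end if a.strand == "+" else a.interval.start
            entry_b = b.interval.start if b.strand == "+" else b.interval.end
            out.append((exit_a, entry_b))
        return out


@dataclass
class FragmentModel:
    """Truncated-normal fragment lengths for the paired-end library."""

    mean: float = 250.0
    sd: float = 50.0
    max_len: int = 1000

    def sample(self, n: int, read_len: int, rng: np.random.Generator) -> np.ndarray:
        lo = read_len
        if self.mean < read_len:
            raise ValueError(
                f"fragment mean {self.mean} is below the read length {read_len}"
            )
        a = (lo - self.mean) / self.sd
        b = (self.max_len - self.mean) / self.sd
        draws = stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)
        return np.clip(np.round(draws).astype(np.int64), lo, self.max_len)


@dataclass
class SimulatedReadPair:
    """One simulated pair with its circular truth placement."""

    pair_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    circ_start: int
    fragment_length: int


def generate_mock_ecdna(
    reference: Reference,
    n_segments: tuple[int, int] = (1, 50),
    total_size: tuple[float, float] = (5e3, 1e7),
    rng: "np.random.Generator | int | None" = None,
    segment_size: Optional[tuple[float, float]] = None,
    min_gap: int = 30_000,
    occupied: Optional[list[GenomicInterval]] = None,
    mock_id: str = "mock0",
    max_tries: int = 500,
) -> MockEcDNA:
    """Draw a random mock ecDNA from the non-N portion of the reference.

    Segments are mutually non-overlapping (and at least ``min_gap`` apart
    from each other and from anything in ``occupied``, which is updated in
    place) with i.i.d. uniform strands.  By default the requested total size
    is drawn uniformly from ``total_size`` and split across segments; the
    desk-scale alternative ``segment_size`` draws each segment length
    i.i.d. uniform instead.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = int(rng.integers(n_segments[0], n_segments[1] + 1))
    if segment_size is not None:
        sizes = rng.integers(int(segment_size[0]), int(segment_size[1]) + 1, size=n)
    else:
        total = int(rng.integers(int(total_size[0]), int(total_size[1]) + 1))
        min_seg = max(200, total // (20 * n))
        props = rng.dirichlet(np.ones(n))
        sizes = (props * (total - n * min_seg)).astype(np.int64) + min_seg
        sizes[-1] += total - int(sizes.sum())
    free: list[tuple[str, int, int]] = []
    for contig in reference.contigs:
        for s, e in reference.n_free_intervals(contig):
            free.append((contig, s, e))
    if not free:
        raise ValueError("reference has no non-N sequence")
    weights = np.array([e - s for _, s, e in free], dtype=np.float64)
    weights /= weights.sum()
    occupied = occupied if occupied is not None else []
    placed: list[OrientedSegment] = []
    for size in sizes:
        size = int(size)
        for attempt in range(max_tries):
            idx = int(rng.choice(len(free), p=weights))
            contig, lo, hi = free[idx]
            if hi - lo < size:
                continue
            start = int(rng.integers(lo, hi - size + 1))
            iv = GenomicInterval(contig, start, start + size)
            padded = GenomicInterval(contig, max(0, start - min_gap), start + size + min_gap)
            if any(padded.overlaps(o) for o in occupied):
                continue
            if any(padded.overlaps(p.interval) for p in placed):
                continue
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            placed.append(OrientedSegment(iv, strand))
            break
        else:
            raise ValueError(
                f"could not place a {size} bp segment after {max_tries} tries; "
                "reference too small for the requested mock"
            )
    occupied.extend(p.interval for p in placed)
    return MockEcDNA(mock_id, placed)


def circular_sequence(mock: MockEcDNA, reference: Reference) -> str:
    """The ligated circular template (linearised at segment 0's start)."""
    parts = []
    for seg in mock.segments:
        raw = reference.sequence(seg.interval.contig, seg.interval.start, seg.interval.end)
        parts.append(raw if seg.strand == "+" else _revcomp(raw))
    return "".join(parts)


def simulate_fragments(
    mock: MockEcDNA,
    local_depth: float,
    read_len: int,
    fragment_model: Optional[FragmentModel] = None,
    rng: "np.random.Generator | int | None" = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(fragment starts on the circle, fragment lengths) at the target depth.

    The pair count follows the coverage identity
    ``round(local_depth * circle_length / (2 * read_len))``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    model = fragment_model or FragmentModel()
    if model.mean < read_len:
        raise ValueError("read length exceeds the fragment mean")
    circle_len = mock.circle_length
    n_pairs = int(round(local_depth * circle_len / (2.0 * read_len)))
    starts = rng.integers(0, circle_len, size=n_pairs)
    lengths = model.sample(n_pairs, read_len, rng)
    lengths = np.minimum(lengths, circle_len)
    return starts, lengths


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    mock: MockEcDNA,
    reference: Reference,
    local_depth: float,
    read_len: int,
    fragment_model: Optional[FragmentModel] = None,
    error_rate: float = 0.0,
    rng: "np.random.Generator | int | None" = None,
    id_prefix: str = "sim",
) -> list[SimulatedReadPair]:
    """Sequence-level pair simulation from the circular template."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    starts, lengths = simulate_fragments(mock, local_depth, read_len, fragment_model, rng)
    circ = circular_sequence(mock, reference)
    doubled = circ + circ
    qual = "I" * read_len  # constant Q40; downstream models never read qualities
    pairs = []
    for i, (f, flen) in enumerate(zip(starts.tolist(), lengths.tolist())):
        r1 = doubled[f : f + read_len]
        r2_start = (f + flen - read_len) % len(circ)
        r2 = _revcomp(doubled[r2_start : r2_start + read_len])
        pairs.append(
            SimulatedReadPair(
                pair_id=f"{id_prefix}{i}",
                r1_seq=_apply_errors(r1, error_rate, rng),
                r1_qual=qual,
                r2_seq=_apply_errors(r2, error_rate, rng),
                r2_qual=qual,
                circ_start=int(f),
                fragment_length=int(flen),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# perfect alignment


def _place_reads(
    mock: MockEcDNA,
    contigs: Sequence[str],
    circ_starts: np.ndarray,
    circ_reverse: np.ndarray,
    read_len: int,
    min_align: int,
) -> dict[str, np.ndarray]:
    """Map circle-coordinate reads to primary reference placements."""
    bounds = mock.boundaries
    circle_len = int(bounds[-1])
    tid_of = {c: i for i, c in enumerate(contigs)}
    seg_tid = np.array([tid_of[s.interval.contig] for s in mock.segments])
    seg_start = np.array([s.interval.start for s in mock.segments], dtype=np.int64)
    seg_end = np.array([s.interval.end for s in mock.segments], dtype=np.int64)
    seg_neg = np.array([s.strand == "-" for s in mock.segments])
    seg_len = seg_end - seg_start
    k = len(mock.segments)

    rs = np.mod(circ_starts, circle_len)
    i = np.searchsorted(bounds, rs, side="right") - 1
    within = bounds[i + 1] - rs
    part_a = np.minimum(read_len, within)
    part_b = read_len - part_a
    j = (i + 1) % k
    part_b_capped = np.minimum(part_b, seg_len[j])
    double_cross = part_b > part_b_capped
    if double_cross.any():
        logger.warning(
            "%d read(s) crossed two junctions; clipped to the longest part",
            int(double_cross.sum()),
        )
    use_a = part_a >= part_b_capped
    seg_idx = np.where(use_a, i, j)
    offset = np.where(use_a, rs - bounds[i], 0)
    aligned = np.where(use_a, part_a, part_b_capped)
    neg = seg_neg[seg_idx]
    ref_start = np.where(
        ~neg,
        seg_start[seg_idx] + offset,
        seg_end[seg_idx] - offset - aligned,
    )
    clip = read_len - aligned
    clip_on_right = np.where(use_a, ~neg, neg)
    return {
        "tid": seg_tid[seg_idx].astype(np.int32),
        "start": ref_start.astype(np.int64),
        "end": (ref_start + aligned).astype(np.int64),
        "reverse": circ_reverse ^ neg,
        "clip_left": np.where(clip_on_right, 0, clip).astype(np.int32),
        "clip_right": np.where(clip_on_right, clip, 0).astype(np.int32),
        "mapped": aligned >= max(min_align, 1),
    }


def place_pairs(
    mock: MockEcDNA,
    contigs: Sequence[str],
    frag_starts: np.ndarray,
    frag_lengths: np.ndarray,
    read_len: int,
    min_align: int = DEFAULT_MIN_ALIGN,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Reference placements of both mates of every fragment."""
    circle_len = mock.circle_length
    r1 = _place_reads(
        mock, contigs, frag_starts, np.zeros(len(frag_starts), dtype=bool), read_len, min_align
    )
    r2_start = np.mod(frag_starts + frag_lengths - read_len, circle_len)
    r2 = _place_reads(
        mock, contigs, r2_start, np.ones(len(frag_starts), dtype=bool), read_len, min_align
    )
    return r1, r2


def _pair_tlen(r1: dict, r2: dict) -> tuple[np.ndarray, np.ndarray]:
    """Signed template lengths for the two mates (0 across contigs/unmapped)."""
    same = (r1["tid"] == r2["tid"]) & r1["mapped"] & r2["mapped"]
    left = np.minimum(r1["start"], r2["start"])
    right = np.maximum(r1["end"], r2["end"])
    span = np.where(same, right - left, 0)
    r1_first = r1["start"] <= r2["start"]
    tlen1 = np.where(r1_first, span, -span)
    return tlen1, -tlen1


def pairs_to_table(
    placements: Sequence[tuple[dict[str, np.ndarray], dict[str, np.ndarray]]],
    contigs: Sequence[str],
    contig_lengths: dict[str, int],
    rid_offset: int = 0,
) -> ReadTable:
    """Assemble mate placements into a coordinate-sorted ReadTable.

    Unmapped reads are dropped; their mapped mates stay, flagged with
    ``mate_tid == -1`` (mate unmapped), exactly as an aligner would leave
    them.
    """
    cols = {name: [] for name in ReadTable.COLUMNS}
    offset = rid_offset
    for r1, r2 in placements:
        n = len(r1["tid"])
        rid = np.arange(offset, offset + n, dtype=np.int64)
        offset += n
        tlen1, tlen2 = _pair_tlen(r1, r2)
        for me, other, tlen, is_r2 in ((r1, r2, tlen1, False), (r2, r1, tlen2, True)):
            keep = me["mapped"]
            mate_ok = other["mapped"]
            cols["rid"].append(rid[keep])
            cols["tid"].append(me["tid"][keep])
            cols["start"].append(me["start"][keep])
            cols["end"].append(me["end"][keep])
            cols["reverse"].append(me["reverse"][keep])
            cols["mapq"].append(np.full(int(keep.sum()), 60, dtype=np.int16))
            cols["tlen"].append(np.where(mate_ok, tlen, 0)[keep])
            cols["mate_tid"].append(np.where(mate_ok, other["tid"], -1)[keep].astype(np.int32))
            cols["mate_start"].append(np.where(mate_ok, other["start"], -1)[keep])
            cols["clip_left"].append(me["clip_left"][keep])
            cols["clip_right"].append(me["clip_right"][keep])
            cols["is_read2"].append(np.full(int(keep.sum()), is_r2, dtype=bool))
    arrays = {name: np.concatenate(chunks) for name, chunks in cols.items()}
    table = ReadTable(contigs, contig_lengths, **arrays)
    return table.sort_by_coordinate()


def background_pairs(
    reference: Reference,
    genome_depth: float,
    read_len: int,
    fragment_model: Optional[FragmentModel] = None,
    rng: "np.random.Generator | int | None" = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Uniform concordant pairs over the non-N reference at the given depth.

    The pair count uses the full reference length in the coverage identity;
    placements avoid N runs entirely.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    model = fragment_model or FragmentModel()
    contigs = reference.contigs
    tid_of = {c: i for i, c in enumerate(contigs)}
    total_len = sum(reference.lengths.values())
    n_pairs = int(round(genome_depth * total_len / (2.0 * read_len)))
    ivs = []
    for contig in contigs:
        for s, e in reference.n_free_intervals(contig):
            ivs.append((tid_of[contig], s, e))
    iv_tid = np.array([t for t, _, _ in ivs])
    iv_start = np.array([s for _, s, _ in ivs], dtype=np.int64)
    iv_end = np.array([e for _, _, e in ivs], dtype=np.int64)
    iv_len = iv_end - iv_start
    cum = np.concatenate(([0], np.cumsum(iv_len)))
    flen = model.sample(n_pairs, read_len, rng)
    tid = np.empty(n_pairs, dtype=np.int32)
    pos = np.empty(n_pairs, dtype=np.int64)
    pending = np.arange(n_pairs)
    while len(pending):
        u = rng.integers(0, cum[-1], size=len(pending))
        idx = np.searchsorted(cum, u, side="right") - 1
        p = iv_start[idx] + (u - cum[idx])
        ok = p + flen[pending] <= iv_end[idx]
        sel = pending[ok]
        tid[sel] = iv_tid[idx[ok]]
        pos[sel] = p[ok]
        pending = pending[~ok]
    n = n_pairs
    r1 = {
        "tid": tid,
        "start": pos,
        "end": pos + read_len,
        "reverse": np.zeros(n, dtype=bool),
        "clip_left": np.zeros(n, dtype=np.int32),
        "clip_right": np.zeros(n, dtype=np.int32),
        "mapped": np.ones(n, dtype=bool),
    }
    r2_start = pos + flen - read_len
    r2 = {
        "tid": tid.copy(),
        "start": r2_start,
        "end": pos + flen,
        "reverse": np.ones(n, dtype=bool),
        "clip_left": np.zeros(n, dtype=np.int32),
        "clip_right": np.zeros(n, dtype=np.int32),
        "mapped": np.ones(n, dtype=bool),
    }
    return r1, r2


def simulate_background(
    reference: Reference,
    genome_depth: float,
    read_len: int,
    fragment_model: Optional[FragmentModel] = None,
    rng: "np.random.Generator | int | None" = None,
) -> ReadTable:
    """Background library as a ready-to-use ReadTable."""
    r1, r2 = background_pairs(reference, genome_depth, read_len, fragment_model, rng)
    return pairs_to_table([(r1, r2)], reference.contigs, reference.lengths)


def merge_tables(tables: Sequence[ReadTable]) -> ReadTable:
    """Concatenate tables over the same contig set, re-keying pair IDs."""
    base = tables[0]
    cols = {name: [] for name in ReadTable.COLUMNS}
    offset = 0
    for t in tables:
        if t.contigs != base.contigs:
            raise ValueError("tables cover different contig sets")
        for name in ReadTable.COLUMNS:
            arr = getattr(t, name)
            if name == "rid":
                arr = arr + offset
            cols[name].append(arr)
        offset += int(t.rid.max(initial=-1)) + 1
    arrays = {name: np.concatenate(chunks) for name, chunks in cols.items()}
    return ReadTable(base.contigs, base.contig_lengths, **arrays).sort_by_coordinate()


def perfect_align(
    pairs: Sequence[SimulatedReadPair],
    mock: MockEcDNA,
    reference: Reference,
    read_len: Optional[int] = None,
    min_align: int = DEFAULT_MIN_ALIGN,
) -> ReadTable:
    """Map sequence-level simulated pairs back through the segment map."""
    if not pairs:
        raise ValueError("no pairs to align")
    read_len = read_len if read_len is not None else len(pairs[0].r1_seq)
    starts = np.array([p.circ_start for p in pairs], dtype=np.int64)
    lengths = np.array([p.fragment_length for p in pairs], dtype=np.int64)
    r1, r2 = place_pairs(mock, reference.contigs, starts, lengths, read_len, min_align)
    return pairs_to_table([(r1, r2)], reference.contigs, reference.lengths)


def write_sam(
    table: ReadTable,
    path: str,
    seqs: Optional[dict[tuple[int, bool], str]] = None,
    id_prefix: str = "sim",
) -> None:
    """Emit the table as coordinate-sorted SAM (SEQ/QUAL omitted by default)."""
    mate_reverse: dict[tuple[int, bool], bool] = {}
    for rid, rev, r2 in zip(table.rid.tolist(), table.reverse.tolist(), table.is_read2.tolist()):
        mate_reverse[(rid, not r2)] = rev
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for contig in table.contigs:
            fh.write(f"@SQ\tSN:{contig}\tLN:{table.contig_lengths[contig]}\n")
        for idx in range(len(table)):
            rid = int(table.rid[idx])
            r2 = bool(table.is_read2[idx])
            flag = 1 | (128 if r2 else 64)
            if table.reverse[idx]:
                flag |= 16
            mate_tid = int(table.mate_tid[idx])
            tlen = int(table.tlen[idx])
            if mate_tid < 0:
                flag |= 8
                rnext, pnext = "*", 0
            else:
                if mate_reverse.get((rid, r2), False):
                    flag |= 32
                rnext = "=" if mate_tid == int(table.tid[idx]) else table.contigs[mate_tid]
                pnext = int(table.mate_start[idx]) + 1
                if mate_tid == int(table.tid[idx]) and 0 < abs(tlen) <= 2000:
                    flag |= 2
            cl, cr = int(table.clip_left[idx]), int(table.clip_right[idx])
            match = int(table.end[idx] - table.start[idx])
            cigar = (f"{cl}S" if cl else "") + f"{match}M" + (f"{cr}S" if cr else "")
            seq = qual = "*"
            if seqs is not None:
                seq = seqs.get((rid, r2), "*")
                qual = "I" * len(seq) if seq != "*" else "*"
            fh.write(
                f"{id_prefix}{rid}\t{flag}\t{table.contigs[int(table.tid[idx])]}"
                f"\t{int(table.start[idx]) + 1}\t{int(table.mapq[idx])}\t{cigar}"
                f"\t{rnext}\t{pnext}\t{tlen}\t{seq}\t{qual}\n"
            )


def write_fastq(pairs: Sequence[SimulatedReadPair], path_r1: str, path_r2: str) -> None:
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.r1_seq}\n+\n{p.r1_qual}\n")
            f2.write(f"@{p.pair_id}/2\n{p.r2_seq}\n+\n{p.r2_qual}\n")


def write_truth_json(mocks: Sequence[MockEcDNA], path: str) -> None:
    payload = [
        {
            "id": m.id,
            "circle_length": m.circle_length,
            "segments": [
                {
                    "contig": s.interval.contig,
                    "start": s.interval.start,
                    "end": s.interval.end,
                    "strand": s.strand,
                }
                for s in m.segments
            ],
        }
        for m in mocks
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_truth_json(path: str) -> list[MockEcDNA]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        MockEcDNA(
            item["id"],
            [
                OrientedSegment(
                    GenomicInterval(s["contig"], s["start"], s["end"]), s["strand"]
                )
                for s in item["segments"]
            ],
        )
        for item in raw
    ]
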