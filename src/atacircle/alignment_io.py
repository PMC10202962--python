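"""Alignment input: read filtering, classification and coordinate conventions.

All coordinates inside the package are 0-based half-open.  SAM/BAM records
(1-based inclusive on disk, 0-based in pysam) are converted at this boundary
and the convention never leaks further in.

Two representations of the same data coexist:

* :class:`AlignedRead` — a per-record dataclass, convenient for small inputs
  and for unit-level reasoning.
* :class:`ReadTable` — a columnar (struct-of-arrays) representation used by
  the pipeline for whole-sample work.  Both are produced by the same filter
  predicate and are interconvertible.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "AlignedRead",
    "ReadClass",
    "ReadFilter",
    "ReadTable",
    "load_filtered_reads",
    "load_read_table",
    "classify_read",
    "classify_table",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contig-anchored 0-based half-open interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.contig}:{self.start}-{self.end}"


class IntervalSet:
    """Merged, sorted intervals per contig with fast overlap queries.

    Used for blacklists and repeat masks.  Query cost is O(log n) via
    binary search on the merged starts/ends.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for contig, ivs in per_contig.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[contig] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[contig] = np.array([m[1] for m in merged], dtype=np.int64)

    def __bool__(self) -> bool:
        return bool(self._starts)

    def contigs(self) -> Sequence[str]:
        return list(self._starts)

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        """Any-overlap (>= 1 bp) test."""
        starts = self._starts.get(contig)
        if starts is None:
            return False
        ends = self._ends[contig]
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and ends[i - 1] > start

    def contains(self, contig: str, start: int, end: int) -> bool:
        """Full-containment test (the strict blacklist mode)."""
        starts = self._starts.get(contig)
        if starts is None:
            return False
        ends = self._ends[contig]
        i = int(np.searchsorted(starts, start, side="right"))
        return i > 0 and ends[i - 1] >= end

    def overlaps_mask(
        self, contig: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorised any-overlap test for parallel start/end arrays."""
        bl_starts = self._starts.get(contig)
        if bl_starts is None or len(starts) == 0:
            return np.zeros(len(starts), dtype=bool)
        bl_ends = self._ends[contig]
        idx = np.searchsorted(bl_starts, ends, side="left")
        mask = idx > 0
        safe = np.maximum(idx - 1, 0)
        mask &= bl_ends[safe] > starts
        return mask

    def overlap_bases(self, contig: str, start: int, end: int) -> int:
        """Total overlapped bases between [start, end) and the set."""
        starts = self._starts.get(contig)
        if starts is None:
            return 0
        ends = self._ends[contig]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        total = 0
        for i in range(lo, hi):
            total += max(0, min(end, ends[i]) - max(start, starts[i]))
        return total

    def total_bases(self, contig: Optional[str] = None) -> int:
        if contig is not None:
            if contig not in self._starts:
                return 0
            return int((self._ends[contig] - self._starts[contig]).sum())
        return sum(int((self._ends[c] - self._starts[c]).sum()) for c in self._starts)

    @classmethod
    def from_bed(cls, path: str) -> "IntervalSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                ivs.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
        return cls(ivs)


class ReadClass(str, enum.Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    CLIPPED = "clipped"
    DISCORDANT_CLIPPED = "discordant+clipped"


@dataclass
class AlignedRead:
    """One aligned record, post-filter, in internal coordinates."""

    read_id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mapq: int
    is_duplicate: bool = False
    mate_contig: Optional[str] = None
    mate_start: int = -1
    template_length: int = 0
    clip_left: int = 0
    clip_right: int = 0
    is_proper_pair: bool = False
    is_read2: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"read {self.read_id}: end must exceed start")
        if self.clip_left < 0 or self.clip_right < 0:
            raise ValueError(f"read {self.read_id}: negative clip length")
        if self.mate_contig is not None and self.mate_contig != self.contig:
            # TLEN is undefined across contigs; normalise to 0.
            self.template_length = 0

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end)


def classify_read(
    read: AlignedRead,
    insert_threshold: int = 1500,
    inter_contig_discordant: bool = True,
) -> ReadClass:
    """Assign exactly one evidence class to a filtered read.

    A read is *discordant* when its absolute template length exceeds
    ``insert_threshold`` (strict) or, by default, when its mate maps to a
    different contig.  A read is *clipped* when any soft/hard clipping is
    present at either alignment end.  The labels compose.
    """
    discordant = abs(read.template_length) > insert_threshold
    if (
        inter_contig_discordant
        and read.mate_contig is not None
        and read.mate_contig != read.contig
    ):
        discordant = True
    clipped = (read.clip_left + read.clip_right) > 0
    if discordant and clipped:
        return ReadClass.DISCORDANT_CLIPPED
    if discordant:
        return ReadClass.DISCORDANT
    if clipped:
        return ReadClass.CLIPPED
    return ReadClass.CONCORDANT


@dataclass
class ReadFilter:
    """The record-level keep/drop predicate applied at load time."""

    mapq_min: int = 10
    blacklist: IntervalSet = field(default_factory=IntervalSet)
    blacklist_mode: str = "any"  # 'any' (>=1 bp overlap drops) or 'full'

    def keep(self, rec: pysam.AlignedSegment, contig: str) -> bool:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            return False
        if rec.is_duplicate:
            return False
        if rec.mapping_quality <= self.mapq_min:
            return False
        if self.blacklist:
            s, e = rec.reference_start, rec.reference_end
            if self.blacklist_mode == "full":
                if self.blacklist.contains(contig, s, e):
                    return False
            elif self.blacklist.overlaps(contig, s, e):
                return False
        return True

    def keep_aligned(self, read: AlignedRead) -> bool:
        """Same predicate on an already-converted read (idempotence checks)."""
        if read.is_duplicate or read.mapq <= self.mapq_min:
            return False
        if self.blacklist:
            if self.blacklist_mode == "full":
                if self.blacklist.contains(read.contig, read.start, read.end):
                    return False
            elif self.blacklist.overlaps(read.contig, read.start, read.end):
                return False
        return True


def _clips(rec: pysam.AlignedSegment) -> tuple[int, int]:
    ct = rec.cigartuples
    if not ct:
        return 0, 0
    left = ct[0][1] if ct[0][0] in (4, 5) else 0
    right = ct[-1][1] if ct[-1][0] in (4, 5) else 0
    return left, right


def _open_alignment(path: str) -> pysam.AlignmentFile:
    mode = "rb" if str(path).endswith(".bam") else "r"
    return pysam.AlignmentFile(str(path), mode, check_sq=False)


def _require_index(path: str) -> None:
    if str(path).endswith(".bam"):
        for ext in (".bai", ".csi"):
            if os.path.exists(str(path) + ext):
                return
        base = str(path)[:-4]
        if os.path.exists(base + ".bai"):
            return
        raise FileNotFoundError(f"missing BAM index for {path} (expected {path}.bai)")


def load_filtered_reads(
    bam_path: str,
    blacklist: Iterable[GenomicInterval] | IntervalSet = (),
    mapq_min: int = 10,
    blacklist_mode: str = "any",
) -> Iterator[AlignedRead]:
    """Stream filtered reads from a coordinate-sorted SAM/BAM in order.

    Emitted reads have ``mapq > mapq_min``, are not duplicates, are primary
    and mapped, and do not overlap the blacklist.  Raises on a missing BAM
    index and on the first out-of-coordinate-order record.
    """
    if not isinstance(blacklist, IntervalSet):
        blacklist = IntervalSet(blacklist)
    _require_index(bam_path)
    flt = ReadFilter(mapq_min=mapq_min, blacklist=blacklist, blacklist_mode=blacklist_mode)
    with _open_alignment(bam_path) as fh:
        last: tuple[int, int] = (-1, -1)
        for rec in fh:
            if rec.is_unmapped:
                continue
            key = (rec.reference_id, rec.reference_start)
            if key < last:
                raise ValueError(
                    f"{bam_path} is not coordinate-sorted: record {rec.query_name} "
                    f"at {rec.reference_name}:{rec.reference_start} is out of order"
                )
            last = key
            contig = rec.reference_name
            if not flt.keep(rec, contig):
                continue
            clip_left, clip_right = _clips(rec)
            mate_contig = None
            mate_start = -1
            if rec.is_paired and not rec.mate_is_unmapped and rec.next_reference_id >= 0:
                mate_contig = rec.next_reference_name
                mate_start = rec.next_reference_start
            tlen = rec.template_length
            if mate_contig is not None and mate_contig != contig:
                tlen = 0
            yield AlignedRead(
                read_id=rec.query_name,
                contig=contig,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                is_duplicate=rec.is_duplicate,
                mate_contig=mate_contig,
                mate_start=mate_start,
                template_length=tlen,
                clip_left=clip_left,
                clip_right=clip_right,
                is_proper_pair=rec.is_proper_pair,
                is_read2=rec.is_read2,
            )


class ReadTable:
    """Columnar store of filtered reads for one sample.

    ``rid`` is an interned integer identifier shared by the two mates of a
    pair (derived from the query name).  ``tid`` indexes into ``contigs``;
    ``mate_tid`` is -1 for unmapped or absent mates.
    """

    COLUMNS = (
        "rid",
        "tid",
        "start",
        "end",
        "reverse",
        "mapq",
        "tlen",
        "mate_tid",
        "mate_start",
        "clip_left",
        "clip_right",
        "is_read2",
    )

    def __init__(self, contigs: Sequence[str], contig_lengths: dict[str, int], **cols):
        self.contigs = list(contigs)
        self.contig_lengths = dict(contig_lengths)
        n = None
        for name in self.COLUMNS:
            arr = np.asarray(cols[name])
            if n is None:
                n = len(arr)
            elif len(arr) != n:
                raise ValueError(f"column {name} has length {len(arr)} != {n}")
            setattr(self, name, arr)
        self._n = n or 0

    def __len__(self) -> int:
        return self._n

    @property
    def spans(self) -> np.ndarray:
        return self.end - self.start

    def select(self, mask: np.ndarray) -> "ReadTable":
        cols = {name: getattr(self, name)[mask] for name in self.COLUMNS}
        return ReadTable(self.contigs, self.contig_lengths, **cols)

    def sort_by_coordinate(self) -> "ReadTable":
        order = np.lexsort((self.start, self.tid))
        cols = {name: getattr(self, name)[order] for name in self.COLUMNS}
        return ReadTable(self.contigs, self.contig_lengths, **cols)

    def contig_slice(self, tid: int) -> np.ndarray:
        return self.tid == tid

    @classmethod
    def from_reads(
        cls,
        reads: Iterable[AlignedRead],
        contig_lengths: dict[str, int],
    ) -> "ReadTable":
        contigs = list(contig_lengths)
        tid_of = {c: i for i, c in enumerate(contigs)}
        interner: dict[str, int] = {}
        cols: dict[str, list] = {name: [] for name in cls.COLUMNS}
        for r in reads:
            rid = interner.setdefault(r.read_id, len(interner))
            cols["rid"].append(rid)
            cols["tid"].append(tid_of[r.contig])
            cols["start"].append(r.start)
            cols["end"].append(r.end)
            cols["reverse"].append(r.strand == "-")
            cols["mapq"].append(r.mapq)
            cols["tlen"].append(r.template_length)
            cols["mate_tid"].append(
                tid_of[r.mate_contig] if r.mate_contig is not None else -1
            )
            cols["mate_start"].append(r.mate_start)
            cols["clip_left"].append(r.clip_left)
            cols["clip_right"].append(r.clip_right)
            cols["is_read2"].append(r.is_read2)
        arrays = {
            "rid": np.array(cols["rid"], dtype=np.int64),
            "tid": np.array(cols["tid"], dtype=np.int32),
            "start": np.array(cols["start"], dtype=np.int64),
            "end": np.array(cols["end"], dtype=np.int64),
            "reverse": np.array(cols["reverse"], dtype=bool),
            "mapq": np.array(cols["mapq"], dtype=np.int16),
            "tlen": np.array(cols["tlen"], dtype=np.int64),
            "mate_tid": np.array(cols["mate_tid"], dtype=np.int32),
            "mate_start": np.array(cols["mate_start"], dtype=np.int64),
            "clip_left": np.array(cols["clip_left"], dtype=np.int32),
            "clip_right": np.array(cols["clip_right"], dtype=np.int32),
            "is_read2": np.array(cols["is_read2"], dtype=bool),
        }
        return cls(contigs, contig_lengths, **arrays)


def load_read_table(
    bam_path: str,
    blacklist: Iterable[GenomicInterval] | IntervalSet = (),
    mapq_min: int = 10,
    blacklist_mode: str = "any",
) -> ReadTable:
    """Load a whole sample through the standard filters into a ReadTable."""
    with _open_alignment(bam_path) as fh:
        contig_lengths = {name: length for name, length in zip(fh.references, fh.lengths)}
    reads = load_filtered_reads(
        bam_path, blacklist=blacklist, mapq_min=mapq_min, blacklist_mode=blacklist_mode
    )
    return ReadTable.from_reads(reads, contig_lengths)


def classify_table(
    table: ReadTable,
    insert_threshold: int = 1500,
    inter_contig_discordant: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`classify_read`: (is_discordant, is_clipped) masks."""
    discordant = np.abs(table.tlen) > insert_threshold
    if inter_contig_discordant:
        discordant |= (table.mate_tid >= 0) & (table.mate_tid != table.tid)
    clipped = (table.clip_left + table.clip_right) > 0
    return discordant, clipped
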