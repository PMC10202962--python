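"""Truth matching and precision/recall/F1 scoring for the mock benchmark.

Two match criteria are supported:

* ``coverage_structure`` — the prediction covers at least ``coverage_frac``
  of the truth circle's bases and has the same ligation structure;
* ``breakpoint_ci_structure`` — same ligation structure and every truth
  breakpoint lies inside the corresponding predicted 95% credible interval.

"Same ligation structure" means a segment-wise bijection (same contig and
strand, reciprocal overlap of at least ``seg_overlap_frac``) that preserves
the cyclic adjacency order, with rotation and reversal-with-strand-flip
allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .circle_search import CircleCandidate, Junction, OrientedSegment
from .simulator import MockEcDNA

__all__ = [
    "MatchCriterion",
    "EvaluationResult",
    "same_ligation_structure",
    "truth_coverage",
    "match",
    "score",
    "write_metrics_tsv",
]


@dataclass(frozen=True)
class MatchCriterion:
    mode: str = "coverage_structure"  # or 'breakpoint_ci_structure'
    coverage_frac: float = 0.95
    seg_overlap_frac: float = 0.95

    def __post_init__(self) -> None:
        if self.mode not in ("coverage_structure", "breakpoint_ci_structure"):
            raise ValueError(f"unknown criterion mode: {self.mode}")
        if not 0 < self.coverage_frac <= 1:
            raise ValueError("coverage_frac must be in (0, 1]")


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def __add__(self, other: "EvaluationResult") -> "EvaluationResult":
        return EvaluationResult(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def _seg_tuples(segments: Sequence[OrientedSegment]) -> list[tuple]:
    return [(s.interval.contig, s.interval.start, s.interval.end, s.strand) for s in segments]


def _reflect(seq: list[tuple]) -> list[tuple]:
    return [(c, s, e, "-" if st == "+" else "+") for c, s, e, st in reversed(seq)]


def _overlap(a: tuple, b: tuple) -> int:
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


def _oriented_alignment(
    pred_seq: list[tuple], truth_seq: list[tuple], frac: float
) -> Optional[list[int]]:
    """Order-preserving bijection pred position -> truth index, or None.

    Each matched pair must share contig and strand with reciprocal overlap
    (>= frac of the truth segment and of the predicted segment).
    """
    k = len(truth_seq)
    if len(pred_seq) != k:
        return None
    mapping: list[int] = []
    used: set[int] = set()
    for p in pred_seq:
        best, best_ov = None, 0
        for ti, t in enumerate(truth_seq):
            if ti in used or t[0] != p[0] or t[3] != p[3]:
                continue
            ov = _overlap(p, t)
            t_len, p_len = t[2] - t[1], p[2] - p[1]
            if ov >= frac * t_len and ov >= frac * p_len and ov > best_ov:
                best, best_ov = ti, ov
        if best is None:
            return None
        used.add(best)
        mapping.append(best)
    for i in range(k):
        if mapping[(i + 1) % k] != (mapping[i] + 1) % k:
            return None
    return mapping


def _structure_alignment(
    pred: CircleCandidate, truth: MockEcDNA, frac: float
) -> Optional[tuple[bool, list[int], list[Junction]]]:
    """(reflected?, mapping, oriented junction list) if structures agree."""
    truth_seq = _seg_tuples(truth.segments)
    pred_seq = _seg_tuples(pred.segments)
    k = len(pred_seq)
    direct = _oriented_alignment(pred_seq, truth_seq, frac)
    if direct is not None:
        return False, direct, list(pred.junctions)
    reflected = _oriented_alignment(_reflect(pred_seq), truth_seq, frac)
    if reflected is not None:
        # junction between reflected positions p and p+1 is the original
        # junction (k-2-p) mod k with entry/exit roles swapped
        juncs = [
            Junction(
                support=pred.junctions[(k - 2 - p) % k].support,
                read_ids=pred.junctions[(k - 2 - p) % k].read_ids,
                ci_a=pred.junctions[(k - 2 - p) % k].ci_b,
                ci_b=pred.junctions[(k - 2 - p) % k].ci_a,
            )
            for p in range(k)
        ]
        return True, reflected, juncs
    return None


def same_ligation_structure(
    pred: CircleCandidate, truth: MockEcDNA, seg_overlap_frac: float = 0.95
) -> bool:
    return _structure_alignment(pred, truth, seg_overlap_frac) is not None


def truth_coverage(pred: CircleCandidate, truth: MockEcDNA) -> float:
    """Fraction of truth-circle bases covered by the predicted segments."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for s in pred.segments:
        by_contig.setdefault(s.interval.contig, []).append((s.interval.start, s.interval.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for contig, ivs in by_contig.items():
        ivs.sort()
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = [(s, e) for s, e in out]
    covered = 0
    for t in truth.segments:
        for s, e in merged.get(t.interval.contig, ()):
            covered += max(0, min(e, t.interval.end) - max(s, t.interval.start))
    return covered / truth.circle_length


def match(
    pred: CircleCandidate, truth: MockEcDNA, criterion: MatchCriterion = MatchCriterion()
) -> bool:
    alignment = _structure_alignment(pred, truth, criterion.seg_overlap_frac)
    if alignment is None:
        return False
    if criterion.mode == "coverage_structure":
        return truth_coverage(pred, truth) >= criterion.coverage_frac
    _, mapping, juncs = alignment
    truth_juncs = truth.junction_coordinates()
    for p, junction in enumerate(juncs):
        exit_coord, entry_coord = truth_juncs[mapping[p]]
        if junction.ci_a is None or junction.ci_b is None:
            return False
        if not junction.ci_a[0] <= exit_coord <= junction.ci_a[1]:
            return False
        if not junction.ci_b[0] <= entry_coord <= junction.ci_b[1]:
            return False
    return True


def score(
    preds: Sequence[CircleCandidate],
    truths: Sequence[MockEcDNA],
    criterion: MatchCriterion = MatchCriterion(),
) -> EvaluationResult:
    """Greedy one-to-one matching, best truth coverage first."""
    candidates = []
    for pi, pred in enumerate(preds):
        for ti, truth in enumerate(truths):
            if match(pred, truth, criterion):
                candidates.append((truth_coverage(pred, truth), pi, ti))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_p: set[int] = set()
    matched_t: set[int] = set()
    for _, pi, ti in candidates:
        if pi in matched_p or ti in matched_t:
            continue
        matched_p.add(pi)
        matched_t.add(ti)
    tp = len(matched_t)
    return EvaluationResult(tp=tp, fp=len(preds) - len(matched_p), fn=len(truths) - tp)


def write_metrics_tsv(results: dict[str, EvaluationResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("criterion\ttp\tfp\tfn\tprecision\trecall\tf1\n")
        for name, r in results.items():
            fh.write(
                f"{name}\t{r.tp}\t{r.fp}\t{r.fn}"
                f"\t{r.precision:.4f}\t{r.recall:.4f}\t{r.f1:.4f}\n"
            )
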