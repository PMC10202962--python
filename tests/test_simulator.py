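import numpy as np
import pytest

from atacircle.alignment_io import GenomicInterval, classify_table, load_read_table
from atacircle.circle_search import OrientedSegment
from atacircle.enrichment import pileup
from atacircle.simulator import (
    FragmentModel,
    MockEcDNA,
    Reference,
    background_pairs,
    circular_sequence,
    generate_mock_ecdna,
    load_truth_json,
    pairs_to_table,
    perfect_align,
    place_pairs,
    simulate_background,
    simulate_fragments,
    simulate_reads,
    write_fastq,
    write_sam,
    write_truth_json,
)


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _mock(reference, segs):
    return MockEcDNA(
        "m0",
        [OrientedSegment(GenomicInterval(c, s, e), st) for c, s, e, st in segs],
    )


class TestReference:
    def test_synthetic_determinism(self):
        a = Reference.synthetic(seed=5, contig_lengths={"c": 10_000})
        b = Reference.synthetic(seed=5, contig_lengths={"c": 10_000})
        assert a.sequence("c") == b.sequence("c")

    def test_n_free_intervals_match_scan(self, small_reference):
        for contig in small_reference.contigs:
            seq = small_reference.sequence(contig)
            ivs = small_reference.n_free_intervals(contig)
            assert sum(e - s for s, e in ivs) == len(seq) - seq.count("N")
            for s, e in ivs:
                assert "N" not in seq[s:e]

    def test_fasta_roundtrip(self, tmp_path, small_reference):
        path = tmp_path / "ref.fa"
        small_reference.write_fasta(str(path))
        back = Reference.from_fasta(str(path))
        assert back.lengths == small_reference.lengths
        assert back.sequence("chr1", 0, 5000) == small_reference.sequence("chr1", 0, 5000)


class TestGenerateMockEcdna:
    def test_single_segment(self, small_reference):
        mock = generate_mock_ecdna(
            small_reference, n_segments=(1, 1), segment_size=(20_000, 20_000), rng=1
        )
        assert len(mock.segments) == 1
        assert mock.circle_length == 20_000

    def test_length_conservation(self, small_reference):
        mock = generate_mock_ecdna(
            small_reference, n_segments=(3, 5), segment_size=(10_000, 30_000), rng=2
        )
        assert mock.circle_length == sum(s.length for s in mock.segments)

    def test_total_size_mode_within_range(self, small_reference):
        rng = np.random.default_rng(3)
        for _ in range(20):
            mock = generate_mock_ecdna(
                small_reference, n_segments=(1, 4), total_size=(30_000, 60_000),
                rng=rng, min_gap=5_000,
            )
            assert 30_000 <= mock.circle_length <= 60_000

    def test_segments_n_free_100_draws(self, small_reference):
        # oracle: direct N-scan of the reference sequence under each segment
        rng = np.random.default_rng(4)
        occupied = []
        for i in range(100):
            mock = generate_mock_ecdna(
                small_reference, n_segments=(1, 2), segment_size=(2_000, 6_000),
                rng=rng, min_gap=1_000, occupied=occupied, mock_id=f"m{i}",
            )
            for seg in mock.segments:
                seq = small_reference.sequence(
                    seg.interval.contig, seg.interval.start, seg.interval.end
                )
                assert "N" not in seq

    def test_min_gap_respected(self, small_reference):
        rng = np.random.default_rng(5)
        occupied = []
        mocks = [
            generate_mock_ecdna(
                small_reference, n_segments=(2, 3), segment_size=(5_000, 10_000),
                rng=rng, min_gap=20_000, occupied=occupied, mock_id=f"m{i}",
            )
            for i in range(3)
        ]
        segs = [s.interval for m in mocks for s in m.segments]
        for a in segs:
            for b in segs:
                if a is b or a.contig != b.contig:
                    continue
                gap = max(a.start, b.start) - min(a.end, b.end)
                assert gap >= 20_000

    def test_too_large_raises(self, small_reference):
        with pytest.raises(ValueError, match="too small|could not place"):
            generate_mock_ecdna(
                small_reference, n_segments=(1, 1),
                segment_size=(5_000_000, 5_000_000), rng=0,
            )


class TestCircularSequence:
    def test_plus_segment_is_reference_substring(self, small_reference):
        mock = _mock(small_reference, [("chr1", 5_000, 8_000, "+")])
        assert circular_sequence(mock, small_reference) == small_reference.sequence(
            "chr1", 5_000, 8_000
        )

    def test_minus_segment_is_revcomp(self, small_reference):
        mock = _mock(small_reference, [("chr1", 5_000, 8_000, "-")])
        assert circular_sequence(mock, small_reference) == _revcomp(
            small_reference.sequence("chr1", 5_000, 8_000)
        )

    def test_junction_and_circularity(self, small_reference):
        mock = _mock(
            small_reference,
            [("chr1", 5_000, 8_000, "+"), ("chr2", 10_000, 12_000, "-")],
        )
        circ = circular_sequence(mock, small_reference)
        assert len(circ) == 5_000
        assert circ[:3_000] == small_reference.sequence("chr1", 5_000, 8_000)
        assert circ[3_000:] == _revcomp(small_reference.sequence("chr2", 10_000, 12_000))
        # circularity: base -1 is adjacent to base 0 on the template
        doubled = circ + circ
        assert doubled[4_999:5_001] == circ[-1] + circ[0]


class TestSimulateReads:
    def test_pair_count_identity(self, small_reference):
        mock = _mock(small_reference, [("chr1", 100_000, 200_000, "+")])
        starts, lengths = simulate_fragments(mock, 30, 100, rng=0)
        assert len(starts) == 15_000  # 30 * 100000 / (2 * 100)

    def test_reads_are_substrings_of_doubled_circle(self, small_reference):
        mock = _mock(
            small_reference,
            [("chr1", 5_000, 15_000, "+"), ("chr2", 30_000, 38_000, "-")],
        )
        pairs = simulate_reads(mock, small_reference, 2, 100, rng=1)
        doubled = circular_sequence(mock, small_reference) * 2
        for p in pairs[:50]:
            assert p.r1_seq in doubled
            assert _revcomp(p.r2_seq) in doubled

    def test_fragment_bounds(self, small_reference):
        mock = _mock(small_reference, [("chr1", 100_000, 150_000, "+")])
        _, lengths = simulate_fragments(mock, 10, 100, rng=2)
        assert lengths.min() >= 100 and lengths.max() <= 1000

    def test_read_len_above_fragment_mean_raises(self, small_reference):
        mock = _mock(small_reference, [("chr1", 100_000, 150_000, "+")])
        with pytest.raises(ValueError, match="fragment mean"):
            simulate_fragments(mock, 10, 300, FragmentModel(mean=250), rng=0)

    def test_empirical_depth_near_target(self, small_reference):
        mock = _mock(small_reference, [("chr1", 100_000, 180_000, "+")])
        starts, lengths = simulate_fragments(mock, 30, 100, rng=3)
        r1, r2 = place_pairs(mock, small_reference.contigs, starts, lengths, 100)
        table = pairs_to_table(
            [(r1, r2)], small_reference.contigs, small_reference.lengths
        )
        depth = pileup(table, table.contig_lengths)["chr1"].values[100_000:180_000]
        assert depth.mean() == pytest.approx(30, rel=0.10)

    def test_error_rate_mutates(self, small_reference):
        mock = _mock(small_reference, [("chr1", 5_000, 15_000, "+")])
        clean = simulate_reads(mock, small_reference, 1, 100, rng=4)
        noisy = simulate_reads(mock, small_reference, 1, 100, error_rate=0.1, rng=4)
        diffs = sum(
            a != b for p, q in zip(clean, noisy) for a, b in zip(p.r1_seq, q.r1_seq)
        )
        assert diffs > 0


class TestBackground:
    def test_pair_count_uses_reference_length(self, small_reference):
        r1, r2 = background_pairs(small_reference, 2.0, 100, rng=0)
        total = sum(small_reference.lengths.values())
        assert len(r1["start"]) == round(2.0 * total / 200.0)

    def test_no_discordant_pairs(self, small_reference):
        table = simulate_background(small_reference, 1.0, 100, rng=1)
        disc, clip = classify_table(table)
        assert disc.sum() == 0 and clip.sum() == 0
        assert np.abs(table.tlen).max() <= 1000

    def test_mean_depth_near_target(self, small_reference):
        table = simulate_background(small_reference, 2.0, 100, rng=2)
        tracks = pileup(table, table.contig_lengths)
        total = sum(float(t.values.sum()) for t in tracks.values())
        assert total / sum(small_reference.lengths.values()) == pytest.approx(2.0, rel=0.1)

    def test_avoids_n_runs(self, small_reference):
        table = simulate_background(small_reference, 1.0, 100, rng=3)
        for contig in small_reference.contigs:
            arr = np.frombuffer(
                small_reference.sequence(contig).encode(), dtype=np.uint8
            )
            tid = small_reference.contigs.index(contig)
            sel = table.tid == tid
            for s, e in zip(table.start[sel][:200], table.end[sel][:200]):
                assert not (arr[s:e] == ord("N")).any()


class TestPerfectAlign:
    def _two_contig_mock(self, reference):
        return _mock(
            reference, [("chr1", 5_000, 15_000, "+"), ("chr2", 30_000, 38_000, "+")]
        )

    def test_read_inside_segment_unclipped(self, small_reference):
        mock = self._two_contig_mock(small_reference)
        r1, r2 = place_pairs(
            mock, small_reference.contigs, np.array([100]), np.array([250]), 100
        )
        assert r1["clip_left"][0] == 0 and r1["clip_right"][0] == 0
        assert r1["start"][0] == 5_100 and r1["end"][0] == 5_200

    def test_junction_crossing_read_clip_arithmetic(self, small_reference):
        # 100 bp read starting 40 bp before the junction at circle coord 10000:
        # aligned part is the 60 bp side (segment 2), clip length = 40
        mock = self._two_contig_mock(small_reference)
        r1, _ = place_pairs(
            mock, small_reference.contigs, np.array([9_960]), np.array([250]), 100
        )
        assert r1["tid"][0] == 1  # chr2 side won (60 > 40)
        assert r1["start"][0] == 30_000 and r1["end"][0] == 30_060
        assert r1["clip_left"][0] == 40 and r1["clip_right"][0] == 0

    def test_clip_plus_aligned_is_read_len(self, small_reference):
        mock = self._two_contig_mock(small_reference)
        starts, lengths = simulate_fragments(mock, 5, 100, rng=0)
        r1, r2 = place_pairs(mock, small_reference.contigs, starts, lengths, 100)
        for r in (r1, r2):
            assert np.all(
                (r["end"] - r["start"]) + r["clip_left"] + r["clip_right"] == 100
            )

    def test_inter_contig_pair_is_discordant(self, small_reference):
        mock = self._two_contig_mock(small_reference)
        # fragment straddling the junction: r1 in chr1, r2 in chr2
        r1, r2 = place_pairs(
            mock, small_reference.contigs, np.array([9_850]), np.array([250]), 100
        )
        table = pairs_to_table(
            [(r1, r2)], small_reference.contigs, small_reference.lengths
        )
        disc, _ = classify_table(table)
        assert disc.all()
        assert (table.tlen == 0).all()

    def test_min_align_drops_short_remainders(self, small_reference):
        mock = self._two_contig_mock(small_reference)
        # crossing read with 90/10 split: 10 bp side clipped, fine at
        # min_align 30; a 25/75 split read dies at min_align 80
        r1, _ = place_pairs(
            mock, small_reference.contigs, np.array([9_990]), np.array([250]), 100,
            min_align=30,
        )
        assert r1["mapped"][0] and r1["clip_left"][0] == 10
        r1b, _ = place_pairs(
            mock, small_reference.contigs, np.array([9_925]), np.array([250]), 100,
            min_align=80,
        )
        assert not r1b["mapped"][0]

    def test_every_junction_witnessed_at_depth(self, small_reference):
        rng = np.random.default_rng(8)
        occupied = []
        mock = generate_mock_ecdna(
            small_reference, n_segments=(3, 3), segment_size=(20_000, 40_000),
            rng=rng, occupied=occupied,
        )
        starts, lengths = simulate_fragments(mock, 10, 100, rng=rng)
        r1, r2 = place_pairs(mock, small_reference.contigs, starts, lengths, 100)
        table = pairs_to_table(
            [(r1, r2)], small_reference.contigs, small_reference.lengths
        )
        disc, _ = classify_table(table)
        tid_of = {c: i for i, c in enumerate(small_reference.contigs)}
        for exit_c, entry_c in [
            j for j in mock.junction_coordinates()
        ]:
            pass
        for i, (exit_c, entry_c) in enumerate(mock.junction_coordinates()):
            seg = mock.segments[i]
            tid = tid_of[seg.interval.contig]
            near = (
                (table.tid == tid)
                & (np.abs((table.start + table.end) // 2 - exit_c) < 1000)
                & disc
            )
            assert near.sum() >= 1, f"junction {i} unwitnessed"

    def test_object_path_agrees_with_table_path(self, small_reference):
        mock = self._two_contig_mock(small_reference)
        pairs = simulate_reads(mock, small_reference, 2, 100, rng=11)
        table = perfect_align(pairs, mock, small_reference)
        starts = np.array([p.circ_start for p in pairs])
        lengths = np.array([p.fragment_length for p in pairs])
        r1, r2 = place_pairs(mock, small_reference.contigs, starts, lengths, 100)
        direct = pairs_to_table(
            [(r1, r2)], small_reference.contigs, small_reference.lengths
        )
        assert np.array_equal(table.start, direct.start)
        assert np.array_equal(table.tlen, direct.tlen)


class TestSamOutput:
    def test_sam_roundtrip_preserves_columns(self, tmp_path, small_reference):
        mock = _mock(
            small_reference,
            [("chr1", 5_000, 15_000, "+"), ("chr2", 30_000, 38_000, "-")],
        )
        starts, lengths = simulate_fragments(mock, 5, 100, rng=6)
        r1, r2 = place_pairs(mock, small_reference.contigs, starts, lengths, 100)
        table = pairs_to_table(
            [(r1, r2)], small_reference.contigs, small_reference.lengths
        )
        path = tmp_path / "sim.sam"
        write_sam(table, str(path))
        back = load_read_table(str(path), mapq_min=0)
        assert len(back) == len(table)
        assert np.array_equal(back.start, table.start)
        assert np.array_equal(back.end, table.end)
        assert np.array_equal(back.clip_left, table.clip_left)
        assert np.array_equal(back.reverse, table.reverse)
        d1, c1 = classify_table(back)
        d2, c2 = classify_table(table)
        assert np.array_equal(d1, d2) and np.array_equal(c1, c2)

    def test_determinism_byte_identical(self, tmp_path, small_reference):
        mock = _mock(small_reference, [("chr1", 5_000, 15_000, "+")])
        outs = []
        for tag in ("a", "b"):
            pairs = simulate_reads(mock, small_reference, 2, 50, rng=7)
            fq1 = tmp_path / f"{tag}_1.fq"
            fq2 = tmp_path / f"{tag}_2.fq"
            write_fastq(pairs, str(fq1), str(fq2))
            table = perfect_align(pairs, mock, small_reference)
            sam = tmp_path / f"{tag}.sam"
            write_sam(table, str(sam))
            outs.append((fq1.read_bytes(), fq2.read_bytes(), sam.read_bytes()))
        assert outs[0] == outs[1]


class TestTruthSerialisation:
    def test_roundtrip(self, tmp_path, small_reference):
        mock = _mock(
            small_reference,
            [("chr1", 5_000, 15_000, "+"), ("chr2", 30_000, 38_000, "-")],
        )
        path = tmp_path / "truth.json"
        write_truth_json([mock], str(path))
        (back,) = load_truth_json(str(path))
        assert back.circle_length == mock.circle_length
        assert [s.strand for s in back.segments] == ["+", "-"]
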