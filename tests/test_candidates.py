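"""Pileup counting, candidate gates, callable regions, interval algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnacall.candidates import (
    compute_callable_regions,
    compute_site_pileup,
    intersect_regions,
    merge_intervals,
    scan_candidates,
)
from rnacall.formats import AlignedRead, GenomicInterval
from rnacall.simdata import expected_pileup


def _read(pos, seq, cigar=None, strand="forward", mapq=60, name="r",
          secondary=False, supplementary=False):
    return AlignedRead(
        name=name, contig="c", pos=pos, mapq=mapq, strand=strand,
        cigar=cigar or [("M", len(seq))], seq=seq,
        is_secondary=secondary, is_supplementary=supplementary,
    )


class TestSitePileup:
    def test_empty_input(self):
        site = compute_site_pileup([], "c", 5)
        assert site.DP == 0
        assert not site.counts.any()

    def test_strand_split_counts(self):
        reads = [_read(0, "AAAAA", name=f"f{i}") for i in range(3)] + [
            _read(3, "GGGGG", strand="reverse", name=f"r{i}") for i in range(2)
        ]
        site = compute_site_pileup(reads, "c", 4, ref_base="A")
        assert site.AD["A"] == 3
        assert site.AD["G"] == 2
        assert site.DP == 5

    def test_spliced_read_contributes_nothing(self):
        read = _read(0, "A" * 20, cigar=[("M", 10), ("N", 50), ("M", 10)])
        assert compute_site_pileup([read], "c", 30).DP == 0
        assert compute_site_pileup([read], "c", 5).DP == 1

    def test_deletion_counts_toward_dp(self):
        # 5M3D5M: deletion spans ref positions [5, 8)
        read = _read(0, "A" * 10, cigar=[("M", 5), ("D", 3), ("M", 5)])
        start = compute_site_pileup([read], "c", 5)
        assert start.counts.sum() == 1 and start.AD["D"] == 1
        inside = compute_site_pileup([read], "c", 6)
        assert inside.DP == 1 and inside.AD["D"] == 0

    def test_exclusions(self):
        reads = [
            _read(0, "AAAAA", mapq=4),
            _read(0, "AAAAA", secondary=True),
            _read(0, "AAAAA", supplementary=True),
            _read(0, "AAAAA"),
        ]
        assert compute_site_pileup(reads, "c", 2).DP == 1

    def test_matches_generative_oracle_everywhere(self, small_sim):
        """Engine counts equal the simulator's independent per-read
        reconstruction at every planted-event and flanking site."""
        positions = set()
        for t in small_sim.truths:
            positions.update(range(t.pos - 2, t.pos + 4))
        for e in small_sim.editing_sites:
            positions.add(e.pos)
        contig = "ctg1"
        for pos in sorted(positions):
            eng = compute_site_pileup(
                small_sim.rna_reads, contig, pos,
                ref_base=small_sim.ref[contig][pos],
            )
            orc = expected_pileup(small_sim, contig, pos)
            assert np.array_equal(eng.counts, orc.counts), pos
            assert eng.ins_seqs == orc.ins_seqs
            assert eng.del_lens == orc.del_lens


class TestScanCandidates:
    def _mixed_reads(self, n_alt, n_ref, pos=10):
        ref = {"c": "A" * 50}
        reads = [_read(0, "A" * 30, name=f"ref{i}") for i in range(n_ref)]
        alt_seq = "A" * pos + "G" + "A" * (29 - pos)
        reads += [_read(0, alt_seq, name=f"alt{i}") for i in range(n_alt)]
        return reads, ref

    def test_low_ad_excluded(self):
        # af 0.1 but AD = 1 < 2
        reads, ref = self._mixed_reads(n_alt=1, n_ref=9)
        assert scan_candidates(reads, ref) == []

    def test_low_af_excluded(self):
        # AD = 5 but af 0.05 <= 0.08
        reads, ref = self._mixed_reads(n_alt=5, n_ref=95)
        assert scan_candidates(reads, ref) == []

    def test_passing_site_found(self):
        reads, ref = self._mixed_reads(n_alt=3, n_ref=7)
        cands = scan_candidates(reads, ref)
        assert len(cands) == 1
        assert cands[0].pos == 10
        assert cands[0].minor_af == pytest.approx(0.3)

    def test_empty_alignments(self):
        assert scan_candidates([], {"c": "AAAA"}) == []

    def test_threshold_monotonicity(self, small_sim):
        """Raising any gate never increases the candidate count."""
        base = len(scan_candidates(small_sim.rna_reads, small_sim.ref))
        for kw in ({"af_threshold": 0.2}, {"min_dp": 10}, {"min_ad": 5}):
            assert (
                len(scan_candidates(small_sim.rna_reads, small_sim.ref, **kw))
                <= base
            )


class TestCallableRegions:
    def test_uniform_coverage(self):
        reads = [_read(0, "A" * 100, name=f"r{i}") for i in range(5)]
        assert compute_callable_regions(reads) == [GenomicInterval("c", 0, 100)]

    def test_dip_splits_interval(self):
        # 5x everywhere except a 1-base dip to 3x at position 3
        reads = [_read(0, "A" * 100, name=f"r{i}") for i in range(3)]
        reads += [
            _read(0, "A" * 99, cigar=[("M", 3), ("N", 1), ("M", 96)],
                  name=f"s{i}")
            for i in range(2)
        ]
        got = compute_callable_regions(reads, min_cov=4)
        assert got == [GenomicInterval("c", 0, 3), GenomicInterval("c", 4, 100)]

    def test_empty(self):
        assert compute_callable_regions([]) == []


class TestIntersect:
    def test_identity(self):
        a = [GenomicInterval("c", 0, 10), GenomicInterval("c", 20, 30)]
        assert intersect_regions(a, a) == a

    def test_partial_overlap(self):
        a = [GenomicInterval("c", 0, 100)]
        b = [GenomicInterval("c", 50, 150)]
        assert intersect_regions(a, b) == [GenomicInterval("c", 50, 100)]

    def test_disjoint(self):
        a = [GenomicInterval("c", 0, 10)]
        b = [GenomicInterval("c", 10, 20)]
        assert intersect_regions(a, b) == []

    @staticmethod
    def _bitmap(ivs, n=64):
        m = np.zeros(n, dtype=bool)
        for iv in ivs:
            m[iv.start : iv.end] = True
        return m

    @given(
        st.lists(st.tuples(st.integers(0, 60), st.integers(1, 10)), max_size=8),
        st.lists(st.tuples(st.integers(0, 60), st.integers(1, 10)), max_size=8),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_against_bitmap_oracle(self, raw_a, raw_b):
        a = merge_intervals(
            GenomicInterval("c", s, min(s + l, 64)) for s, l in raw_a
        )
        b = merge_intervals(
            GenomicInterval("c", s, min(s + l, 64)) for s, l in raw_b
        )
        got = self._bitmap(intersect_regions(a, b))
        want = self._bitmap(a) & self._bitmap(b)
        assert np.array_equal(got, want)
        # commutativity
        assert intersect_regions(a, b) == intersect_regions(b, a)
        # idempotence
        assert intersect_regions(a, a) == a
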