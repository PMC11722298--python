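"""Truth filtering, variant matching, metrics, stratification."""

import pytest

from rnacall.benchmark import (
    compute_metrics,
    filter_truth,
    match_variants,
    normalize_alleles,
    stratify,
)
from rnacall.formats import AlignedRead, GenomicInterval, TruthVariant, VariantCall


def _call(pos, ref, alts, gt="0/1", filt="PASS", contig="c"):
    return VariantCall(contig, pos, ref, alts, gt, 30.0, filt, 5, (5,))


def _truth(pos, ref, alts, gt="0/1", contig="c"):
    return TruthVariant(contig, pos, ref, tuple(alts), gt)


REGION = [GenomicInterval("c", 0, 1_000)]


class TestNormalizeAlleles:
    def test_right_padded_equals_minimal(self):
        # ATT>AT (deletion of one T, right-padded) == AT>A
        assert normalize_alleles(5, "ATT", ["AT"]) == normalize_alleles(5, "AT", ["A"])

    def test_leading_context_trimmed(self):
        # CAG>CTG is the SNP A>T at pos+1
        pos, ref, alts = normalize_alleles(10, "CAG", ["CTG"])
        assert (pos, ref, alts) == (11, "A", ("T",))

    def test_snp_unchanged(self):
        assert normalize_alleles(3, "A", ["G"]) == (3, "A", ("G",))


class TestFilterTruth:
    def _reads(self, n_alt, n_ref):
        reads = [
            AlignedRead(name=f"ref{i}", contig="c", pos=0, mapq=60,
                        strand="forward", cigar=[("M", 30)], seq="A" * 30)
            for i in range(n_ref)
        ]
        reads += [
            AlignedRead(name=f"alt{i}", contig="c", pos=0, mapq=60,
                        strand="forward", cigar=[("M", 30)],
                        seq="A" * 10 + "G" + "A" * 19)
            for i in range(n_alt)
        ]
        return reads

    def test_ad_below_two_excluded(self):
        got = filter_truth([_truth(10, "A", ["G"])], self._reads(1, 9), REGION)
        assert got == []

    def test_ad_two_kept(self):
        got = filter_truth([_truth(10, "A", ["G"])], self._reads(2, 8), REGION)
        assert len(got) == 1

    def test_outside_region_excluded(self):
        got = filter_truth(
            [_truth(10, "A", ["G"])], self._reads(5, 5),
            [GenomicInterval("c", 500, 600)],
        )
        assert got == []


class TestMatchVariants:
    def test_exact_match_is_tp(self):
        m = match_variants([_call(10, "A", ("G",))], [_truth(10, "A", ["G"])])
        assert (m.tp["Overall"], m.fp["Overall"], m.fn["Overall"]) == (1, 0, 0)
        assert m.tp["SNP"] == 1

    def test_missing_call_is_fn(self):
        m = match_variants([], [_truth(10, "A", ["G"])])
        assert m.fn["Overall"] == 1

    def test_genotype_mismatch_aware_vs_skip(self):
        calls = [_call(10, "A", ("G",), gt="1/1")]
        truths = [_truth(10, "A", ["G"], gt="0/1")]
        aware = match_variants(calls, truths)
        assert (aware.tp["Overall"], aware.fp["Overall"], aware.fn["Overall"]) == (0, 1, 1)
        skip = match_variants(calls, truths, skip_genotyping=True)
        assert (skip.tp["Overall"], skip.fp["Overall"], skip.fn["Overall"]) == (1, 0, 0)

    def test_paired_reduction_equals_mismatch_count(self):
        """skip_genotyping removes exactly one FP and one FN per
        genotype-mismatch site."""
        calls = [
            _call(10, "A", ("G",), gt="1/1"),
            _call(20, "C", ("T",), gt="0/1"),
            _call(30, "G", ("T",), gt="0/1"),  # FP: no truth
            _call(40, "T", ("C",), gt="1/1"),
        ]
        truths = [
            _truth(10, "A", ["G"], gt="0/1"),
            _truth(20, "C", ["T"], gt="0/1"),
            _truth(40, "T", ["C"], gt="0/1"),
            _truth(50, "G", ["A"], gt="0/1"),  # FN: no call
        ]
        aware = match_variants(calls, truths)
        skip = match_variants(calls, truths, skip_genotyping=True)
        k = len(aware.genotype_mismatches)
        assert k == 2
        assert aware.fp["Overall"] - skip.fp["Overall"] == k
        assert aware.fn["Overall"] - skip.fn["Overall"] == k
        assert skip.tp["Overall"] - aware.tp["Overall"] == k

    def test_indel_representation_invariance(self):
        call = _call(5, "ATT", ("AT",), gt="0/1")
        truth = _truth(5, "AT", ["A"], gt="0/1")
        m = match_variants([call], [truth])
        assert m.tp["Deletion"] == 1

    def test_low_qual_calls_ignored_by_default(self):
        m = match_variants(
            [_call(10, "A", ("G",), filt="LowQual")], [_truth(10, "A", ["G"])]
        )
        assert m.fn["Overall"] == 1 and m.fp["Overall"] == 0

    def test_duplicate_calls_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            match_variants(
                [_call(10, "A", ("G",)), _call(10, "A", ("G",))], []
            )


class TestComputeMetrics:
    def test_hand_tally(self):
        m = match_variants(
            [_call(i * 10, "A", ("G",)) for i in range(10)],
            [_truth(i * 10, "A", ["G"]) for i in range(1, 11)],
        )
        # calls at 0..90, truths at 10..100 -> 9 TP, 1 FP, 1 FN
        rep = compute_metrics(m)
        assert rep.precision["Overall"] == pytest.approx(0.9)
        assert rep.recall["Overall"] == pytest.approx(0.9)
        assert rep.f1["Overall"] == pytest.approx(0.9)

    def test_empty_is_undefined_not_zero(self):
        rep = compute_metrics(match_variants([], []))
        assert rep.precision["Overall"] is None
        assert rep.f1["SNP"] is None

    def test_perfect(self):
        rep = compute_metrics(
            match_variants([_call(10, "A", ("G",))], [_truth(10, "A", ["G"])])
        )
        assert rep.f1["Overall"] == 1.0

    def test_na_rendered_in_frame(self):
        frame = compute_metrics(match_variants([], [])).to_frame()
        assert frame["precision"].isna().all()


class TestStratify:
    def test_single_cell_matches_unstratified(self, small_sim):
        from rnacall.candidates import compute_callable_regions, intersect_regions

        regions = intersect_regions(
            compute_callable_regions(small_sim.rna_reads), small_sim.hc_regions
        )
        truths = filter_truth(small_sim.truths, small_sim.rna_reads, regions)
        calls = [
            VariantCall(t.contig, t.pos, t.ref, t.alts, t.genotype, 40.0,
                        "PASS", 5, tuple(5 for _ in t.alts))
            for t in truths
        ]
        grid = stratify(calls, truths, regions, small_sim.rna_reads, [4], [2])
        cell = grid[(4, 2)]
        assert cell.recall["Overall"] == 1.0

    def test_truth_count_monotone_in_dp(self, small_sim):
        from rnacall.candidates import compute_callable_regions, intersect_regions

        regions = intersect_regions(
            compute_callable_regions(small_sim.rna_reads), small_sim.hc_regions
        )
        truths = filter_truth(small_sim.truths, small_sim.rna_reads, regions)
        grid = stratify([], truths, regions, small_sim.rna_reads, [4, 10, 20], [2])
        def n_truth(cell):
            return cell.counts.fn["Overall"]
        assert n_truth(grid[(4, 2)]) >= n_truth(grid[(10, 2)]) >= n_truth(grid[(20, 2)])

    def test_unsorted_thresholds_rejected(self, small_sim):
        with pytest.raises(ValueError):
            stratify([], [], [], small_sim.rna_reads, [10, 4], [2])
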