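"""Zygosity switching, 21-genotype encoding, example labeling, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnacall.candidates import scan_candidates
from rnacall.labels import (
    GENOTYPE21_PAIRS,
    GENOTYPE_ALPHABET,
    N_GENOTYPE_CLASSES,
    ZygositySwitchParams,
    augment_by_subsampling,
    decode_genotype21,
    drop_hp_augmentation,
    encode_genotype21,
    infer_zygosity,
    load_examples,
    make_training_examples,
    save_examples,
)


class TestInferZygosity:
    @pytest.mark.parametrize(
        "vaf,truth,expect",
        [
            (0.95, "0/1", "1/1"),  # hom-looking het is switched
            (0.05, "0/1", "0/0"),  # unexpressed allele becomes hom-ref
            (0.5, "0/1", "0/1"),   # het branch blocked for het truth
            (0.6, "1/1", "0/1"),   # het-looking hom is switched
            (0.85, "0/1", "1/1"),  # just above hom - eps
            (0.0, "1/1", "0/0"),
            (0.5, "1/2", "0/1"),
            (0.3, "0/1", "0/1"),   # no branch fires
        ],
    )
    def test_printed_defaults(self, vaf, truth, expect):
        assert infer_zygosity(vaf, truth) == expect

    def test_brute_force_grid(self):
        """Dense VAF grid x all truth genotypes against an independent
        re-statement of the piecewise cascade."""
        p = ZygositySwitchParams()

        def oracle(vaf, gt):
            branches = [
                (p.vaf_het - p.epsilon < vaf < p.vaf_het + p.epsilon
                 and gt != "0/1", "0/1"),
                (vaf > p.vaf_hom - p.epsilon and gt != "1/1", "1/1"),
                (vaf < p.vaf_artifact, "0/0"),
            ]
            for cond, out in branches:
                if cond:
                    return out
            return gt

        for i in range(101):
            vaf = i / 100
            for gt in ("0/0", "0/1", "1/1", "1/2"):
                assert infer_zygosity(vaf, gt, p) == oracle(vaf, gt), (vaf, gt)

    def test_rejects_invalid_vaf(self):
        with pytest.raises(ValueError):
            infer_zygosity(1.5, "0/1")

    def test_overlapping_branch_params_rejected(self):
        with pytest.raises(ValueError):
            ZygositySwitchParams(epsilon=0.45)


class TestGenotype21:
    def test_class_count_is_21(self):
        classes = {
            encode_genotype21(a, b)
            for a in GENOTYPE_ALPHABET
            for b in GENOTYPE_ALPHABET
        }
        assert len(classes) == N_GENOTYPE_CLASSES == 21

    def test_order_insensitive(self):
        assert encode_genotype21("C", "G") == encode_genotype21("G", "C")

    def test_homozygous_class(self):
        assert decode_genotype21(encode_genotype21("A", "A")) == ("A", "A")

    @given(st.sampled_from(GENOTYPE21_PAIRS))
    @settings(deadline=None, derandomize=True)
    def test_bijection(self, pair):
        assert decode_genotype21(encode_genotype21(*pair)) == pair

    def test_rejects_unknown_allele(self):
        with pytest.raises(ValueError):
            encode_genotype21("A", "N")


@pytest.fixture(scope="module")
def labeled(small_sim):
    cands = scan_candidates(small_sim.rna_reads, small_sim.ref)
    edits = {(e.contig, e.pos) for e in small_sim.editing_sites}
    examples = make_training_examples(
        cands, small_sim.truths, edits, small_sim.rna_reads
    )
    return small_sim, cands, edits, examples


class TestMakeExamples:
    def test_every_candidate_labeled(self, labeled):
        _, cands, _, examples = labeled
        assert len(examples) == len(cands)

    def test_editing_sites_fold_to_hom_ref(self, labeled):
        _, _, edits, examples = labeled
        edited = [e for e in examples if (e.contig, e.pos) in edits]
        assert edited, "no candidate at a planted editing site"
        assert all(e.zygosity == 0 for e in edited)

    def test_non_truth_candidates_are_hom_ref(self, labeled):
        sim, _, edits, examples = labeled
        truth_pos = {(t.contig, t.pos) for t in sim.truths} | {
            (t.contig, t.pos + 1) for t in sim.truths
        }
        for e in examples:
            if (e.contig, e.pos) not in truth_pos | edits:
                assert e.zygosity == 0

    def test_high_vaf_het_becomes_hom_var(self, labeled):
        """A het truth expressed near-exclusively from the alt
        haplotype must carry switched (1/1) labels."""
        sim, _, _, examples = labeled
        switched = [
            e for e in examples
            if e.label is not None
            and e.label.gt_truth == "0/1"
            and e.label.vaf_o > 0.8
        ]
        assert switched, "simulation produced no allele-imbalanced het"
        assert all(e.label.gt_inferred == "1/1" for e in switched)

    def test_no_candidates_gives_empty(self, small_sim):
        assert make_training_examples([], [], set(), small_sim.rna_reads) == []

    def test_store_round_trip(self, labeled, tmp_path):
        _, _, _, examples = labeled
        path = str(tmp_path / "store.npz")
        save_examples(examples, path)
        got = load_examples(path)
        assert len(got) == len(examples)
        for a, b in zip(got, examples):
            assert (a.contig, a.pos, a.genotype21, a.zygosity) == (
                b.contig, b.pos, b.genotype21, b.zygosity
            )
            assert np.allclose(a.features, b.features)


class TestAugmentation:
    def test_fraction_one_is_identity(self, small_sim):
        subsets = augment_by_subsampling(small_sim.rna_reads, [1.0], seed=4)
        assert subsets[0] == small_sim.rna_reads

    def test_binomial_bound(self):
        reads = ["r"] * 10_000  # only count semantics matter
        kept = augment_by_subsampling(reads, [0.5], seed=4)[0]
        sigma = (10_000 * 0.25) ** 0.5
        assert abs(len(kept) - 5_000) < 3 * sigma

    def test_seed_determinism(self, small_sim):
        a = augment_by_subsampling(small_sim.rna_reads, [0.5, 0.25], seed=7)
        b = augment_by_subsampling(small_sim.rna_reads, [0.5, 0.25], seed=7)
        assert a == b

    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            augment_by_subsampling([], [0.0], seed=1)


class TestDropHp:
    def _phased_examples(self, small_sim):
        cands = scan_candidates(small_sim.rna_reads, small_sim.ref)
        return make_training_examples(
            cands, small_sim.truths, set(), small_sim.rna_reads, phasing=True
        )

    def test_probability_zero_unchanged(self, small_sim):
        ex = self._phased_examples(small_sim)
        out = drop_hp_augmentation(ex, 0.0, seed=1)
        assert all(np.array_equal(a.features, b.features) for a, b in zip(ex, out))

    def test_probability_one_zeroes_phasing_columns(self, small_sim):
        ex = self._phased_examples(small_sim)
        out = drop_hp_augmentation(ex, 1.0, seed=1)
        for a, b in zip(ex, out):
            assert not b.features[:, 18:].any()
            # unphased columns untouched
            assert np.array_equal(a.features[:, :18], b.features[:, :18])
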