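"""Network mechanics: focal loss, gradients, training contract, call logic."""

import math

import numpy as np
import pytest

from rnacall.candidates import compute_site_pileup
from rnacall.formats import AlignedRead
from rnacall.labels import TrainingExample, encode_genotype21
from rnacall.model import (
    NetworkConfig,
    PileupNetwork,
    _focal_batch_loss,
    _focal_dlogits,
    decide_call,
    focal_loss,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)

TINY = NetworkConfig(input_features=4, hidden_size=3, dense_sizes=(5, 4), window=5)


class TestFocalLoss:
    def test_gamma_zero_is_cross_entropy(self):
        p = np.array([0.2, 0.5, 0.3])
        y = np.array([0.0, 1.0, 0.0])
        assert focal_loss(p, y, gamma=0.0) == pytest.approx(-math.log(0.5))

    def test_perfect_prediction_is_zero(self):
        p = np.array([0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0])
        assert focal_loss(p, y, gamma=2.0) == pytest.approx(0.0)

    def test_closed_form_half(self):
        # p_true = 0.5, gamma = 2: 0.25 * ln 2
        p = np.array([0.5, 0.5])
        y = np.array([1.0, 0.0])
        assert focal_loss(p, y, gamma=2.0) == pytest.approx(0.25 * math.log(2))

    def test_zero_probability_is_finite(self):
        p = np.array([0.0, 1.0])
        y = np.array([1.0, 0.0])
        assert np.isfinite(focal_loss(p, y, gamma=2.0))

    def test_monotone_in_p_true(self):
        grid = np.linspace(0.01, 0.99, 50)
        losses = [
            focal_loss(np.array([p, 1 - p]), np.array([1.0, 0.0]), gamma=2.0)
            for p in grid
        ]
        assert all(a >= b for a, b in zip(losses, losses[1:]))

    def test_class_weights_scale(self):
        p = np.array([0.5, 0.5])
        y = np.array([1.0, 0.0])
        w = np.array([2.0, 1.0])
        assert focal_loss(p, y, 2.0, w) == pytest.approx(2 * 0.25 * math.log(2))


class TestBackprop:
    def test_gradients_match_numerical(self):
        """Analytic gradients through both heads, the dense stack and
        both Bi-LSTM layers agree with central differences."""
        net = PileupNetwork(TINY, seed=0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, 5, 4))
        yg = np.array([0, 20, 7])
        yz = np.array([0, 2, 1])

        def loss():
            pg, pz = net.forward(x)
            return _focal_batch_loss(pg, yg, 2.0) + _focal_batch_loss(pz, yz, 2.0)

        pg, pz, cache = net.forward(x, want_cache=True)
        grads = net.backward(
            _focal_dlogits(pg, yg, 2.0), _focal_dlogits(pz, yz, 2.0), cache
        )
        eps = 1e-6
        for name, g in grads.items():
            flat = net.params[name].reshape(-1)
            for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = g.reshape(-1)[i]
                assert abs(num - ana) <= 1e-3 * max(1.0, abs(num)), name


def _toy_examples(n=60, seed=0):
    """Separable toy set: class decided by which feature is hot."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cls = i % 3
        feats = rng.poisson(1.0, size=(5, 4)).astype(float)
        feats[:, cls] += 20
        out.append(
            TrainingExample(
                contig="c", pos=i, features=feats,
                genotype21=cls, zygosity=cls % 3,
            )
        )
    return out


class TestTrain:
    def test_overfits_small_set(self):
        cfg = NetworkConfig(
            input_features=4, hidden_size=8, dense_sizes=(8, 8), window=5,
            learning_rate=5e-2, batch_size=8,
        )
        examples = _toy_examples(50)
        net, tlog = train(examples, cfg, seed=0)
        probs = predict(net, [e.features for e in examples])
        acc = np.mean(
            [p[0].argmax() == e.genotype21 for p, e in zip(probs, examples)]
        )
        assert acc > 0.9
        assert tlog.train_losses[-1] < 0.1

    def test_epoch_bound(self):
        cfg = NetworkConfig(
            input_features=4, hidden_size=4, dense_sizes=(4, 4), window=5,
            max_epochs=30,
        )
        _, tlog = train(_toy_examples(30), cfg, seed=0)
        assert tlog.epochs_run <= 30

    def test_seed_determinism(self):
        cfg = NetworkConfig(
            input_features=4, hidden_size=4, dense_sizes=(4, 4), window=5,
            max_epochs=3,
        )
        _, log_a = train(_toy_examples(30), cfg, seed=5)
        _, log_b = train(_toy_examples(30), cfg, seed=5)
        assert log_a.val_losses == log_b.val_losses

    def test_empty_examples_rejected(self):
        with pytest.raises(ValueError):
            train([], TINY, seed=0)


class TestPredict:
    def test_heads_are_distributions(self):
        net = PileupNetwork(TINY, seed=0)
        rng = np.random.default_rng(0)
        probs = predict(net, list(rng.poisson(3, size=(4, 5, 4))))
        for pg, pz in probs:
            assert pg.shape == (21,) and pz.shape == (3,)
            assert pg.sum() == pytest.approx(1.0, abs=1e-6)
            assert pz.sum() == pytest.approx(1.0, abs=1e-6)

    def test_order_preserved_and_identical_inputs_agree(self):
        net = PileupNetwork(TINY, seed=0)
        x = np.random.default_rng(1).poisson(3, size=(5, 4)).astype(float)
        probs = predict(net, [x, x.copy(), x * 2])
        assert np.allclose(probs[0][0], probs[1][0])
        assert not np.allclose(probs[0][0], probs[2][0])

    def test_width_mismatch_rejected(self):
        net = PileupNetwork(TINY, seed=0)
        with pytest.raises(ValueError, match="expected input"):
            predict(net, [np.zeros((5, 7))])


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        net = PileupNetwork(TINY, seed=3)
        path = str(tmp_path / "model.ckpt.npz")
        save_checkpoint(net, path)
        got = load_checkpoint(path)
        assert got.config == net.config
        x = np.random.default_rng(0).poisson(2, size=(2, 5, 4)).astype(float)
        a = net.forward(net.standardize(x))
        b = got.forward(got.standardize(x))
        assert np.allclose(a[0], b[0]) and np.allclose(a[1], b[1])


def _pileup(reads, pos, ref_base):
    return compute_site_pileup(reads, "c", pos, ref_base=ref_base)


def _probs(pair_idx, zyg, p=0.9):
    pg = np.full(21, (1 - p) / 20)
    pg[pair_idx] = p
    pz = np.full(3, (1 - p) / 2)
    pz[zyg] = p
    return pg, pz


class TestDecideCall:
    def _het_reads(self):
        reads = [
            AlignedRead(name=f"r{i}", contig="c", pos=0, mapq=60,
                        strand="forward", cigar=[("M", 20)],
                        seq="A" * 10 + "G" + "A" * 9)
            for i in range(5)
        ]
        reads += [
            AlignedRead(name=f"a{i}", contig="c", pos=0, mapq=60,
                        strand="forward", cigar=[("M", 20)], seq="A" * 20)
            for i in range(5)
        ]
        return reads

    def test_hom_ref_argmax_emits_nothing(self):
        pile = _pileup(self._het_reads(), 10, "A")
        probs = _probs(encode_genotype21("A", "A"), 0)
        assert decide_call(probs, pile) is None

    def test_het_snp_call(self):
        pile = _pileup(self._het_reads(), 10, "A")
        probs = _probs(encode_genotype21("A", "G"), 1)
        call = decide_call(probs, pile, ref_seq="A" * 20)
        assert call is not None
        assert (call.ref, call.alts, call.genotype) == ("A", ("G",), "0/1")
        assert call.alt_depths == (5,)

    def test_low_qual_threshold_by_platform(self):
        # genotype mass split between het-G and hom-ref: the call wins
        # but substantial hom-ref mass keeps QUAL in (2, 8)
        pile = _pileup(self._het_reads(), 10, "A")
        pg = np.full(21, 0.2 / 19)
        pg[encode_genotype21("A", "G")] = 0.5
        pg[encode_genotype21("A", "A")] = 0.3
        pz = np.array([0.4, 0.5, 0.1])
        ont = decide_call((pg, pz), pile, platform="ont")
        pacbio = decide_call((pg, pz), pile, platform="pacbio")
        assert 2 < ont.qual < 8
        assert ont.filter == "LowQual"
        assert pacbio.filter == "PASS"

    def test_unsupported_alleles_never_emitted(self):
        """Mass on alleles without read support is renormalized away:
        the call falls back to the supported alternate, never inventing
        a T or an insertion the reads do not show."""
        pile = _pileup(self._het_reads(), 10, "A")
        probs = _probs(encode_genotype21("A", "T"), 1)  # no T in reads
        call = decide_call(probs, pile)
        assert call is None or call.alts == ("G",)
        probs = _probs(encode_genotype21("A", "I"), 1)  # no insertions
        call = decide_call(probs, pile)
        assert call is None or call.alts == ("G",)

    def test_deletion_reanchored_left(self):
        reads = [
            AlignedRead(name=f"d{i}", contig="c", pos=0, mapq=60,
                        strand="forward", cigar=[("M", 10), ("D", 2), ("M", 8)],
                        seq="A" * 18)
            for i in range(6)
        ]
        ref_seq = "A" * 10 + "CG" + "A" * 8
        pile = _pileup(reads, 10, "C")  # first deleted base
        probs = _probs(encode_genotype21("D", "D"), 2)
        call = decide_call(probs, pile, ref_seq=ref_seq)
        assert call.pos == 9
        assert (call.ref, call.alts, call.genotype) == ("ACG", ("A",), "1/1")
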