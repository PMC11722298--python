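"""Training-label engineering for RNA-derived candidates.

RNA alignments do not show variants at their DNA allele fractions:
allele-biased expression and isoform structure make a heterozygous DNA
variant look homozygous (either way) in RNA, and A-to-I editing plants
A>G / T>C mismatches with no DNA counterpart. Labels are therefore
built from an *inferred* genotype — the DNA truth genotype switched
when the observed RNA allele fraction contradicts it — and benchmark
editing sites are folded into the homozygous-reference class so the
network learns to call them non-variant.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .candidates import CandidateSite
from .formats import AlignedRead, TruthVariant
from .tensors import (
    PileupTensor,
    attach_phasing_features,
    build_pileup_tensor,
    CoverageCap,
    normalize_tensor,
)

log = logging.getLogger("rnacall")

# ---------------------------------------------------------------------------
# Zygosity switching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZygositySwitchParams:
    """Expected allele fractions for het/hom variants and artifacts,
    with tolerance epsilon around them."""

    vaf_het: float = 0.5
    vaf_hom: float = 1.0
    vaf_artifact: float = 0.08
    epsilon: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.vaf_artifact < self.vaf_het - self.epsilon:
            raise ValueError("artifact fraction overlaps het branch")
        if self.vaf_het + self.epsilon > self.vaf_hom - self.epsilon + 1e-12:
            raise ValueError("het and hom branches overlap")


GENOTYPES = ("0/0", "0/1", "1/1", "1/2")


def infer_zygosity(
    vaf_o: float,
    gt_truth: str,
    params: ZygositySwitchParams = ZygositySwitchParams(),
) -> str:
    """Switch a truth genotype when the observed RNA VAF contradicts it.

    First-match cascade: (1) a fraction within epsilon of the het
    expectation, on a non-het truth, becomes 0/1; (2) a fraction above
    the hom expectation minus epsilon, on a non-hom-var truth, becomes
    1/1; (3) a fraction below the artifact level becomes 0/0; else the
    truth genotype stands.
    """
    if not 0 <= vaf_o <= 1:
        raise ValueError(f"VAF {vaf_o} outside [0, 1]")
    p = params
    if (p.vaf_het - p.epsilon) < vaf_o < (p.vaf_het + p.epsilon) and gt_truth != "0/1":
        return "0/1"
    if vaf_o > (p.vaf_hom - p.epsilon) and gt_truth != "1/1":
        return "1/1"
    if vaf_o < p.vaf_artifact:
        return "0/0"
    return gt_truth


def zygosity_class(genotype: str) -> int:
    """3-class zygosity: 0 hom-ref, 1 het (0/1 and 1/2), 2 hom-var."""
    return {"0/0": 0, "0/1": 1, "1/2": 1, "1/1": 2}[genotype]


ZYGOSITY_NAMES = ("hom-ref", "het", "hom-var")

# ---------------------------------------------------------------------------
# 21-genotype encoding
# ---------------------------------------------------------------------------

GENOTYPE_ALPHABET = ("A", "C", "G", "T", "I", "D")  # I=insertion, D=deletion

#: the 21 unordered pairs over the 6-symbol alphabet, canonical order
GENOTYPE21_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations_with_replacement(GENOTYPE_ALPHABET, 2)
)
_PAIR_TO_CLASS = {p: i for i, p in enumerate(GENOTYPE21_PAIRS)}
N_GENOTYPE_CLASSES = len(GENOTYPE21_PAIRS)  # 21
N_ZYGOSITY_CLASSES = 3


def encode_genotype21(allele_a: str, allele_b: str) -> int:
    """Class index of an unordered allele pair (6 homozygous + 15 het)."""
    for a in (allele_a, allele_b):
        if a not in GENOTYPE_ALPHABET:
            raise ValueError(f"allele {a!r} outside alphabet {GENOTYPE_ALPHABET}")
    key = tuple(
        sorted((allele_a, allele_b), key=GENOTYPE_ALPHABET.index)
    )
    return _PAIR_TO_CLASS[key]


def decode_genotype21(class_index: int) -> tuple[str, str]:
    return GENOTYPE21_PAIRS[class_index]


def allele_symbol(ref: str, alt: str) -> str:
    """Collapse an allele to the 6-symbol alphabet: base, I(ns) or D(el)."""
    if len(ref) == 1 and len(alt) == 1:
        return alt
    return "I" if len(alt) > len(ref) else "D"


def candidate_position(variant) -> int:
    """Pileup position where a VCF-anchored variant shows up in the scan.

    SNPs and insertions surface at their VCF position; a deletion is
    counted at its first deleted base, one right of the VCF anchor.
    """
    if len(variant.ref) > 1 and any(len(a) < len(variant.ref) for a in variant.alts):
        return variant.pos + 1
    return variant.pos


# ---------------------------------------------------------------------------
# Labeled examples
# ---------------------------------------------------------------------------

@dataclass
class TruthLabel:
    gt_truth: str
    vaf_o: float
    gt_inferred: str
    genotype21: int
    zygosity: int


@dataclass
class TrainingExample:
    contig: str
    pos: int
    features: np.ndarray  # (33, 18) or (33, 30)
    genotype21: int
    zygosity: int
    label: Optional[TruthLabel] = None


def _genotype_alleles(ref_base: str, alt_syms: Sequence[str], gt: str) -> tuple[str, str]:
    """Allele pair (in the 6-symbol alphabet) realizing a genotype."""
    symbols = (ref_base,) + tuple(alt_syms)
    i, j = (int(x) for x in gt.split("/"))
    return symbols[i], symbols[j]


def label_candidate(
    cand: CandidateSite,
    truth: Optional[TruthVariant],
    is_editing_site: bool,
    params: ZygositySwitchParams = ZygositySwitchParams(),
) -> Optional[TruthLabel]:
    """Label one candidate: editing sites and artifacts fold into
    hom-ref; truth-matched candidates go through zygosity switching.

    Returns None for a truth site with no qualifying coverage (such a
    site is unusable for training).
    """
    pile = cand.pileup
    ref_base = pile.ref_base
    hom_ref = TruthLabel(
        gt_truth="0/0",
        vaf_o=0.0,
        gt_inferred="0/0",
        genotype21=encode_genotype21(ref_base, ref_base),
        zygosity=0,
    )
    if is_editing_site or truth is None:
        if truth is None and is_editing_site is False:
            # artifact candidate: hom-ref, but record its observed VAF
            hom_ref.vaf_o = cand.minor_af
        return hom_ref

    dp = pile.DP
    if dp == 0:
        log.info(
            "truth %s:%d has no qualifying coverage; skipped",
            truth.contig, truth.pos,
        )
        return None
    ad = pile.AD
    alt_syms = [allele_symbol(truth.ref, a) for a in truth.alts]
    gt = truth.genotype
    if gt == "1/2" and len(alt_syms) == 2:
        fracs = [ad.get(s, 0) / dp for s in alt_syms]
        surviving = [i for i, f in enumerate(fracs) if f >= params.vaf_artifact]
        if len(surviving) == 2:
            vaf_o = sum(fracs)
            return TruthLabel(
                gt_truth=gt,
                vaf_o=vaf_o,
                gt_inferred="1/2",
                genotype21=encode_genotype21(alt_syms[0], alt_syms[1]),
                zygosity=1,
            )
        if len(surviving) == 1:
            # one alt is missing in RNA: re-infer as a bi-allelic case
            alt_syms = [alt_syms[surviving[0]]]
            gt = "0/1"
        else:
            return hom_ref
    vaf_o = min(ad.get(alt_syms[0], 0) / dp, 1.0)
    gt_inf = infer_zygosity(vaf_o, gt, params)
    pair = _genotype_alleles(ref_base, alt_syms, gt_inf)
    return TruthLabel(
        gt_truth=truth.genotype,
        vaf_o=vaf_o,
        gt_inferred=gt_inf,
        genotype21=encode_genotype21(*pair),
        zygosity=zygosity_class(gt_inf),
    )


def make_training_examples(
    candidates: Sequence[CandidateSite],
    truths: Sequence[TruthVariant],
    editing_sites: Iterable[tuple[str, int]],
    alignments: Sequence[AlignedRead],
    params: ZygositySwitchParams = ZygositySwitchParams(),
    phasing: bool = False,
    cap: Optional[CoverageCap] = None,
) -> list[TrainingExample]:
    """Assemble labeled tensors for training.

    Truth-matched candidates are labeled through zygosity switching on
    their observed VAF; remaining candidates (which already passed the
    DP/AD/AF artifact gates during scanning) and benchmark editing
    sites are labeled homozygous-reference.
    """
    from .phasing import extract_haplotype_counts
    from .formats import GenomicInterval
    from .tensors import WINDOW_FLANK

    truth_by_pos = {(t.contig, candidate_position(t)): t for t in truths}
    editing = set(editing_sites)
    by_contig: dict[str, list[AlignedRead]] = {}
    for r in alignments:
        by_contig.setdefault(r.contig, []).append(r)

    out: list[TrainingExample] = []
    for cand in candidates:
        key = (cand.contig, cand.pos)
        label = label_candidate(
            cand, truth_by_pos.get(key), key in editing, params
        )
        if label is None:
            continue
        reads = by_contig.get(cand.contig, [])
        window_reads = [
            r for r in reads
            if r.pos < cand.pos + WINDOW_FLANK + 1
            and r.reference_end > cand.pos - WINDOW_FLANK
        ]
        tensor = build_pileup_tensor(cand, window_reads)
        if phasing:
            win = GenomicInterval(
                cand.contig,
                max(cand.pos - WINDOW_FLANK, 0),
                cand.pos + WINDOW_FLANK + 1,
            )
            hap = extract_haplotype_counts(window_reads, win)
            full = np.zeros((2 * WINDOW_FLANK + 1, hap.shape[1]), dtype=np.int64)
            off = win.start - (cand.pos - WINDOW_FLANK)
            full[off : off + hap.shape[0]] = hap
            tensor = attach_phasing_features(tensor, full)
        if cap is not None:
            tensor = normalize_tensor(tensor, cap)
        out.append(
            TrainingExample(
                contig=cand.contig,
                pos=cand.pos,
                features=tensor.features,
                genotype21=label.genotype21,
                zygosity=label.zygosity,
                label=label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment_by_subsampling(
    alignments: Sequence[AlignedRead],
    fractions: Sequence[float],
    seed: int,
) -> list[list[AlignedRead]]:
    """Per-read Bernoulli subsampling at each coverage fraction.

    HP tags assigned on the full-coverage alignment travel with the
    kept reads, so subsampled sets stay haplotagged without re-phasing.
    """
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
    out = []
    for i, f in enumerate(fractions):
        if f == 1.0:
            out.append(list(alignments))
            continue
        rng = np.random.default_rng((seed, i))
        keep = rng.random(len(alignments)) < f
        out.append([r for r, k in zip(alignments, keep) if k])
    return out


def drop_hp_augmentation(
    examples: Sequence[TrainingExample],
    drop_probability: float,
    seed: int,
) -> list[TrainingExample]:
    """Randomly strip haplotype information from phased examples.

    For each selected example the 12 phasing feature columns are
    zeroed — equivalent to recomputing them with every HP tag removed —
    while the 18 unphased columns are untouched. Emulates the phasing
    signal loss seen at low coverage.
    """
    if not 0 <= drop_probability <= 1:
        raise ValueError("drop probability outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for ex in examples:
        if ex.features.shape[1] <= 18 or rng.random() >= drop_probability:
            out.append(ex)
            continue
        feats = ex.features.copy()
        feats[:, 18:] = 0
        out.append(
            TrainingExample(
                contig=ex.contig,
                pos=ex.pos,
                features=feats,
                genotype21=ex.genotype21,
                zygosity=ex.zygosity,
                label=ex.label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Example store
# ---------------------------------------------------------------------------

STORE_VERSION = 1


def save_examples(examples: Sequence[TrainingExample], path: str) -> None:
    """Persist examples as a versioned .npz with a JSON manifest."""
    feats = np.stack([ex.features for ex in examples]).astype(np.float32)
    manifest = {
        "version": STORE_VERSION,
        "n": len(examples),
        "feature_shape": list(feats.shape[1:]),
        "keys": [[ex.contig, ex.pos] for ex in examples],
    }
    np.savez_compressed(
        path,
        features=feats,
        genotype21=np.array([ex.genotype21 for ex in examples], dtype=np.int64),
        zygosity=np.array([ex.zygosity for ex in examples], dtype=np.int64),
        manifest=np.frombuffer(
            json.dumps(manifest).encode(), dtype=np.uint8
        ),
    )


def load_examples(path: str) -> list[TrainingExample]:
    with np.load(path) as z:
        manifest = json.loads(bytes(z["manifest"]).decode())
        if manifest["version"] != STORE_VERSION:
            raise ValueError(f"unsupported store version {manifest['version']}")
        feats = z["features"]
        g21 = z["genotype21"]
        zyg = z["zygosity"]
        keys = manifest["keys"]
    return [
        TrainingExample(
            contig=keys[i][0],
            pos=int(keys[i][1]),
            features=feats[i],
            genotype21=int(g21[i]),
            zygosity=int(zyg[i]),
        )
        for i in range(len(keys))
    ]
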