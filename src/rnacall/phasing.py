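"""Haplotype-tag consumption.

Variant phasing and read haplotagging themselves are upstream concerns
(reads arrive with integer ``HP`` tags); this module turns those tags
into per-position haplotype counts for the phased tensor, reports
haplotagging statistics, and selects the heterozygous SNPs used for
phasing.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .candidates import (
    DEFAULT_MIN_MAPQ,
    N_HAP_FEATURES,
    RegionPileup,
    qualifies,
)
from .formats import AlignedRead, GenomicInterval, TruthVariant, VariantCall


def extract_haplotype_counts(
    reads: Iterable[AlignedRead],
    window: GenomicInterval,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> np.ndarray:
    """Per-position haplotype counts over a window.

    Returns a (len(window), 12) grid: [A,C,G,T,I,D] for HP=1 then HP=2,
    strand-agnostic; untagged reads contribute to neither haplotype.
    Indels count at their start position, mirroring the unphased
    I_S/D_S convention.
    """
    rp = RegionPileup(
        reads,
        window.contig,
        window.start,
        window.end,
        min_mapq=min_mapq,
        track_haplotypes=True,
    )
    return rp.hap_counts


@dataclass
class HaplotagReport:
    total_qualifying_reads: int
    tagged_reads: int
    per_contig: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def tagged_fraction(self) -> float:
        if self.total_qualifying_reads == 0:
            return 0.0
        return self.tagged_reads / self.total_qualifying_reads


def haplotag_statistics(
    alignments: Iterable[AlignedRead], min_mapq: int = DEFAULT_MIN_MAPQ
) -> HaplotagReport:
    """Fraction of haplotagged reads among qualifying reads.

    Both numerator and denominator exclude supplementary reads,
    secondary reads, and reads with mapping quality below 5.
    """
    per_contig: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    total = tagged = 0
    for r in alignments:
        if not qualifies(r, min_mapq):
            continue
        total += 1
        per_contig[r.contig][0] += 1
        if r.hp in (1, 2):
            tagged += 1
            per_contig[r.contig][1] += 1
    return HaplotagReport(
        total_qualifying_reads=total,
        tagged_reads=tagged,
        per_contig={c: (t, g) for c, (t, g) in sorted(per_contig.items())},
    )


def select_phasing_variants(
    calls: Sequence[VariantCall],
    truths: Optional[Sequence[TruthVariant]] = None,
) -> list[VariantCall]:
    """Heterozygous SNPs to phase on.

    Training mode (truths given): only het SNPs present in both the
    call set and the truth set (matching position and alleles) — this
    keeps false positives out of the phasing signal. Inference mode
    (no truths): het SNP calls from the first calling round.
    """
    het_snps = [c for c in calls if c.is_snp and c.is_het]
    if truths is None:
        return het_snps
    truth_keys = {
        (t.contig, t.pos, t.ref, t.alts)
        for t in truths
        if t.is_snp and t.genotype in ("0/1", "1/2")
    }
    return [
        c for c in het_snps if (c.contig, c.pos, c.ref, c.alts) in truth_keys
    ]
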