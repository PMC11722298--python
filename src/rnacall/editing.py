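"""A-to-I editing: orthogonal benchmark generation and call tagging.

A-to-I editing appears in alignments as A>G on one reference strand
and T>C on the other, and is indistinguishable from a germline SNP
from RNA alone. Two complementary mechanisms are provided: (1) an
orthogonal benchmark built by cross-validating RNA mismatch sites
against paired DNA alignments — a site edited in RNA shows the edited
allele at high fraction in RNA but (unlike a germline variant) at
background fraction in DNA; (2) tagging of called variants against a
known-editing-site database (REDIportal-style), requiring agreement of
at least two constituent sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .candidates import (
    DEFAULT_MIN_MAPQ,
    RegionPileup,
    _contig_span,
)
from .formats import AlignedRead, EditingDB, VariantCall

log = logging.getLogger("rnacall")

#: the two A-to-I substitution representations
EDITING_PAIRS = (("A", "G"), ("T", "C"))


@dataclass(frozen=True)
class EditingParams:
    """Depth/fraction gates of the orthogonal benchmark rule."""

    mdp: int = 8  # minimal coverage depth, RNA and DNA
    maf_r: float = 0.75  # minimal RNA edited-allele fraction
    maf_d: float = 0.08  # maximal DNA edited-allele fraction

    def __post_init__(self) -> None:
        if self.mdp < 1 or not 0 < self.maf_d < self.maf_r <= 1:
            raise ValueError("invalid editing benchmark parameters")


@dataclass
class EditingEvidence:
    contig: str
    pos: int
    ref: str  # A or T
    edited_alt: str  # G or C
    dp_r: int
    vaf_r: float
    dp_d: int
    vaf_d: float
    verdict: bool = False


def decide_editing(evidence: EditingEvidence, params: EditingParams = EditingParams()) -> bool:
    """isEditing: true iff DP_R >= MDP and VAF_R >= MAF_R and
    DP_D >= MDP and VAF_D < MAF_D."""
    return (
        evidence.dp_r >= params.mdp
        and evidence.vaf_r >= params.maf_r
        and evidence.dp_d >= params.mdp
        and evidence.vaf_d < params.maf_d
    )


def build_editing_benchmark(
    rna_alignments: Sequence[AlignedRead],
    dna_alignments: Sequence[AlignedRead],
    ref: dict[str, str],
    params: EditingParams = EditingParams(),
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[EditingEvidence]:
    """Scan RNA pileups for A>G / T>C sites and cross-check them in DNA.

    Keeps verdict-true sites only, in (contig, pos) order. Contigs with
    RNA but no DNA coverage are skipped with a warning.
    """
    rna_by_contig: dict[str, list[AlignedRead]] = {}
    dna_by_contig: dict[str, list[AlignedRead]] = {}
    for r in rna_alignments:
        rna_by_contig.setdefault(r.contig, []).append(r)
    for r in dna_alignments:
        dna_by_contig.setdefault(r.contig, []).append(r)

    out: list[EditingEvidence] = []
    for contig in sorted(rna_by_contig):
        if contig not in dna_by_contig:
            log.warning("contig %s has RNA but no DNA alignments; skipped", contig)
            continue
        seq = ref.get(contig, "")
        rna_reads = rna_by_contig[contig]
        start, end = _contig_span(rna_reads)
        rna = RegionPileup(rna_reads, contig, start, end, min_mapq=min_mapq)
        dna_reads = dna_by_contig[contig]
        d_start, d_end = _contig_span(dna_reads)
        dna = RegionPileup(dna_reads, contig, d_start, d_end, min_mapq=min_mapq)
        rna_dp = rna.depth()
        for i in range(end - start):
            pos = start + i
            if pos >= len(seq):
                continue
            ref_base = seq[pos]
            alt = dict(EDITING_PAIRS).get(ref_base)
            if alt is None:
                continue
            dp_r = int(rna_dp[i])
            if dp_r < params.mdp:
                continue
            site_r = rna.site(pos, ref_base)
            ad_r = site_r.AD.get(alt, 0)
            vaf_r = ad_r / dp_r if dp_r else 0.0
            if vaf_r < params.maf_r:
                continue
            if d_start <= pos < d_end:
                site_d = dna.site(pos, ref_base)
                dp_d = site_d.DP
                vaf_d = site_d.AD.get(alt, 0) / dp_d if dp_d else 0.0
            else:
                dp_d, vaf_d = 0, 0.0
            ev = EditingEvidence(
                contig=contig, pos=pos, ref=ref_base, edited_alt=alt,
                dp_r=dp_r, vaf_r=vaf_r, dp_d=dp_d, vaf_d=vaf_d,
            )
            ev.verdict = decide_editing(ev, params)
            if ev.verdict:
                out.append(ev)
    return out


def tag_rediportal(
    calls: Iterable[VariantCall],
    editing_db: EditingDB,
    min_sources: int = 2,
) -> list[VariantCall]:
    """Retag calls matching a known A>G / T>C editing site as RNAEditing.

    A call is retagged iff its (contig, pos, ref, alt) matches a
    database entry whose source agreement is at least min_sources;
    other calls keep their filter value.
    """
    out = []
    for call in calls:
        entry = editing_db.lookup(call.contig, call.pos)
        if (
            entry is not None
            and entry.source_count >= min_sources
            and call.ref == entry.ref
            and entry.alt in call.alts
        ):
            call = VariantCall(
                contig=call.contig, pos=call.pos, ref=call.ref,
                alts=call.alts, genotype=call.genotype, qual=call.qual,
                filter="RNAEditing", ref_depth=call.ref_depth,
                alt_depths=call.alt_depths,
            )
        out.append(call)
    return out


def editing_overlap_report(
    false_positive_calls: Iterable[tuple],
    benchmark_sites: Iterable[tuple],
    editing_db: EditingDB,
) -> dict[str, int]:
    """Cardinalities of the 7 regions of the three-set Venn diagram:
    known DB editing sites, A>G/T>C false-positive calls, and the
    orthogonal benchmark set, keyed by (contig, pos, ref, alt)."""
    db = {(e.contig, e.pos, e.ref, e.alt) for e in editing_db}
    fp = set(false_positive_calls)
    bm = set(benchmark_sites)
    return {
        "db_only": len(db - fp - bm),
        "fp_only": len(fp - db - bm),
        "benchmark_only": len(bm - db - fp),
        "db_fp": len((db & fp) - bm),
        "db_benchmark": len((db & bm) - fp),
        "fp_benchmark": len((fp & bm) - db),
        "db_fp_benchmark": len(db & fp & bm),
    }
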