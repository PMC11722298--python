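"""Gene-level evaluation: coverage overlap, error-free genes, phasing.

RNA-seq only covers expressed exons, so calling performance is best
summarized per annotated gene: how much of each gene lies inside the
callable high-confidence regions (overlap ratio H), whether the gene
is free of SNP/indel errors, whether it is wholly contained in one
phaseset, and how many switch errors its phased het variants show.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .benchmark import MatchResult
from .formats import GenomicInterval


@dataclass(frozen=True)
class GeneCoverageParams:
    alpha: float = 0.75  # partial-overlap threshold fraction

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


CATEGORY_WHOLLY = "wholly"
CATEGORY_PARTIALLY = "partially"
CATEGORY_BELOW = "below_threshold"
CATEGORY_NOT_COVERED = "not_covered"


def overlap_ratio(
    gene: GenomicInterval, hc_regions: Sequence[GenomicInterval]
) -> float:
    """H(g) = L_O(g) / L(g), with L_O(g) the summed intersection of the
    gene with its overlapping high-confidence regions:
    L_O(g) = sum_i max(0, min(g_end, hc_end_i) - max(g_start, hc_start_i)).
    Computed in integer arithmetic before the final division."""
    length = len(gene)
    if length == 0:
        raise ValueError(f"zero-length gene interval {gene}")
    l_o = 0
    for hc in hc_regions:
        if hc.contig != gene.contig:
            continue
        l_o += max(0, min(gene.end, hc.end) - max(gene.start, hc.start))
    return l_o / length


def categorize_gene(h: float, params: GeneCoverageParams = GeneCoverageParams()) -> str:
    """wholly iff H = 1; partially iff alpha <= H < 1; not_covered iff
    H = 0; anything else falls below the threshold."""
    if not 0 <= h <= 1:
        raise ValueError(f"overlap ratio {h} outside [0, 1]")
    if h == 1.0:
        return CATEGORY_WHOLLY
    if h >= params.alpha:
        return CATEGORY_PARTIALLY
    if h == 0.0:
        return CATEGORY_NOT_COVERED
    return CATEGORY_BELOW


@dataclass
class GeneErrorFlags:
    no_snp_error: bool
    no_indel_error: bool


def gene_error_status(
    gene: GenomicInterval,
    match: MatchResult,
    subregions: Optional[Sequence[GenomicInterval]] = None,
) -> GeneErrorFlags:
    """Error-free status of one gene from annotated match outcomes.

    A gene has no SNP (indel) errors iff at least one SNP (indel) true
    positive lies inside the evaluated region and no SNP (indel) false
    positive or false negative does. ``subregions`` restricts the
    evaluation to e.g. the gene's CDS or exon intervals.
    """
    spans = list(subregions) if subregions is not None else [gene]

    def inside(contig: str, pos: int) -> bool:
        return any(
            s.contig == contig and s.start <= pos < s.end for s in spans
        )

    counts = {("SNP", "TP"): 0, ("SNP", "bad"): 0,
              ("Indel", "TP"): 0, ("Indel", "bad"): 0}
    for contig, pos, cats, outcome in match.annotations:
        if not inside(contig, pos):
            continue
        for kind in ("SNP", "Indel"):
            if kind not in cats:
                continue
            if outcome == "TP":
                counts[(kind, "TP")] += 1
            else:  # FP, FN or genotype mismatch (one FP + one FN)
                counts[(kind, "bad")] += 1
    return GeneErrorFlags(
        no_snp_error=counts[("SNP", "TP")] > 0 and counts[("SNP", "bad")] == 0,
        no_indel_error=counts[("Indel", "TP")] > 0 and counts[("Indel", "bad")] == 0,
    )


def wholly_phased(
    gene: GenomicInterval, phaseset_intervals: Sequence[GenomicInterval]
) -> bool:
    """True iff the gene lies entirely within a single phaseset."""
    return any(ps.contains(gene) for ps in phaseset_intervals)


def count_switch_errors(
    assignment_a: Sequence[int], assignment_b: Sequence[int]
) -> int:
    """Switch errors between two haplotype assignments of the same
    ordered het-variant list.

    Counts positions where the relative phase (agree/disagree between
    the two assignments) flips between consecutive variants — the
    editing distance of the two phasings up to a global haplotype flip,
    so it is invariant under flipping either assignment globally.
    """
    if len(assignment_a) != len(assignment_b):
        raise ValueError(
            f"assignment lengths differ: {len(assignment_a)} vs {len(assignment_b)}"
        )
    for v in list(assignment_a) + list(assignment_b):
        if v not in (1, 2):
            raise ValueError(f"haplotype labels must be 1 or 2, got {v}")
    rel = [int(a == b) for a, b in zip(assignment_a, assignment_b)]
    return sum(1 for x, y in zip(rel, rel[1:]) if x != y)


@dataclass
class GeneStatus:
    gene_id: str
    h: float
    category: str
    no_snp_error: Optional[bool] = None
    no_indel_error: Optional[bool] = None
    wholly_phased: Optional[bool] = None


def gene_report(
    genes: Iterable,
    hc_regions: Sequence[GenomicInterval],
    match: Optional[MatchResult] = None,
    phasesets: Optional[Sequence[GenomicInterval]] = None,
    params: GeneCoverageParams = GeneCoverageParams(),
) -> list[GeneStatus]:
    """Per-gene coverage category plus, where evaluable, error and
    phasing status. Error flags are only defined for genes overlapping
    the callable high-confidence regions."""
    out = []
    for gene in genes:
        iv = gene.interval
        h = overlap_ratio(iv, hc_regions)
        cat = categorize_gene(h, params)
        status = GeneStatus(gene_id=gene.gene_id, h=h, category=cat)
        if cat != CATEGORY_NOT_COVERED:
            if match is not None:
                flags = gene_error_status(iv, match)
                status.no_snp_error = flags.no_snp_error
                status.no_indel_error = flags.no_indel_error
            if phasesets is not None:
                status.wholly_phased = wholly_phased(iv, phasesets)
        out.append(status)
    return out
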