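"""Genotype-aware benchmarking of call sets against truth sets.

The workflow mirrors how RNA call sets have to be evaluated: truth
variants are first restricted to callable high-confidence regions and
to sites the RNA actually covers (at least two alt-supporting reads),
then calls are matched exactly on (contig, pos, ref, alt-set) after
allele normalization. A genotype mismatch at an allele-matched site
counts as one FP plus one FN unless zygosity is disregarded
(skip_genotyping), in which case the allele match suffices — the
paired FP/FN reduction under that flag measures how much of the error
is pure zygosity switching. Metrics come in five categories: Overall,
SNP, Indel, Insertion, Deletion.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .candidates import (
    DEFAULT_MIN_MAPQ,
    RegionPileup,
    _contig_span,
    in_regions,
)
from .formats import AlignedRead, GenomicInterval, TruthVariant, VariantCall
from .labels import allele_symbol, candidate_position

CATEGORIES = ("Overall", "SNP", "Indel", "Insertion", "Deletion")


def normalize_alleles(pos: int, ref: str, alts: Sequence[str]) -> tuple[int, str, tuple[str, ...]]:
    """Left-trim shared leading/trailing context from an allele set.

    Trailing bases common to every allele are removed first, then
    leading bases (shifting pos right), always leaving at least one
    base per allele. Makes right-padded and minimal representations of
    the same variant compare equal.
    """
    alleles = [ref] + list(alts)
    while all(len(a) > 1 for a in alleles) and len({a[-1] for a in alleles}) == 1:
        alleles = [a[:-1] for a in alleles]
    while all(len(a) > 1 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        pos += 1
    return pos, alleles[0], tuple(alleles[1:])


def _variant_key(contig: str, pos: int, ref: str, alts: Sequence[str]):
    pos, ref, alts = normalize_alleles(pos, ref, alts)
    return (contig, pos, ref, tuple(sorted(alts)))


def variant_atoms(contig: str, pos: int, ref: str, alts: Sequence[str]) -> frozenset:
    """Decompose a (possibly multi-allelic) record into per-allele atoms,
    each normalized independently, for allele-level comparison."""
    out = set()
    for alt in alts:
        p, r, a = normalize_alleles(pos, ref, [alt])
        out.add((contig, p, r, a[0]))
    return frozenset(out)


def _categories_of(ref: str, alts: Sequence[str]) -> set[str]:
    cats = set()
    for alt in alts:
        sym = allele_symbol(ref, alt)
        if sym in "ACGT":
            cats.add("SNP")
        elif sym == "I":
            cats.update(("Indel", "Insertion"))
        else:
            cats.update(("Indel", "Deletion"))
    return cats


# ---------------------------------------------------------------------------
# Truth filtering
# ---------------------------------------------------------------------------

def filter_truth(
    truths: Sequence[TruthVariant],
    rna_alignments: Sequence[AlignedRead],
    regions: Sequence[GenomicInterval],
    min_ad: int = 2,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[TruthVariant]:
    """Keep truths inside the benchmarking regions whose alternate
    allele has at least min_ad supporting RNA reads."""
    by_contig: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in rna_alignments:
        by_contig[r.contig].append(r)
    piles: dict[str, RegionPileup] = {}
    for contig, reads in by_contig.items():
        start, end = _contig_span(reads)
        piles[contig] = RegionPileup(reads, contig, start, end, min_mapq=min_mapq)
    out = []
    for t in truths:
        if not in_regions(t.contig, t.pos, regions):
            continue
        cpos = candidate_position(t)
        rp = piles.get(t.contig)
        if rp is None or not (rp.start <= cpos < rp.end):
            continue
        site = rp.site(cpos, t.ref[0])
        ad = site.AD
        support = max(
            ad.get(allele_symbol(t.ref, a), 0) for a in t.alts
        )
        if support >= min_ad:
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    tp: dict[str, int] = field(default_factory=lambda: dict.fromkeys(CATEGORIES, 0))
    fp: dict[str, int] = field(default_factory=lambda: dict.fromkeys(CATEGORIES, 0))
    fn: dict[str, int] = field(default_factory=lambda: dict.fromkeys(CATEGORIES, 0))
    #: allele-matched sites where only the genotype disagreed
    genotype_mismatches: list[tuple[str, int]] = field(default_factory=list)
    #: per-site annotations: (contig, pos, category-set, outcome)
    annotations: list[tuple[str, int, frozenset, str]] = field(default_factory=list)


def match_variants(
    calls: Sequence[VariantCall],
    truths: Sequence[TruthVariant],
    regions: Optional[Sequence[GenomicInterval]] = None,
    skip_genotyping: bool = False,
    pass_only: bool = True,
) -> MatchResult:
    """Exact-match comparison after allele normalization.

    A call matches a truth iff the normalized (contig, pos, ref,
    alt-set) agree. Genotype-aware mode additionally requires the
    genotype: an allele match with discordant genotype scores one FP
    and one FN. With skip_genotyping the allele match alone is a TP.
    """
    if pass_only:
        calls = [c for c in calls if c.filter == "PASS"]
    if regions is not None:
        calls = [c for c in calls if in_regions(c.contig, c.pos, regions)]
        truths = [t for t in truths if in_regions(t.contig, t.pos, regions)]
    seen_keys = set()
    call_atoms: list[tuple[frozenset, VariantCall]] = []
    atom_to_call: dict[tuple, int] = {}
    for c in calls:
        key = _variant_key(c.contig, c.pos, c.ref, c.alts)
        if key in seen_keys:
            raise ValueError(
                f"duplicate call record at {c.contig}:{c.pos + 1}"
            )
        seen_keys.add(key)
        atoms = variant_atoms(c.contig, c.pos, c.ref, c.alts)
        idx = len(call_atoms)
        call_atoms.append((atoms, c))
        for a in atoms:
            atom_to_call.setdefault(a, idx)

    res = MatchResult()

    def tally(bucket: dict[str, int], cats: set[str]) -> None:
        bucket["Overall"] += 1
        for cat in cats:
            bucket[cat] += 1

    matched_calls: set[int] = set()
    for t in truths:
        t_atoms = variant_atoms(t.contig, t.pos, t.ref, t.alts)
        cats = _categories_of(*_variant_key(t.contig, t.pos, t.ref, t.alts)[2:])
        hit = next(
            (atom_to_call[a] for a in t_atoms if a in atom_to_call), None
        )
        if hit is None or hit in matched_calls:
            tally(res.fn, cats)
            res.annotations.append((t.contig, t.pos, frozenset(cats), "FN"))
            continue
        c_atoms, call = call_atoms[hit]
        # allele-level agreement: exact set for genotype-aware matching,
        # call-subset-of-truth when zygosity is disregarded (an allele
        # dropped by expression is a zygosity effect, not a new allele)
        alleles_exact = c_atoms == t_atoms
        alleles_ok = alleles_exact or (skip_genotyping and c_atoms <= t_atoms)
        if not alleles_ok:
            tally(res.fn, cats)
            res.annotations.append((t.contig, t.pos, frozenset(cats), "FN"))
            continue
        matched_calls.add(hit)
        gt_match = alleles_exact and call.genotype == t.genotype
        if gt_match or skip_genotyping:
            tally(res.tp, cats)
            res.annotations.append((t.contig, t.pos, frozenset(cats), "TP"))
            if not gt_match:
                res.genotype_mismatches.append((t.contig, t.pos))
        else:
            tally(res.fp, cats)
            tally(res.fn, cats)
            res.genotype_mismatches.append((t.contig, t.pos))
            res.annotations.append((t.contig, t.pos, frozenset(cats), "GT"))
    for idx, (atoms, c) in enumerate(call_atoms):
        if idx not in matched_calls:
            key = _variant_key(c.contig, c.pos, c.ref, c.alts)
            cats = _categories_of(key[2], key[3])
            tally(res.fp, cats)
            res.annotations.append((c.contig, c.pos, frozenset(cats), "FP"))
    return res


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    precision: dict[str, Optional[float]]
    recall: dict[str, Optional[float]]
    f1: dict[str, Optional[float]]
    counts: MatchResult
    settings: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in CATEGORIES:
            rows.append(
                {
                    "category": cat,
                    "tp": self.counts.tp[cat],
                    "fp": self.counts.fp[cat],
                    "fn": self.counts.fn[cat],
                    "precision": self.precision[cat],
                    "recall": self.recall[cat],
                    "f1": self.f1[cat],
                    **self.settings,
                }
            )
        return pd.DataFrame(rows)


def compute_metrics(match: MatchResult, settings: Optional[dict] = None) -> MetricsReport:
    """Precision/recall/F1 per category; zero-denominator cells are
    None (reported as NA, never 0)."""
    precision: dict[str, Optional[float]] = {}
    recall: dict[str, Optional[float]] = {}
    f1: dict[str, Optional[float]] = {}
    for cat in CATEGORIES:
        tp, fp, fn = match.tp[cat], match.fp[cat], match.fn[cat]
        p = tp / (tp + fp) if tp + fp > 0 else None
        r = tp / (tp + fn) if tp + fn > 0 else None
        precision[cat] = p
        recall[cat] = r
        if p is None or r is None or p + r == 0:
            f1[cat] = None
        else:
            f1[cat] = 2 * p * r / (p + r)
    return MetricsReport(
        precision=precision, recall=recall, f1=f1, counts=match,
        settings=settings or {},
    )


# ---------------------------------------------------------------------------
# DP/AD stratification
# ---------------------------------------------------------------------------

def stratify(
    calls: Sequence[VariantCall],
    truths: Sequence[TruthVariant],
    regions: Sequence[GenomicInterval],
    rna_alignments: Sequence[AlignedRead],
    dp_thresholds: Sequence[int],
    ad_thresholds: Sequence[int],
    skip_genotyping: bool = False,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> dict[tuple[int, int], MetricsReport]:
    """Metrics over a grid of minimum-DP x minimum-AD gates.

    For each (d, a) cell, truth sites and calls are restricted to
    positions whose RNA pileup shows DP >= d and best-alt AD >= a, and
    the metrics recomputed on that subset.
    """
    if list(dp_thresholds) != sorted(dp_thresholds) or list(
        ad_thresholds
    ) != sorted(ad_thresholds):
        raise ValueError("thresholds must be ascending")
    by_contig: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in rna_alignments:
        by_contig[r.contig].append(r)
    piles: dict[str, RegionPileup] = {}
    for contig, reads in by_contig.items():
        start, end = _contig_span(reads)
        piles[contig] = RegionPileup(reads, contig, start, end, min_mapq=min_mapq)

    def site_stats(contig: str, pos: int) -> tuple[int, int]:
        rp = piles.get(contig)
        if rp is None or not (rp.start <= pos < rp.end):
            return 0, 0
        site = rp.site(pos)
        alts = site.best_alts(1)
        return site.DP, alts[0][1] if alts else 0

    out: dict[tuple[int, int], MetricsReport] = {}
    for d in dp_thresholds:
        for a in ad_thresholds:
            sub_truths = [
                t for t in truths
                if (lambda s: s[0] >= d and s[1] >= a)(
                    site_stats(t.contig, candidate_position(t))
                )
            ]
            sub_calls = [
                c for c in calls
                if (lambda s: s[0] >= d and s[1] >= a)(
                    site_stats(c.contig, candidate_position(c))
                )
            ]
            match = match_variants(
                sub_calls, sub_truths, regions, skip_genotyping=skip_genotyping
            )
            out[(d, a)] = compute_metrics(
                match,
                settings={"min_dp": d, "min_ad": a, "skip_genotyping": skip_genotyping},
            )
    return out
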