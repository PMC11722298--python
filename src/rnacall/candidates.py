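"""Spliced-pileup counting, candidate discovery and callable regions.

The single-pass CIGAR-walk engine here is the counting primitive behind
everything downstream: per-site pileups, the 18-feature candidate tensors,
the 12 haplotype features, callable-region derivation and the RNA/DNA
evidence used for editing-site benchmarking.

Conventions (uniform across the package):

* a read contributes to depth (DP) at a position if it aligns a base
  there or deletes it; spliced-over (CIGAR ``N``) positions get nothing;
* an insertion is attributed to the reference position immediately to
  the left of the inserted bases;
* a deletion "starts" at its first deleted reference position, and the
  remaining deleted positions count as deletion-inside;
* secondary and supplementary alignments, and reads below the mapping-
  quality floor (default 5), are excluded everywhere.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .formats import AlignedRead, GenomicInterval

DEFAULT_MIN_MAPQ = 5
DEFAULT_AF_THRESHOLD = 0.08
DEFAULT_MIN_DP = 4
DEFAULT_MIN_AD = 2
DEFAULT_MIN_COV = 4

#: per-position feature channels, forward strand first
FEATURE_NAMES = [
    "A+", "C+", "G+", "T+", "I_S+", "I_1S+", "D_S+", "D_1S+", "D_R+",
    "A-", "C-", "G-", "T-", "I_S-", "I_1S-", "D_S-", "D_1S-", "D_R-",
]
N_FEATURES = len(FEATURE_NAMES)  # 18

#: haplotype feature channels appended when phasing is enabled
HAP_FEATURE_NAMES = [
    "A_H1", "C_H1", "G_H1", "T_H1", "I_H1", "D_H1",
    "A_H2", "C_H2", "G_H2", "T_H2", "I_H2", "D_H2",
]
N_HAP_FEATURES = len(HAP_FEATURE_NAMES)  # 12

_CH = {name: i for i, name in enumerate(FEATURE_NAMES)}
_BASES = "ACGT"


def qualifies(read: AlignedRead, min_mapq: int = DEFAULT_MIN_MAPQ) -> bool:
    """Inclusion rule applied to every counting operation."""
    return (
        not read.is_secondary
        and not read.is_supplementary
        and read.mapq >= min_mapq
    )


def iter_read_events(read: AlignedRead) -> Iterator[tuple[str, int, object]]:
    """Walk a CIGAR, yielding (kind, refpos, payload) counting events.

    kinds: ``base`` (payload: base char), ``ins`` (payload: inserted
    sequence, anchored left), ``del`` (payload: deleted length, at the
    first deleted position).
    """
    rpos = read.pos
    q = 0
    for op, ln in read.cigar:
        if op in "M=X":
            seq = read.seq[q : q + ln]
            for k in range(ln):
                yield ("base", rpos + k, seq[k])
            rpos += ln
            q += ln
        elif op == "I":
            yield ("ins", rpos - 1, read.seq[q : q + ln])
            q += ln
        elif op == "D":
            yield ("del", rpos, ln)
            rpos += ln
        elif op == "N":
            rpos += ln
        elif op == "S":
            q += ln
        elif op == "H":
            pass
        else:
            raise ValueError(f"read {read.name}: unsupported CIGAR op {op!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SitePileup:
    """Strand-split allele and indel counts at one reference position.

    ``AD`` maps allele keys ``A/C/G/T`` (aligned base support) and
    ``I``/``D`` (insertion / deletion starts) to supporting-read counts;
    ``DP`` is the qualifying read coverage (aligned or deleting reads).
    """

    contig: str
    pos: int
    ref_base: str
    counts: np.ndarray  # shape (18,), FEATURE_NAMES order
    ins_seqs: Counter = field(default_factory=Counter)
    del_lens: Counter = field(default_factory=Counter)

    @property
    def DP(self) -> int:
        c = self.counts
        base = sum(int(c[_CH[b + s]]) for b in _BASES for s in "+-")
        dels = int(
            c[_CH["D_S+"]] + c[_CH["D_S-"]] + c[_CH["D_R+"]] + c[_CH["D_R-"]]
        )
        return base + dels

    @property
    def AD(self) -> dict[str, int]:
        c = self.counts
        ad = {b: int(c[_CH[b + "+"]] + c[_CH[b + "-"]]) for b in _BASES}
        ad["I"] = int(c[_CH["I_S+"]] + c[_CH["I_S-"]])
        ad["D"] = int(c[_CH["D_S+"]] + c[_CH["D_S-"]])
        return ad

    def alt_support(self) -> dict[str, int]:
        """AD restricted to non-reference alleles."""
        return {a: n for a, n in self.AD.items() if a != self.ref_base and n > 0}

    def best_alts(self, k: int = 2) -> list[tuple[str, int]]:
        alts = sorted(
            self.alt_support().items(), key=lambda kv: (-kv[1], kv[0])
        )
        return alts[:k]


@dataclass
class CandidateSite:
    """A SitePileup that passed the candidate gates."""

    pileup: SitePileup
    minor_af: float

    @property
    def contig(self) -> str:
        return self.pileup.contig

    @property
    def pos(self) -> int:
        return self.pileup.pos


# ---------------------------------------------------------------------------
# Region pileup engine
# ---------------------------------------------------------------------------

class RegionPileup:
    """Accumulated pileup counts over a half-open window of one contig.

    Feature grid ``counts[p - start, channel]`` in FEATURE_NAMES order;
    optional ``hap_counts`` grid (12 channels) from HP tags.
    """

    def __init__(
        self,
        reads: Iterable[AlignedRead],
        contig: str,
        start: int,
        end: int,
        min_mapq: int = DEFAULT_MIN_MAPQ,
        track_haplotypes: bool = False,
    ):
        if end < start:
            raise ValueError("end < start")
        self.contig = contig
        self.start = start
        self.end = end
        n = end - start
        self.counts = np.zeros((n, N_FEATURES), dtype=np.int64)
        self.hap_counts = (
            np.zeros((n, N_HAP_FEATURES), dtype=np.int64)
            if track_haplotypes
            else None
        )
        self.ins_seqs: dict[int, Counter] = defaultdict(Counter)
        self.del_lens: dict[int, Counter] = defaultdict(Counter)
        for read in reads:
            if read.contig != contig or not qualifies(read, min_mapq):
                continue
            self._add(read)

    def _add(self, read: AlignedRead) -> None:
        lo, hi = self.start, self.end
        s = "+" if read.strand == "forward" else "-"
        hp_off = None
        if self.hap_counts is not None and read.hp in (1, 2):
            hp_off = 0 if read.hp == 1 else 6
        for kind, rpos, payload in iter_read_events(read):
            if kind == "base":
                if lo <= rpos < hi and payload in _BASES:
                    i = rpos - lo
                    self.counts[i, _CH[payload + s]] += 1
                    if hp_off is not None:
                        self.hap_counts[i, hp_off + _BASES.index(payload)] += 1
            elif kind == "ins":
                if lo <= rpos < hi:
                    i = rpos - lo
                    self.counts[i, _CH["I_S" + s]] += 1
                    if len(payload) == 1:
                        self.counts[i, _CH["I_1S" + s]] += 1
                    self.ins_seqs[rpos][payload] += 1
                    if hp_off is not None:
                        self.hap_counts[i, hp_off + 4] += 1
            else:  # del
                ln = int(payload)
                if lo <= rpos < hi:
                    i = rpos - lo
                    self.counts[i, _CH["D_S" + s]] += 1
                    if ln == 1:
                        self.counts[i, _CH["D_1S" + s]] += 1
                    self.del_lens[rpos][ln] += 1
                    if hp_off is not None:
                        self.hap_counts[i, hp_off + 5] += 1
                for p in range(max(rpos + 1, lo), min(rpos + ln, hi)):
                    self.counts[p - lo, _CH["D_R" + s]] += 1

    def site(self, pos: int, ref_base: str = "N") -> SitePileup:
        if not (self.start <= pos < self.end):
            raise IndexError(f"position {pos} outside pileup window")
        return SitePileup(
            contig=self.contig,
            pos=pos,
            ref_base=ref_base,
            counts=self.counts[pos - self.start].copy(),
            ins_seqs=Counter(self.ins_seqs.get(pos, {})),
            del_lens=Counter(self.del_lens.get(pos, {})),
        )

    def depth(self) -> np.ndarray:
        """Qualifying coverage (aligned + deleted) per window position."""
        cols = [
            _CH[b + s] for b in _BASES for s in "+-"
        ] + [_CH["D_S+"], _CH["D_S-"], _CH["D_R+"], _CH["D_R-"]]
        return self.counts[:, cols].sum(axis=1)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_site_pileup(
    reads: Iterable[AlignedRead],
    contig: str,
    pos: int,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    ref_base: str = "N",
) -> SitePileup:
    """Pileup at a single position from reads overlapping it."""
    if pos < 0:
        raise ValueError(f"position {pos} outside contig")
    rp = RegionPileup(reads, contig, pos, pos + 1, min_mapq=min_mapq)
    return rp.site(pos, ref_base)


def _contig_span(reads: Sequence[AlignedRead]) -> tuple[int, int]:
    start = min(r.pos for r in reads)
    end = max(r.reference_end for r in reads)
    return start, end


def scan_candidates(
    alignments: Iterable[AlignedRead],
    ref: dict[str, str],
    af_threshold: float = DEFAULT_AF_THRESHOLD,
    min_dp: int = DEFAULT_MIN_DP,
    min_ad: int = DEFAULT_MIN_AD,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[CandidateSite]:
    """Site-by-site scan for candidate variants.

    Emits sites with DP >= min_dp, best-alternate AD >= min_ad and minor
    allelic fraction (best alt AD / DP) strictly above af_threshold,
    ordered by (contig, pos).
    """
    by_contig: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in alignments:
        by_contig[r.contig].append(r)
    out: list[CandidateSite] = []
    for contig in sorted(by_contig):
        reads = by_contig[contig]
        start, end = _contig_span(reads)
        rp = RegionPileup(reads, contig, start, end, min_mapq=min_mapq)
        seq = ref.get(contig, "")
        dp = rp.depth()
        for i in np.nonzero(dp >= min_dp)[0]:
            pos = start + int(i)
            ref_base = seq[pos] if pos < len(seq) else "N"
            site = rp.site(pos, ref_base)
            alts = site.best_alts(1)
            if not alts:
                continue
            best_ad = alts[0][1]
            d = site.DP
            af = best_ad / d if d > 0 else 0.0
            if best_ad >= min_ad and af > af_threshold:
                out.append(CandidateSite(pileup=site, minor_af=af))
    return out


def compute_callable_regions(
    alignments: Iterable[AlignedRead],
    min_cov: int = DEFAULT_MIN_COV,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[GenomicInterval]:
    """Maximal merged intervals with qualifying coverage >= min_cov.

    Spliced-out (N) stretches contribute no coverage, so a single read
    covering two exons yields two callable fragments.
    """
    by_contig: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in alignments:
        if qualifies(r, min_mapq):
            by_contig[r.contig].append(r)
    out: list[GenomicInterval] = []
    for contig in sorted(by_contig):
        reads = by_contig[contig]
        start, end = _contig_span(reads)
        cov = np.zeros(end - start, dtype=np.int64)
        for read in reads:
            rpos = read.pos
            for op, ln in read.cigar:
                if op in "M=XD":
                    cov[rpos - start : rpos + ln - start] += 1
                    rpos += ln
                elif op == "N":
                    rpos += ln
        mask = cov >= min_cov
        # maximal runs of True
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            out.append(GenomicInterval(contig, start + int(lo), start + int(hi)))
    return out


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping/adjacent intervals."""
    ivs = sorted(ivs, key=lambda v: (v.contig, v.start, v.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].contig == iv.contig and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.contig, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def intersect_regions(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Exact set intersection of two sorted, non-overlapping interval sets."""
    by_contig_b: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in b:
        by_contig_b[iv.contig].append(iv)
    out: list[GenomicInterval] = []
    for iv in a:
        for jv in by_contig_b.get(iv.contig, ()):
            lo = max(iv.start, jv.start)
            hi = min(iv.end, jv.end)
            if lo < hi:
                out.append(GenomicInterval(iv.contig, lo, hi))
    return sorted(out, key=lambda v: (v.contig, v.start))


def total_length(ivs: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in ivs)


def in_regions(
    contig: str, pos: int, regions: Sequence[GenomicInterval]
) -> bool:
    """Membership test; linear scan is fine at the scales used here."""
    return any(
        iv.contig == contig and iv.start <= pos < iv.end for iv in regions
    )
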