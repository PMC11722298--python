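"""File-format I/O with fixed coordinate conventions.

All in-memory coordinates are 0-based, half-open. Conversion to each
format's native convention (VCF and GTF are 1-based; BED is 0-based
half-open) happens only at the file boundary, so no other module needs
to reason about off-by-ones.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam
from gffutils.feature import feature_from_line

log = logging.getLogger("rnacall")

QUERY_CONSUMING = set("MIS=X")
REF_CONSUMING = set("MDN=X")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class AlignedRead:
    """One alignment record; spliced alignments carry N CIGAR ops."""

    name: str
    contig: str
    pos: int  # 0-based leftmost reference offset
    mapq: int
    strand: str  # "forward" | "reverse"
    cigar: list[tuple[str, int]]
    seq: str
    is_secondary: bool = False
    is_supplementary: bool = False
    hp: Optional[int] = None  # haplotype tag, 1 or 2, None if untagged

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in QUERY_CONSUMING)
        if self.seq and qlen != len(self.seq):
            raise ValueError(
                f"read {self.name}: CIGAR consumes {qlen} query bases "
                f"but sequence has {len(self.seq)}"
            )

    @property
    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in REF_CONSUMING)

    @property
    def is_reverse(self) -> bool:
        return self.strand == "reverse"


@dataclass(frozen=True)
class TruthVariant:
    """A ground-truth variant with its DNA genotype."""

    contig: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    genotype: str  # "0/1", "1/1", "1/2"

    def __post_init__(self) -> None:
        for a in (self.ref,) + self.alts:
            if not a or set(a) - set("ACGT"):
                raise ValueError(f"invalid allele {a!r}")
        idx = {int(x) for x in self.genotype.split("/")}
        if max(idx) > len(self.alts):
            raise ValueError(
                f"genotype {self.genotype} references missing alt"
            )

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


@dataclass
class VariantCall:
    """An emitted variant record."""

    contig: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    genotype: str
    qual: float
    filter: str = "PASS"  # PASS | LowQual | RNAEditing
    ref_depth: int = 0
    alt_depths: tuple[int, ...] = ()

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_het(self) -> bool:
        a, b = self.genotype.split("/")
        return a != b


@dataclass
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    strand: str
    biotype: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)


@dataclass(frozen=True)
class EditingDBEntry:
    contig: str
    pos: int  # 0-based
    ref: str  # A or T
    alt: str  # G or C
    source_count: int


class EditingDB:
    """Index of known editing sites, keyed by (contig, pos)."""

    def __init__(self, entries: Iterable[EditingDBEntry] = ()):
        self._by_pos: dict[tuple[str, int], EditingDBEntry] = {}
        for e in entries:
            self._by_pos[(e.contig, e.pos)] = e

    def lookup(self, contig: str, pos: int) -> Optional[EditingDBEntry]:
        return self._by_pos.get((contig, pos))

    def __len__(self) -> int:
        return len(self._by_pos)

    def __iter__(self) -> Iterator[EditingDBEntry]:
        return iter(self._by_pos.values())


# ---------------------------------------------------------------------------
# Alignments (SAM/BAM)
# ---------------------------------------------------------------------------

def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    hp = None
    if rec.has_tag("HP"):
        v = rec.get_tag("HP")
        if v in (1, 2):
            hp = int(v)
    return AlignedRead(
        name=rec.query_name or "",
        contig=rec.reference_name or "",
        pos=rec.reference_start,
        mapq=rec.mapping_quality,
        strand="reverse" if rec.is_reverse else "forward",
        cigar=[(op, ln) for op, ln in _cigar_tuples(rec)],
        seq=rec.query_sequence or "",
        is_secondary=rec.is_secondary,
        is_supplementary=rec.is_supplementary,
        hp=hp,
    )


_CIGAR_OPS = "MIDNSHP=XB"


def _cigar_tuples(rec: pysam.AlignedSegment) -> list[tuple[str, int]]:
    return [(_CIGAR_OPS[op], ln) for op, ln in (rec.cigartuples or [])]


def read_alignments(
    path: str, region: Optional[GenomicInterval] = None
) -> Iterator[AlignedRead]:
    """Stream alignments from SAM/BAM, optionally restricted to a region.

    Reads are yielded in file (coordinate) order. With a region and an
    indexed BAM the index is used; otherwise the file is streamed and
    filtered. Unmapped records are skipped. A malformed CIGAR raises a
    ValueError naming the read.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        if region is not None and af.has_index():
            it = af.fetch(region.contig, region.start, region.end)
        else:
            it = (r for r in af if not r.is_unmapped)
            if region is not None:
                it = (
                    r
                    for r in it
                    if r.reference_name == region.contig
                    and r.reference_start < region.end
                    and r.reference_end > region.start
                )
        for rec in it:
            if rec.is_unmapped:
                continue
            yield _from_pysam(rec)


def write_alignments(
    reads: Iterable[AlignedRead],
    path: str,
    contig_lengths: dict[str, int],
    sort_and_index: bool = True,
) -> None:
    """Write alignments to SAM or BAM; BAMs are sorted and indexed."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in contig_lengths.items()],
    }
    is_bam = path.endswith(".bam")
    tmp = path + ".unsorted.bam" if (is_bam and sort_and_index) else path
    mode = "wb" if tmp.endswith(".bam") else "w"
    with pysam.AlignmentFile(tmp, mode, header=header) as af:
        tids = {c: i for i, c in enumerate(contig_lengths)}
        for r in reads:
            seg = pysam.AlignedSegment(af.header)
            seg.query_name = r.name
            seg.reference_id = tids[r.contig]
            seg.reference_start = r.pos
            seg.mapping_quality = r.mapq
            seg.query_sequence = r.seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            seg.cigartuples = [
                (_CIGAR_OPS.index(op), ln) for op, ln in r.cigar
            ]
            flag = 0
            if r.is_reverse:
                flag |= 16
            if r.is_secondary:
                flag |= 256
            if r.is_supplementary:
                flag |= 2048
            seg.flag = flag
            if r.hp is not None:
                seg.set_tag("HP", r.hp, "i")
            af.write(seg)
    if is_bam and sort_and_index:
        pysam.sort("-o", path, tmp)
        os.remove(tmp)
        pysam.index(path)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_FILTERS = {
    "PASS": None,
    "LowQual": "Low quality score",
    "RNAEditing": "Known RNA editing site",
}


def write_vcf(
    calls: Iterable[VariantCall], path: str, contig_lengths: dict[str, int]
) -> None:
    """Write calls as VCF 4.2; input must be sorted by (contig, pos).

    Each record carries the reference and alternate alleles, the genotype,
    the reference-allele coverage and the coverage of every alternate
    allele (GT/DP/AD), with FILTER in {PASS, LowQual, RNAEditing}.
    """
    header = pysam.VariantHeader()
    for name, desc in _VCF_FILTERS.items():
        if desc is not None:
            header.filters.add(name, None, None, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add(
        "AD", "R", "Integer", "Read depth of the ref and each alt allele"
    )
    for c, ln in contig_lengths.items():
        header.contigs.add(c, length=ln)
    header.add_sample("SAMPLE")

    order = {c: i for i, c in enumerate(contig_lengths)}
    prev: Optional[tuple[int, int]] = None
    with pysam.VariantFile(path, "w", header=header) as vf:
        for call in calls:
            key = (order[call.contig], call.pos)
            if prev is not None and key < prev:
                raise ValueError(
                    f"unsorted call at {call.contig}:{call.pos + 1}"
                )
            prev = key
            rec = vf.new_record(
                contig=call.contig,
                start=call.pos,
                alleles=(call.ref,) + call.alts,
                qual=round(call.qual, 2),
                filter=call.filter,
            )
            gt = tuple(int(x) for x in call.genotype.split("/"))
            rec.samples["SAMPLE"]["GT"] = gt
            dp = call.ref_depth + sum(call.alt_depths)
            rec.samples["SAMPLE"]["DP"] = dp
            ad = list(call.alt_depths) + [0] * (len(call.alts) - len(call.alt_depths))
            rec.samples["SAMPLE"]["AD"] = (call.ref_depth, *ad)
            vf.write(rec)


def read_vcf(path: str) -> list[VariantCall]:
    """Read a VCF into VariantCall records (0-based positions)."""
    out: list[VariantCall] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            sample = rec.samples[0] if rec.samples else None
            gt = "./."
            dp = 0
            ad: tuple[int, ...] = ()
            if sample is not None:
                gtv = sample.get("GT")
                if gtv and None not in gtv:
                    gt = "/".join(str(x) for x in sorted(gtv))
                dp = sample.get("DP") or 0
                adv = sample.get("AD")
                if adv is not None:
                    ad = tuple(int(x) for x in adv)
            filters = list(rec.filter.keys()) or ["PASS"]
            out.append(
                VariantCall(
                    contig=rec.contig,
                    pos=rec.start,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    genotype=gt,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    filter=filters[0],
                    ref_depth=ad[0] if ad else max(dp - 0, 0),
                    alt_depths=ad[1:] if len(ad) > 1 else (),
                )
            )
    return out


def read_truth_vcf(path: str) -> list[TruthVariant]:
    """Read a truth VCF into TruthVariant records."""
    out: list[TruthVariant] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            gtv = rec.samples[0].get("GT") if rec.samples else None
            if not gtv or None in gtv:
                continue
            gt = "/".join(str(x) for x in sorted(gtv))
            out.append(
                TruthVariant(
                    contig=rec.contig,
                    pos=rec.start,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    genotype=gt,
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# GTF gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str) -> list[GeneRecord]:
    """Read a GENCODE-style GTF into gene records with exon/CDS intervals.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Features lacking a gene_id are skipped with a warning.
    """
    genes: dict[str, GeneRecord] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            feat = feature_from_line(line, dialect=None)
            if "gene_id" not in feat.attributes:
                log.warning("skipping %s feature without gene_id", feat.featuretype)
                continue
            gid = feat.attributes["gene_id"][0]
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end)
            if feat.featuretype == "gene":
                biotype = (
                    feat.attributes.get("gene_type")
                    or feat.attributes.get("gene_biotype")
                    or [""]
                )[0]
                genes[gid] = GeneRecord(
                    gene_id=gid,
                    interval=iv,
                    strand=feat.strand,
                    biotype=biotype,
                )
            elif feat.featuretype in ("exon", "CDS"):
                rec = genes.get(gid)
                if rec is None:
                    rec = genes[gid] = GeneRecord(
                        gene_id=gid, interval=iv, strand=feat.strand, biotype=""
                    )
                (rec.exons if feat.featuretype == "exon" else rec.cds).append(iv)
    return list(genes.values())


# ---------------------------------------------------------------------------
# Editing-site database (minimal 6-column TSV)
# ---------------------------------------------------------------------------

EDITING_DB_COLUMNS = ("contig", "pos", "ref", "alt", "sources", "n_sources")
_EDITING_SOURCES = ("ATLAS", "DARNED", "RADAR")


def read_editing_db(path: str) -> EditingDB:
    """Load the editing-site table (TSV: contig, 1-based pos, ref, alt,
    then one 0/1 flag per source in ATLAS, DARNED, RADAR order).

    Only the two A-to-I representations (A>G, T>C) are accepted; other
    ref/alt pairs are rejected with a warning.
    """
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            contig, pos1, ref, alt = f[0], int(f[1]), f[2], f[3]
            if (ref, alt) not in (("A", "G"), ("T", "C")):
                log.warning(
                    "editing DB row %s:%s %s>%s is not an A-to-I "
                    "representation; rejected",
                    contig, pos1, ref, alt,
                )
                continue
            flags = [int(x) for x in f[4:7]]
            entries.append(
                EditingDBEntry(contig, pos1 - 1, ref, alt, sum(flags))
            )
    return EditingDB(entries)


def write_editing_db(entries: Iterable[EditingDBEntry], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(EDITING_DB_COLUMNS[:4] + _EDITING_SOURCES) + "\n")
        for e in entries:
            # distribute source_count over the first source_count flags
            flags = [1 if i < e.source_count else 0 for i in range(3)]
            fh.write(
                f"{e.contig}\t{e.pos + 1}\t{e.ref}\t{e.alt}\t"
                + "\t".join(str(x) for x in flags)
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    if os.path.exists(path + ".fai"):
        os.remove(path + ".fai")


def read_fasta(path: str) -> dict[str, str]:
    with pysam.FastaFile(path) as fa:
        return {name: fa.fetch(name) for name in fa.references}
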