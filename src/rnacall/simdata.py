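"""Seeded synthetic diploid spliced-transcriptome simulator.

Generates, fully deterministically under a seed, the coupled inputs
the pipeline consumes: a reference genome carrying genes with exons
and introns, a diploid pair of haplotypes with planted SNPs and small
indels, planted A>G / T>C editing events with per-site edited
fractions, spliced RNA reads (CIGAR N over introns) with heavy-tailed
per-gene coverage, optional allele-biased expression (so truth
variants hit the zygosity-switch branches), sequencing errors, HP
haplotype tags on a configurable fraction of reads, and a paired
unspliced "DNA" sample without editing.

Reads are emitted pre-aligned: their coordinates are generative, so no
aligner is involved and every read's bases are reproducible from the
haplotype sequence, the planted events, and the seeded errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .candidates import SitePileup, _CH
from .formats import (
    AlignedRead,
    EditingDBEntry,
    GenomicInterval,
    GeneRecord,
    TruthVariant,
    VariantCall,
    write_alignments,
    write_bed,
    write_editing_db,
    write_fasta,
    write_vcf,
)

_BASES = "ACGT"
_EDIT_ALT = {"A": "G", "T": "C"}


@dataclass
class SimConfig:
    seed: int = 0
    n_contigs: int = 1
    contig_length: int = 50_000
    n_genes: int = 8
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 500
    snps_per_gene: int = 3
    indels_per_gene: int = 1
    editing_sites_per_gene: int = 2
    edited_fraction_range: tuple[float, float] = (0.85, 1.0)
    base_error_rate: float = 0.015  # substitutions per emitted base
    error_indel_rate: float = 0.003  # micro-indel starts per base
    coverage_mean: float = 30.0  # RNA reads per gene (full-transcript)
    heavy_tail_fraction: float = 0.1  # genes with multiplied coverage
    heavy_tail_multiplier: float = 5.0
    allelic_imbalance_prob: float = 0.3
    imbalance_major_fraction: float = 0.9
    hp_tag_fraction: float = 0.6
    dna_coverage: float = 20.0
    dna_read_length: int = 1000
    hc_margin: int = 100  # masked contig tails

    def __post_init__(self) -> None:
        for p in (
            self.heavy_tail_fraction, self.allelic_imbalance_prob,
            self.hp_tag_fraction, self.base_error_rate, self.error_indel_rate,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        span = self.exons_per_gene * self.exon_length + (
            self.exons_per_gene - 1
        ) * self.intron_length
        if (span + 200) * self.n_genes > self.contig_length:
            raise ValueError(
                f"cannot place {self.n_genes} genes of span {span} on a "
                f"{self.contig_length} bp contig"
            )


@dataclass
class PlantedEditingSite:
    contig: str
    pos: int
    ref: str
    alt: str
    fraction: float


@dataclass
class SimOutput:
    """Everything the simulation produced, in memory plus ground truth."""

    config: SimConfig
    ref: dict[str, str]
    rna_reads: list[AlignedRead]
    dna_reads: list[AlignedRead]
    truths: list[TruthVariant]
    expressed_vaf: dict[tuple[str, int], float]  # haplotype expression share
    editing_sites: list[PlantedEditingSite]
    genes: list[GeneRecord]
    hc_regions: list[GenomicInterval]
    read_haplotype: dict[str, int]  # every read's haplotype of origin

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.ref.items()}

    def write(self, outdir: str) -> dict[str, str]:
        """Write all artifacts in standard formats; returns paths."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "ref_fasta": os.path.join(outdir, "ref.fa"),
            "rna_bam": os.path.join(outdir, "rna.bam"),
            "dna_bam": os.path.join(outdir, "dna.bam"),
            "truth_vcf": os.path.join(outdir, "truth.vcf"),
            "gtf": os.path.join(outdir, "genes.gtf"),
            "high_conf_bed": os.path.join(outdir, "high_conf.bed"),
            "editing_tsv": os.path.join(outdir, "editing_db.tsv"),
        }
        write_fasta(self.ref, paths["ref_fasta"])
        cl = self.contig_lengths
        write_alignments(self.rna_reads, paths["rna_bam"], cl)
        write_alignments(self.dna_reads, paths["dna_bam"], cl)
        order = {c: i for i, c in enumerate(cl)}
        calls = [
            VariantCall(
                contig=t.contig, pos=t.pos, ref=t.ref, alts=t.alts,
                genotype=t.genotype, qual=60.0, filter="PASS",
            )
            for t in sorted(self.truths, key=lambda t: (order[t.contig], t.pos))
        ]
        write_vcf(calls, paths["truth_vcf"], cl)
        with open(paths["gtf"], "w") as fh:
            for g in self.genes:
                attrs = (
                    f'gene_id "{g.gene_id}"; gene_type "{g.biotype}";'
                )
                iv = g.interval
                fh.write(
                    f"{iv.contig}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                for ex in g.exons:
                    fh.write(
                        f"{ex.contig}\tsim\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )
        write_bed(self.hc_regions, paths["high_conf_bed"])
        write_editing_db(
            [
                EditingDBEntry(e.contig, e.pos, e.ref, e.alt, 3)
                for e in self.editing_sites
            ],
            paths["editing_tsv"],
        )
        return paths


# ---------------------------------------------------------------------------
# Event maps
# ---------------------------------------------------------------------------

@dataclass
class _HapEvent:
    kind: str  # "sub" | "ins" | "del"
    payload: object  # base | inserted seq | deleted length


def _plant_variants(
    rng: np.random.Generator,
    seq: str,
    contig: str,
    genes: list[GeneRecord],
    cfg: SimConfig,
) -> tuple[list[TruthVariant], dict[int, dict[int, _HapEvent]], set[int]]:
    """Place SNPs/indels and editing sites in exons; min 6 bp apart."""
    events: dict[int, dict[int, _HapEvent]] = {1: {}, 2: {}}
    truths: list[TruthVariant] = []
    used: set[int] = set()

    def reserve(pos: int, span: int = 1) -> bool:
        span_range = range(pos - 6, pos + span + 6)
        if any(p in used for p in span_range):
            return False
        used.update(range(pos, pos + span))
        return True

    for gene in genes:
        exonic = [
            p
            for ex in gene.exons
            for p in range(ex.start + 5, ex.end - 10)
        ]
        rng.shuffle(exonic)
        cursor = 0

        def next_pos(span: int = 1) -> Optional[int]:
            nonlocal cursor
            while cursor < len(exonic):
                p = exonic[cursor]
                cursor += 1
                if reserve(p, span):
                    return p
            return None

        for _ in range(cfg.snps_per_gene):
            pos = next_pos()
            if pos is None:
                break
            ref_base = seq[pos]
            gt_kind = rng.choice(["het", "hom", "multi"], p=[0.65, 0.25, 0.10])
            others = [b for b in _BASES if b != ref_base]
            if gt_kind == "multi":
                a1, a2 = rng.choice(others, size=2, replace=False)
                events[1][pos] = _HapEvent("sub", a1)
                events[2][pos] = _HapEvent("sub", a2)
                truths.append(
                    TruthVariant(contig, pos, ref_base, (str(a1), str(a2)), "1/2")
                )
            else:
                alt = str(rng.choice(others))
                if gt_kind == "hom":
                    events[1][pos] = events[2][pos] = _HapEvent("sub", alt)
                    gt = "1/1"
                else:
                    hap = int(rng.integers(1, 3))
                    events[hap][pos] = _HapEvent("sub", alt)
                    gt = "0/1"
                truths.append(TruthVariant(contig, pos, ref_base, (alt,), gt))

        for _ in range(cfg.indels_per_gene):
            ln = int(rng.integers(1, 4))
            pos = next_pos(span=ln + 1)
            if pos is None:
                break
            is_ins = bool(rng.random() < 0.5)
            hom = bool(rng.random() < 0.3)
            haps = (1, 2) if hom else (int(rng.integers(1, 3)),)
            anchor = seq[pos]
            if is_ins:
                ins_seq = "".join(rng.choice(list(_BASES), size=ln))
                for h in haps:
                    events[h][pos] = _HapEvent("ins", ins_seq)
                truths.append(
                    TruthVariant(
                        contig, pos, anchor, (anchor + ins_seq,),
                        "1/1" if hom else "0/1",
                    )
                )
            else:
                for h in haps:
                    events[h][pos] = _HapEvent("del", ln)
                truths.append(
                    TruthVariant(
                        contig, pos, seq[pos : pos + ln + 1], (anchor,),
                        "1/1" if hom else "0/1",
                    )
                )
    return truths, events, used


def _plant_editing(
    rng: np.random.Generator,
    seq: str,
    contig: str,
    genes: list[GeneRecord],
    used: set[int],
    cfg: SimConfig,
) -> list[PlantedEditingSite]:
    lo, hi = cfg.edited_fraction_range
    sites: list[PlantedEditingSite] = []
    for gene in genes:
        exonic = [
            p
            for ex in gene.exons
            for p in range(ex.start + 5, ex.end - 10)
            if seq[p] in _EDIT_ALT
        ]
        rng.shuffle(exonic)
        placed = 0
        for p in exonic:
            if placed >= cfg.editing_sites_per_gene:
                break
            if any(q in used for q in range(p - 6, p + 7)):
                continue
            used.update(range(p, p + 1))
            frac = float(rng.uniform(lo, hi))
            sites.append(
                PlantedEditingSite(contig, p, seq[p], _EDIT_ALT[seq[p]], frac)
            )
            placed += 1
    return sites


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

def _emit_read(
    rng: np.random.Generator,
    seq: str,
    segments: list[tuple[int, int]],
    events: dict[int, _HapEvent],
    editing: dict[int, PlantedEditingSite],
    cfg: SimConfig,
) -> tuple[int, list[tuple[str, int]], str]:
    """Walk reference segments (exons) applying haplotype events,
    per-molecule editing and seeded errors; returns (pos, cigar, seq)."""
    cigar: list[tuple[str, int]] = []
    out: list[str] = []

    def push(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))

    start = segments[0][0]
    prev_end: Optional[int] = None
    for seg_start, seg_end in segments:
        if prev_end is not None:
            push("N", seg_start - prev_end)
        prev_end = seg_end
        p = seg_start
        skip_until = -1
        while p < seg_end:
            if p < skip_until:
                p += 1
                continue
            ev = events.get(p)
            if ev is not None and ev.kind == "del":
                # VCF-anchored: base at p kept, next `payload` bases deleted
                base = seq[p]
                ins_after = None
            elif ev is not None and ev.kind == "sub":
                base = str(ev.payload)
                ins_after = None
            elif ev is not None and ev.kind == "ins":
                base = seq[p]
                ins_after = str(ev.payload)
            else:
                base = seq[p]
                ins_after = None
            ed = editing.get(p)
            if ed is not None and rng.random() < ed.fraction:
                base = ed.alt
            # sequencing errors
            if rng.random() < cfg.base_error_rate:
                base = str(rng.choice([b for b in _BASES if b != base]))
            out.append(base)
            push("M", 1)
            if ev is not None and ev.kind == "del":
                ln = int(ev.payload)
                ln = min(ln, seg_end - p - 1)
                push("D", ln)
                skip_until = p + ln + 1
            if ins_after is not None:
                out.append(ins_after)
                push("I", len(ins_after))
            if rng.random() < cfg.error_indel_rate:
                ln = int(rng.geometric(0.7))
                if rng.random() < 0.5:
                    err_ins = "".join(rng.choice(list(_BASES), size=ln))
                    out.append(err_ins)
                    push("I", ln)
                elif p + 1 + ln < seg_end:
                    push("D", ln)
                    skip_until = p + ln + 1
            p += 1
    return start, cigar, "".join(out)


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------

def simulate(config: SimConfig) -> SimOutput:
    """Run the full simulation; byte-identical outputs for equal configs."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ref: dict[str, str] = {}
    all_genes: list[GeneRecord] = []
    truths: list[TruthVariant] = []
    editing_sites: list[PlantedEditingSite] = []
    rna_reads: list[AlignedRead] = []
    dna_reads: list[AlignedRead] = []
    read_haplotype: dict[str, int] = {}
    expressed_vaf: dict[tuple[str, int], float] = {}
    hc_regions: list[GenomicInterval] = []

    gene_span = cfg.exons_per_gene * cfg.exon_length + (
        cfg.exons_per_gene - 1
    ) * cfg.intron_length

    for ci in range(cfg.n_contigs):
        contig = f"ctg{ci + 1}"
        seq = "".join(rng.choice(list(_BASES), size=cfg.contig_length))
        ref[contig] = seq
        hc_regions.append(
            GenomicInterval(
                contig, cfg.hc_margin, cfg.contig_length - cfg.hc_margin
            )
        )

        # gene placement: evenly spaced with jitter
        slot = cfg.contig_length // cfg.n_genes
        genes: list[GeneRecord] = []
        for gi in range(cfg.n_genes):
            margin = slot - gene_span - 20
            offset = int(rng.integers(10, max(margin, 11)))
            g_start = gi * slot + offset
            exons = [
                GenomicInterval(
                    contig,
                    g_start + k * (cfg.exon_length + cfg.intron_length),
                    g_start + k * (cfg.exon_length + cfg.intron_length)
                    + cfg.exon_length,
                )
                for k in range(cfg.exons_per_gene)
            ]
            genes.append(
                GeneRecord(
                    gene_id=f"{contig}_g{gi + 1}",
                    interval=GenomicInterval(contig, g_start, exons[-1].end),
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype="protein_coding",
                    exons=exons,
                )
            )
        all_genes.extend(genes)

        c_truths, events, used = _plant_variants(rng, seq, contig, genes, cfg)
        truths.extend(c_truths)
        c_edits = _plant_editing(rng, seq, contig, genes, used, cfg)
        editing_sites.extend(c_edits)
        edit_by_pos = {e.pos: e for e in c_edits}

        # --- RNA reads: full-transcript spliced reads per gene
        for gene in genes:
            segs = [(ex.start, ex.end) for ex in gene.exons]
            mean = cfg.coverage_mean
            if rng.random() < cfg.heavy_tail_fraction:
                mean *= cfg.heavy_tail_multiplier
            n_reads = int(rng.poisson(mean))
            if rng.random() < cfg.allelic_imbalance_prob:
                major = int(rng.integers(1, 3))
                p_h1 = (
                    cfg.imbalance_major_fraction
                    if major == 1
                    else 1 - cfg.imbalance_major_fraction
                )
            else:
                p_h1 = 0.5
            gene_positions = {
                p for ex in gene.exons for p in range(ex.start, ex.end)
            }
            for t in c_truths:
                if t.pos in gene_positions:
                    # expression share of the alt-carrying haplotype(s)
                    if t.genotype == "1/1" or t.genotype == "1/2":
                        expressed_vaf[(contig, t.pos)] = 1.0
                    else:
                        alt_on_h1 = t.pos in events[1]
                        expressed_vaf[(contig, t.pos)] = (
                            p_h1 if alt_on_h1 else 1 - p_h1
                        )
            for ri in range(n_reads):
                hap = 1 if rng.random() < p_h1 else 2
                pos, cigar, rseq = _emit_read(
                    rng, seq, segs, events[hap], edit_by_pos, cfg
                )
                name = f"{gene.gene_id}_r{ri}"
                hp = hap if rng.random() < cfg.hp_tag_fraction else None
                rna_reads.append(
                    AlignedRead(
                        name=name, contig=contig, pos=pos, mapq=60,
                        strand="forward" if rng.random() < 0.5 else "reverse",
                        cigar=cigar, seq=rseq, hp=hp,
                    )
                )
                read_haplotype[name] = hap

        # --- DNA reads: unspliced tiling, no editing, no HP tags
        n_dna = int(
            cfg.contig_length * cfg.dna_coverage / cfg.dna_read_length
        )
        for ri in range(n_dna):
            start = int(
                rng.integers(0, cfg.contig_length - cfg.dna_read_length)
            )
            hap = int(rng.integers(1, 3))
            pos, cigar, rseq = _emit_read(
                rng, seq, [(start, start + cfg.dna_read_length)],
                events[hap], {}, cfg,
            )
            name = f"{contig}_d{ri}"
            dna_reads.append(
                AlignedRead(
                    name=name, contig=contig, pos=pos, mapq=60,
                    strand="forward" if rng.random() < 0.5 else "reverse",
                    cigar=cigar, seq=rseq,
                )
            )
            read_haplotype[name] = hap

    truths.sort(key=lambda t: (t.contig, t.pos))
    rna_reads.sort(key=lambda r: (r.contig, r.pos))
    dna_reads.sort(key=lambda r: (r.contig, r.pos))
    return SimOutput(
        config=cfg,
        ref=ref,
        rna_reads=rna_reads,
        dna_reads=dna_reads,
        truths=truths,
        expressed_vaf=expressed_vaf,
        editing_sites=editing_sites,
        genes=all_genes,
        hc_regions=hc_regions,
        read_haplotype=read_haplotype,
    )


# ---------------------------------------------------------------------------
# Generative pileup oracle
# ---------------------------------------------------------------------------

def expected_pileup(
    sim: SimOutput, contig: str, pos: int, rna: bool = True
) -> SitePileup:
    """Reconstruct the pileup at one site directly from the emitted
    read records, independently of the candidates-module engine.

    Walks each read's CIGAR with plain per-op bookkeeping (no shared
    code with RegionPileup) and tallies the same 18 channels.
    """
    from collections import Counter

    reads = sim.rna_reads if rna else sim.dna_reads
    counts = np.zeros(18, dtype=np.int64)
    ins_seqs: Counter = Counter()
    del_lens: Counter = Counter()
    for read in reads:
        if read.contig != contig or read.is_secondary or read.is_supplementary:
            continue
        if read.mapq < 5:
            continue
        if not (read.pos <= pos < read.reference_end):
            continue
        s = "+" if read.strand == "forward" else "-"
        rp = read.pos
        q = 0
        for op, ln in read.cigar:
            if op in "M=X":
                if rp <= pos < rp + ln:
                    base = read.seq[q + (pos - rp)]
                    if base in _BASES:
                        counts[_CH[base + s]] += 1
                rp += ln
                q += ln
            elif op == "I":
                if rp - 1 == pos:
                    counts[_CH["I_S" + s]] += 1
                    if ln == 1:
                        counts[_CH["I_1S" + s]] += 1
                    ins_seqs[read.seq[q : q + ln]] += 1
                q += ln
            elif op == "D":
                if rp == pos:
                    counts[_CH["D_S" + s]] += 1
                    if ln == 1:
                        counts[_CH["D_1S" + s]] += 1
                    del_lens[ln] += 1
                elif rp < pos < rp + ln:
                    counts[_CH["D_R" + s]] += 1
                rp += ln
            elif op == "N":
                rp += ln
            elif op == "S":
                q += ln
    ref_base = sim.ref[contig][pos] if pos < len(sim.ref[contig]) else "N"
    return SitePileup(
        contig=contig, pos=pos, ref_base=ref_base, counts=counts,
        ins_seqs=ins_seqs, del_lens=del_lens,
    )
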