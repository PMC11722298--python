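# Methods

This note documents the models, conventions and numerical choices behind
`rnacall`, in the spirit of a methods supplement: what is computed, under
which assumptions, and where genuinely open design questions were decided.

## Pileup model and coordinate conventions

All in-memory coordinates are 0-based half-open; 1-based formats (VCF,
GTF) are converted at file boundaries only.

The counting engine walks each alignment's CIGAR once. A read contributes
to depth (DP) at a position if it aligns a base there or deletes it;
spliced-over (`N`) stretches contribute nothing, which is what makes
RNA-seq coverage exon-shaped. Insertions are attributed to the reference
base immediately left of the inserted sequence (the VCF anchor).
Deletions are counted at their **first deleted base** (`D_S`, with `D_R`
for the remaining deleted positions); the emitted VCF record re-anchors
one base left, per VCF convention. The mapping between the two
conventions is `candidate_position()`. With this attribution, every
qualifying read contributes exactly one count among
{A, C, G, T, D_S, D_R} at each covered position, so the 12 base/deletion
channels sum to DP — an invariant the tests rely on.

Secondary alignments, supplementary alignments and reads with mapping
quality < 5 are excluded from every counting operation (depth, callable
regions, haplotag statistics). The 5 cutoff is the haplotagging
convention; it is applied uniformly because carrying two depth
definitions through the pipeline invites off-by-one-read bugs. No
base-quality filter is applied (long-read per-base qualities are not
part of the feature definition); a hook exists if one is wanted.

The interpretation of the `I_1S`/`D_1S` channels — indel starts of length
exactly 1, with `I_S`/`D_S` counting all starts — is a stand-in: the
feature list names "start" and "remaining" indel positions but the
precise split of the length-1 channels is not pinned down anywhere
authoritative. The chosen reading keeps the 18 channels non-redundant.

## Tensors and coverage normalization

A candidate tensor covers the candidate ± 16 positions (33 total) × 18
channels = 594 integers; window overhang beyond the contig edge is
zero-padded rather than shifted, consistent with the all-zero background
used for uncovered and spliced-over positions. Phasing appends 12
haplotype channels (`X_H1`, `X_H2`, strand-agnostic, indel starts only),
giving 33 × 30.

The coverage cap `C_T` is the nearest-rank 90th percentile of the
training coverage distribution (drop the top 10% of sites, take the
maximum of the rest). "Confidence interval" phrasings of this quantity
are ambiguous; nearest-rank is exact, integer-valued and monotone.
Candidate coverage `C_I` is measured at the **center position only**, as
the sum of base and deletion support on both strands (equal to DP).
Above the cap, all 594 entries scale by `C_T / C_I` and stay real-valued
— re-rounding would destroy exactly the small allele fractions the
normalization is meant to preserve.

## Label engineering

Truth-matched candidates are labeled with the inferred genotype from the
zygosity-switch cascade (defaults `VAF_HET = 0.5`, `VAF_HOM = 1.0`,
`VAF_Artifact = 0.08`, `ε = 0.2`). The cascade is evaluated strictly
top-to-bottom; with non-default `ε` that creates overlapping branches,
the first match wins. Multi-allelic 1/2 truths are handled minimally: an
alt whose observed fraction falls below the artifact level is dropped
and the remaining alt re-inferred as bi-allelic; if both survive, 1/2
stands; if neither, the site is hom-ref.

The zygosity head has three classes (hom-ref, het, hom-var); 1/2 maps to
het. A hom-ref class is required because the cascade can produce 0/0 and
because artifact and editing-site candidates are first-class training
examples. Candidates matching the editing benchmark are labeled hom-ref
(both heads), teaching the network to treat editing evidence as
reference; non-truth candidates that passed the DP ≥ 4 / AD ≥ 2 /
AF > 0.08 gates are artifact examples, also hom-ref.

Coverage augmentation subsamples reads per-read Bernoulli at configured
fractions, carrying HP tags from the full-coverage haplotagging. HP-drop
augmentation zeroes the 12 phasing columns of randomly selected phased
examples (default probability 0.2, unspecified upstream and exposed as
config), emulating candidates that lose phasing at low coverage.

## Network and training

Architecture: two bidirectional LSTM layers (hidden 64 per direction),
flatten, two ReLU dense layers (128, 64), then the 21-class genotype
head and 3-class zygosity head — three fully connected stages in total. Where
descriptions of the dense depth disagree, three is used. The network is
implemented directly in NumPy with hand-written backpropagation; the
numerical gradient check in the test suite pins its correctness. This
keeps training deterministic, dependency-light and CPU-friendly.

Inputs enter the network as `log1p(count)`. Z-scoring per feature was
tried and rejected: it turns the semantically meaningful all-zero
padding into large nonzero constants and measurably degraded learning.

Loss is the focal loss per head (γ = 2), summed with equal weight. No
per-class weights are used: focal loss is itself the imbalance
mechanism, and class-weighted variants degraded accuracy in side-by-side
runs. The optimizer is Rectified Adam (β₁ = 0.9, β₂ = 0.999) with global
gradient-norm clipping at 5, a 1-epoch linear warm-up, initial learning
rate 2e-2 decaying ×0.95 per epoch, batch 32. The defaults were chosen
for convergence speed at desk scale on one CPU; much smaller rates
underfit badly within the epoch budget.

Training runs at most 30 epochs on a seeded 90/10 split and stops early
when the validation loss fails to decrease epoch-over-epoch for 5
consecutive epochs; the epoch with the best validation loss supplies the
final weights. The epoch-over-epoch reading (rather than
no-new-best-for-5) matters at desk scale, where the small validation
split is noisy.

## Call decision and VCF output

For each candidate the joint score of genotype class g is
`s(g) = P21(g) × Pzyg(z(g))`, with `z(g)` the zygosity consistent with g
given the reference base — the simplest combination of the two heads
consistent with "combined probabilities". The maximization is restricted
to classes whose alleles are the reference or have read support at the
site, with the heads' mass on unsupported alleles renormalized away:
allele identity, like indel length, is taken from the supporting read
evidence. (The network cannot see the reference base — the 18 features
are pure counts — so without this restriction it can only guess between,
say, a hom-var (C,C) and an edit-like (T,T) reading of an all-C column.)
A hom-ref argmax emits no record. Indel allele sequences come from the
supporting reads at the site: the most frequent insertion sequence /
deletion length, ties broken to the shortest.

QUAL follows standard VCF semantics: the phred-scaled probability that
the site is homozygous reference, computed from the normalized joint
scores (`−10·log10 P(hom-ref)`, capped at 60). This is a package
convention — no QUAL definition is inherited — and it is deliberately a
*variant-ness* confidence rather than an exact-genotype confidence,
matching what the FILTER thresholds (LowQual below QUAL 2 for PacBio, 8
for ONT, configurable) are meant to gate. Calls matching an editing-site
database entry (A>G / T>C with source agreement ≥ 2) are retagged
`RNAEditing`.

## Editing benchmark

The orthogonal benchmark scans RNA pileups for A>G and T>C mismatches
genome-wide, ignoring transcript strand (T>C is the opposite-strand
representation of the same A-to-I event), and cross-checks the same
positions in paired DNA. The printed boundary semantics are kept
literally: `≥` for the depth and RNA-fraction minima, strict `<` for the
DNA-fraction maximum. Each site is evaluated only under its own
ref-consistent pattern (an A site looks for G support, a T site for C
support); pooling both patterns at one site was considered and rejected
as double-counting. RNA/DNA fractions use the same pileup rules as
candidate scanning — one depth definition everywhere.

## Benchmarking comparator

The comparator is exact-match after allele normalization (shared
leading/trailing context trimmed, position shifted), not a
haplotype-aware comparison: at desk scale, with simulator-controlled
representations, exact matching is deterministic and sufficient, and
complex MNP decomposition is out of scope. PASS-only records are
benchmarked by default (configurable). Genotype-aware matching scores an
allele match with discordant genotype as one FP plus one FN; with
zygosity disregarded the same site is a TP, so the paired FP/FN
reduction equals the number of genotype-mismatch sites exactly — a
bookkeeping identity the tests assert. Matching is allele-level: records
are decomposed into per-allele normalized atoms, and with zygosity
disregarded a call whose alleles are a subset of a multi-allelic truth's
matches — a 1/2 truth expressed as a single allele in RNA is a zygosity
effect, not a novel allele. Undefined metrics (zero
denominators) are reported as NA, never 0. "Overall" counts each site
once; a site with both SNP and indel alleles appears in both
subcategory tables but once in Overall.

Gene categories use the Methods-style inclusive boundary (partially
covered iff `H ≥ α`); genes with `0 < H < α` get an explicit
`below_threshold` bucket rather than silence. Switch errors are counted
as transitions of the agree/disagree indicator between consecutive
phased het variants, invariant to globally flipping either haplotype
assignment — the standard switch-error definition. "Wholly phased" is
pure interval containment of the gene in a single phaseset; requiring
every het variant to be phased was considered and not adopted.

## Synthetic data generator

The simulator emulates, under one seed: a random-sequence diploid genome
with evenly spaced multi-exon genes; exonic SNPs (het/hom/multi-allelic
at 65/25/10%), 1–3 bp indels; A>G / T>C editing sites with per-site
edited fractions drawn uniform from (0.85, 1.0), i.e. benchmark-grade
high-editing sites; full-transcript spliced RNA reads with Poisson
per-gene coverage (mean 30), a 10% heavy-tail fraction at 5× coverage,
allele-biased expression in 30% of genes (major haplotype fraction 0.9 —
these genes produce the zygosity-switch cases), ~1.5% substitution
errors plus geometric micro-indels, and HP tags on 60% of reads; and a
paired unspliced, editing-free DNA sample at 20×. Reads are emitted
pre-aligned — coordinates are generative — because alignment is not part
of this package's scope.

What the simulator does **not** emulate, and what passing tests
therefore do not show: sequence-context effects (Alu enrichment of
editing sites, homopolymer indel errors), isoform structure beyond one
transcript per gene, mapping ambiguity and alignment artifacts,
reference bias, and realistic transcript-abundance distributions. In
particular, a synthetic A>G editing site and a synthetic A>G variant are
feature-identical up to their allele fractions, which overlap; the
residual confusion between them is irreducible in this setting and is
handled in the pipeline the same way it is handled in practice — by
tagging calls at known editing sites rather than by the network alone.

`expected_pileup` reconstructs any site's pileup directly from the
emitted reads with an independent bookkeeping path, serving as the
oracle against which the counting engine is verified exhaustively.

## Problem sizes used in the checks

The end-to-end recovery check trains on eight simulated 100 kb contigs
(~3,700 augmented candidate examples at two coverage levels) and
evaluates on a held-out 100 kb genome at the DP ≥ 10 / AD ≥ 4 cell with
zygosity disregarded, applying the inference-side coverage cap and
editing-site tagging, and gating calls at the PacBio QUAL threshold
(the simulator's ~1.5% error model emulates the high-accuracy
chemistries, for which that threshold is designed); the pileup-equivalence check covers every position
of a 100 kb, 30× spliced genome; the editing-recovery check plants 50
editing sites on a 60 kb genome. These sizes were chosen so the whole
suite runs comfortably on a single CPU while leaving each property
statistically meaningful.

## Known limitations

* The comparator is not haplotype-aware; complex representation
  differences beyond simple normalization would not match.
* The model is desk-scale: its accuracy ceiling on real data is not
  established here, and no pre-trained production weights are provided.
* The editing-site database schema is a minimal 6-column TSV stand-in;
  converting a real database export requires a small adapter.
* Deletion-spanning reads count toward DP (mapped coverage); pipelines
  that exclude them will report slightly different depths at deletion
  sites.
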