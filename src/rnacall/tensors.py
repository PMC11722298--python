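"""Fixed-shape pileup input tensors and coverage normalization.

A candidate tensor summarizes 33 consecutive reference positions (the
candidate plus 16 flanking positions on each side) with 18 strand-split
count features per position — 594 integers per candidate. With phasing
enabled, 12 haplotype count features are appended, giving 30 features
per position. Positions with no covering reads (window overhang at
contig edges, spliced-over stretches) are all-zero background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .candidates import (
    N_FEATURES,
    N_HAP_FEATURES,
    DEFAULT_MIN_MAPQ,
    RegionPileup,
    _BASES,
    _CH,
)
from .formats import AlignedRead

WINDOW_FLANK = 16
WINDOW_SIZE = 2 * WINDOW_FLANK + 1  # 33
TENSOR_INTEGERS = WINDOW_SIZE * N_FEATURES  # 594

#: channels summed to measure candidate coverage C_I: reads supporting
#: A, C, G, T and deletions (starts + inside), both strands.
_COVERAGE_CHANNELS = [
    _CH[b + s] for b in _BASES for s in "+-"
] + [_CH["D_S+"], _CH["D_S-"], _CH["D_R+"], _CH["D_R-"]]


@dataclass
class PileupTensor:
    contig: str
    pos: int  # center (candidate) position
    features: np.ndarray  # (33, 18) int or (33, 30); float after normalization

    @property
    def window_start(self) -> int:
        return self.pos - WINDOW_FLANK

    @property
    def phased(self) -> bool:
        return self.features.shape[1] == N_FEATURES + N_HAP_FEATURES

    @property
    def center_coverage(self) -> float:
        """C_I: reads supporting A/C/G/T and deletions at the center."""
        return float(
            self.features[WINDOW_FLANK, _COVERAGE_CHANNELS].sum()
        )


@dataclass(frozen=True)
class CoverageCap:
    c_t: int

    def __post_init__(self) -> None:
        if self.c_t < 1:
            raise ValueError("coverage cap must be >= 1")


def build_pileup_tensor(
    candidate,
    alignments: Iterable[AlignedRead],
    ref: Optional[dict[str, str]] = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> PileupTensor:
    """Build the 33x18 integer tensor around a candidate site.

    ``candidate`` needs ``contig`` and ``pos`` attributes (a
    CandidateSite or any site-like object). Window overhang beyond the
    contig start is zero-padded.
    """
    contig, pos = candidate.contig, candidate.pos
    lo = pos - WINDOW_FLANK
    hi = pos + WINDOW_FLANK + 1
    grid = np.zeros((WINDOW_SIZE, N_FEATURES), dtype=np.int64)
    rp = RegionPileup(
        alignments, contig, max(lo, 0), hi, min_mapq=min_mapq
    )
    offset = max(lo, 0) - lo
    grid[offset : offset + (rp.end - rp.start)] = rp.counts
    return PileupTensor(contig=contig, pos=pos, features=grid)


def estimate_coverage_cap(site_coverages: Sequence[float]) -> CoverageCap:
    """C_T from a training-sample coverage distribution.

    The top 10% of high-coverage sites are excluded and the maximum of
    the rest taken — the nearest-rank 90th percentile.
    """
    if len(site_coverages) == 0:
        raise ValueError("empty coverage sample")
    xs = sorted(site_coverages)
    k = math.ceil(0.9 * len(xs))
    return CoverageCap(c_t=max(int(xs[k - 1]), 1))


def normalize_tensor(tensor: PileupTensor, cap: CoverageCap) -> PileupTensor:
    """Scale a high-coverage tensor down to the training coverage cap.

    With candidate coverage C_I above the cap C_T, every feature is
    scaled by C_T / C_I (F_norm = F * C_T / C_I); otherwise the tensor
    is returned unchanged. Scaled values stay real-valued so small
    allele fractions survive.
    """
    c_i = tensor.center_coverage
    if c_i <= cap.c_t:
        return tensor
    scaled = tensor.features.astype(np.float64) * (cap.c_t / c_i)
    return PileupTensor(contig=tensor.contig, pos=tensor.pos, features=scaled)


def attach_phasing_features(
    tensor: PileupTensor, haplotype_counts: np.ndarray
) -> PileupTensor:
    """Concatenate the 12 per-position haplotype features (33x12 grid,
    H1 [A,C,G,T,I,D] then H2) onto an 18-feature tensor, giving 33x30."""
    if haplotype_counts.shape != (WINDOW_SIZE, N_HAP_FEATURES):
        raise ValueError(
            f"haplotype grid shape {haplotype_counts.shape} does not match "
            f"window ({WINDOW_SIZE}, {N_HAP_FEATURES})"
        )
    if tensor.features.shape[1] != N_FEATURES:
        raise ValueError("tensor already carries phasing features")
    feats = np.concatenate(
        [tensor.features, haplotype_counts.astype(tensor.features.dtype)],
        axis=1,
    )
    return PileupTensor(contig=tensor.contig, pos=tensor.pos, features=feats)
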