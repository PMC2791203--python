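"""Peak extraction from CCMs and global ranking of co-occurring locus pairs.

Peaks are extracted greedily per arm pair: take the global maximum of the
CCM, record it, zero out a square neighborhood around it (half-width 2
sigma by default) so one smooth blob yields one peak, and repeat until the
requested count is reached or no positive signal remains.  Per-pair peaks
are then pooled across all arm pairs, same-chromosome pairs optionally
discarded, and the pool sorted into a single ranked top-N list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cooccur.smooth import ConvolvedCooccurrenceMatrix


@dataclass(frozen=True)
class Peak:
    """A pair of genomic loci with its smoothed co-occurrence score."""

    chrom_a: str
    arm_a: str
    pos_a: int
    chrom_b: str
    arm_b: str
    pos_b: int
    score: float
    mode: str
    scale_bp: float
    rank: int | None = None

    @property
    def locus_a(self) -> tuple[str, str, int]:
        return (self.chrom_a, self.arm_a, self.pos_a)

    @property
    def locus_b(self) -> tuple[str, str, int]:
        return (self.chrom_b, self.arm_b, self.pos_b)


@dataclass
class RankedPeakList:
    """Globally ranked peaks for one (mode, scale): score non-increasing, ranks 1..N."""

    mode: str
    scale_bp: float
    N: int
    peaks: list[Peak] = field(default_factory=list)

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


def extract_peaks(
    ccm: ConvolvedCooccurrenceMatrix,
    max_peaks: int,
    exclusion_radius_bp: float | None = None,
) -> list[Peak]:
    """Greedy maxima of one CCM with a square exclusion neighborhood.

    ``exclusion_radius_bp`` defaults to 2 sigma.  Ties at the maximum break
    deterministically by (row, column) ascending.  Extraction stops once all
    remaining values are <= 0: negative scores never rank.
    """
    if exclusion_radius_bp is None:
        exclusion_radius_bp = 2.0 * ccm.sigma_bp
    if exclusion_radius_bp < 0:
        raise ValueError("exclusion radius must be >= 0")
    r = int(round(exclusion_radius_bp / ccm.spacing))
    work = ccm.values.copy()
    n_rows, n_cols = work.shape
    out: list[Peak] = []
    while len(out) < max_peaks:
        flat = int(np.argmax(work))  # first occurrence = (row, col) ascending
        j, k = divmod(flat, n_cols)
        score = work[j, k]
        if score <= 0:
            break
        out.append(
            Peak(
                chrom_a=ccm.chrom_a,
                arm_a=ccm.arm_a,
                pos_a=int(ccm.coords_a[j]),
                chrom_b=ccm.chrom_b,
                arm_b=ccm.arm_b,
                pos_b=int(ccm.coords_b[k]),
                score=float(score),
                mode=ccm.mode,
                scale_bp=ccm.scale_bp,
            )
        )
        work[max(0, j - r) : j + r + 1, max(0, k - r) : k + r + 1] = -np.inf
    return out


def _sort_key(p: Peak):
    return (-p.score, p.chrom_a, p.pos_a, p.chrom_b, p.pos_b, p.arm_a, p.arm_b)


def rank_global(
    per_pair_peaks: list[Peak],
    N: int,
    exclude_same_chromosome: bool = True,
    mode: str | None = None,
    scale_bp: float | None = None,
) -> RankedPeakList:
    """Pool per-arm-pair peaks into one ranked top-N list.

    Same-chromosome pairs (p/q arms of one chromosome) are computed but
    discarded here when the flag is set, mirroring a genome-wide analysis
    that disregards intra-chromosomal co-occurrence.  Ties in score break by
    genomic coordinates ascending, then arm labels, for reproducibility.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    pool = list(per_pair_peaks)
    if exclude_same_chromosome:
        pool = [p for p in pool if p.chrom_a != p.chrom_b]
    pool.sort(key=_sort_key)
    pool = pool[:N]
    ranked = [replace(p, rank=i + 1) for i, p in enumerate(pool)]
    if mode is None:
        mode = ranked[0].mode if ranked else "unknown"
    if scale_bp is None:
        scale_bp = ranked[0].scale_bp if ranked else float("nan")
    return RankedPeakList(mode=mode, scale_bp=float(scale_bp), N=N, peaks=ranked)
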