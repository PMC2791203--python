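"""Gene annotation of peaks and enrichment statistics.

Each peak locus is translated to the set of genes whose midposition lies
within one sigma of the peak coordinate (a 2-sigma window overall).  Two
questions are then asked of the resulting gene sets:

* cancer-gene enrichment — are known oncogenes / tumor suppressors
  over-represented among peak genes relative to the gene universe?
  (two-sided Fisher exact test on the 2x2 table);
* functional-interaction enrichment — the interaction ratio, the fraction
  of peak genes participating in at least one high-confidence cross-locus
  interaction, compared with the same ratio for randomly placed
  size-matched locus pairs (two-sided Fisher exact test on the counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact

from cooccur.grid import ArmDefinition, DEFAULT_SPACING
from cooccur.peaks import Peak, RankedPeakList


@dataclass(frozen=True)
class GeneRecord:
    """A gene located by its midposition, ``(start + end) // 2``."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")

    @property
    def midposition(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakGeneSets:
    """Gene sets of both loci of one peak."""

    peak: Peak
    genes_a: set[str]
    genes_b: set[str]


@dataclass
class EnrichmentResult:
    """A 2x2 contingency table with its Fisher exact test."""

    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    odds_ratio: float
    category: str


class InteractionTable:
    """Undirected gene-gene interactions with confidence in [0, 1].

    ``(a, b)`` and ``(b, a)`` are the same interaction; on duplicates the
    maximum confidence is kept.
    """

    def __init__(self, records: list[tuple[str, str, float]] | None = None):
        self._conf: dict[frozenset, float] = {}
        for a, b, c in records or []:
            self.add(a, b, c)

    def add(self, gene_a: str, gene_b: str, confidence: float) -> None:
        if not 0.0 <= confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {confidence}")
        if gene_a == gene_b:
            return  # self-interactions carry no cross-locus information
        key = frozenset((gene_a, gene_b))
        self._conf[key] = max(self._conf.get(key, 0.0), confidence)

    def confidence(self, gene_a: str, gene_b: str) -> float:
        return self._conf.get(frozenset((gene_a, gene_b)), 0.0)

    def __len__(self) -> int:
        return len(self._conf)


def genes_in_window(
    locus: tuple[str, str, int], sigma_bp: float, genes: list[GeneRecord]
) -> set[str]:
    """Genes with midposition within [locus - sigma, locus + sigma], inclusive."""
    if sigma_bp <= 0:
        raise ValueError("sigma_bp must be positive")
    chrom, _arm, pos = locus
    return {
        g.gene_id
        for g in genes
        if g.chromosome == chrom and abs(g.midposition - pos) <= sigma_bp
    }


def peak_gene_sets(
    peaks: list[Peak] | RankedPeakList, sigma_bp: float, genes: list[GeneRecord]
) -> list[PeakGeneSets]:
    """Gene sets for every peak in a list."""
    return [
        PeakGeneSets(
            peak=p,
            genes_a=genes_in_window(p.locus_a, sigma_bp, genes),
            genes_b=genes_in_window(p.locus_b, sigma_bp, genes),
        )
        for p in peaks
    ]


def fisher_enrichment(
    selected: set[str], category: set[str], universe: set[str], label: str = ""
) -> EnrichmentResult:
    """Two-sided Fisher exact test for category enrichment in ``selected``.

    Category genes outside the universe are dropped before testing, so the
    table margins are consistent with the reference gene set.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    category = category & universe
    a = len(selected & category)
    b = len(selected - category)
    c = len(category - selected)
    d = len(universe - (selected | category))
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(
        table=((a, b), (c, d)), p_value=float(p), odds_ratio=float(odds), category=label
    )


def interaction_pairs(
    genes_a: set[str],
    genes_b: set[str],
    interactions: InteractionTable,
    threshold: float = 0.9,
) -> set[frozenset]:
    """Cross-locus gene pairs with interaction confidence strictly above threshold.

    Within-locus pairs are excluded: only one gene from each locus.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    out: set[frozenset] = set()
    for ga in genes_a:
        for gb in genes_b:
            if ga == gb:
                continue
            if interactions.confidence(ga, gb) > threshold:
                out.add(frozenset((ga, gb)))
    return out


def interaction_ratio(
    gene_sets: list[PeakGeneSets],
    interactions: InteractionTable,
    threshold: float = 0.9,
) -> tuple[float, set[str], set[str]]:
    """Fraction of peak genes with at least one qualifying cross-locus interaction.

    Returns ``(ratio, interacting_genes, all_genes)`` with set semantics:
    a gene shared between peaks counts once in numerator and denominator.
    """
    if not gene_sets:
        raise ValueError("at least one peak required")
    interacting: set[str] = set()
    all_genes: set[str] = set()
    for gs in gene_sets:
        all_genes |= gs.genes_a | gs.genes_b
        for pair in interaction_pairs(gs.genes_a, gs.genes_b, interactions, threshold):
            interacting |= set(pair)
    if not all_genes:
        raise ValueError("no genes on any peak locus")
    return len(interacting) / len(all_genes), interacting, all_genes


def _draw_random_locus(
    rng: np.random.Generator,
    arms: list[ArmDefinition],
    arm_weights: np.ndarray,
    spacing: int,
) -> tuple[str, str, int]:
    i = rng.choice(len(arms), p=arm_weights)
    a = arms[i]
    n_grid = (a.end - a.start) // spacing + 1
    k = int(rng.integers(n_grid))
    return (a.chromosome, a.arm, a.start + k * spacing)


def random_loci_control(
    peak_list: RankedPeakList | list[Peak],
    genome: list[ArmDefinition],
    genes: list[GeneRecord],
    interactions: InteractionTable,
    threshold: float = 0.9,
    n_random: int = 100,
    seed: int | None = None,
    sigma_bp: float | None = None,
    spacing: int = DEFAULT_SPACING,
    distinct_chromosomes: bool = True,
) -> tuple[float, EnrichmentResult]:
    """Compare the observed interaction ratio against random locus pairs.

    Draws ``n_random`` pairs of loci uniformly over grid positions (arms
    weighted by grid length), windows size-matched to the observed sigma,
    computes the pooled random interaction ratio, and tests observed vs
    random interactor counts with a two-sided Fisher exact test on
    ``[[I_obs, G_obs - I_obs], [I_rand, G_rand - I_rand]]``.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    peaks = list(peak_list)
    if sigma_bp is None:
        if isinstance(peak_list, RankedPeakList):
            sigma_bp = peak_list.scale_bp / 6.0
        else:
            sigma_bp = peaks[0].scale_bp / 6.0
    for a in genome:
        if a.length < 2 * sigma_bp:
            raise ValueError(f"arm {a.name} shorter than the {2 * sigma_bp:.0f} bp window")
    obs_sets = peak_gene_sets(peaks, sigma_bp, genes)
    _, I_obs, G_obs = interaction_ratio(obs_sets, interactions, threshold)

    rng = np.random.default_rng(seed)
    weights = np.array([(a.end - a.start) // spacing + 1 for a in genome], dtype=float)
    weights /= weights.sum()
    rand_interacting: set[str] = set()
    rand_all: set[str] = set()
    for _ in range(n_random):
        while True:
            la = _draw_random_locus(rng, genome, weights, spacing)
            lb = _draw_random_locus(rng, genome, weights, spacing)
            if not distinct_chromosomes or la[0] != lb[0]:
                break
        ga = genes_in_window(la, sigma_bp, genes)
        gb = genes_in_window(lb, sigma_bp, genes)
        rand_all |= ga | gb
        for pair in interaction_pairs(ga, gb, interactions, threshold):
            rand_interacting |= set(pair)
    ratio_rand = len(rand_interacting) / len(rand_all) if rand_all else 0.0
    table = [
        [len(I_obs), len(G_obs) - len(I_obs)],
        [len(rand_interacting), len(rand_all) - len(rand_interacting)],
    ]
    odds, p = fisher_exact(table, alternative="two-sided")
    result = EnrichmentResult(
        table=tuple(tuple(row) for row in table),
        p_value=float(p),
        odds_ratio=float(odds),
        category="interaction-ratio vs random loci",
    )
    return ratio_rand, result
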