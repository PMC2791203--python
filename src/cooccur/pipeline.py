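"""Pipeline orchestration: per-arm-pair execution loop and configuration.

The genome-wide analysis decomposes exactly into independent tasks, one per
(arm pair, mode, scale): each task scores one pair of chromosome arms,
smooths the score matrix and extracts its local peaks.  For n arms, s
scales and 4 modes that is C(n, 2) * s * 4 tasks (8892 for a 39-arm genome
at 3 scales).  Only one arm-pair score matrix is resident at a time, so
grid spacing is the user's lever on memory.

Peaks from all tasks of one (comparison, scale) are pooled into a global
ranked top-N list.  Four mode matrices are computed but three comparisons
are reported: gain-loss and loss-gain peaks are merged into a single
"gain-loss" list (the mode field of each peak retains its direction).

All randomness flows from the single config seed; the random-loci control
for report r uses ``seed + index(r)``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from cooccur import io as cio
from cooccur.annotate import interaction_ratio, fisher_enrichment, peak_gene_sets, random_loci_control
from cooccur.channels import MODES, select_mode_columns, separate_signals
from cooccur.grid import DEFAULT_SPACING, build_grid, interpolate_dataset
from cooccur.network import build_graph, cluster_loci, locus_distance_matrix, prune_core
from cooccur.peaks import Peak, extract_peaks, rank_global
from cooccur.score import score_matrix
from cooccur.smooth import convolve_ccm, sample_kernel

logger = logging.getLogger("cooccur")

DEFAULT_SCALES = (2_000_000, 10_000_000, 20_000_000)

REPORTED_COMPARISONS = {
    "gain-gain": ("gain-gain",),
    "loss-loss": ("loss-loss",),
    "gain-loss": ("gain-loss", "loss-gain"),
}


@dataclass
class RunConfig:
    """Everything one genome-wide run needs.

    Scales are kernel widths in bp (sigma = scale / 6).  ``top_n`` bounds
    the primary ranked lists, ``network_top_n`` the list fed into network
    construction (smallest scale).
    """

    probes: str | None = None
    arms: str | None = None
    genes: str | None = None
    interactions: str | None = None
    categories: dict[str, str] = field(default_factory=dict)
    spacing: int = DEFAULT_SPACING
    scales: tuple[int, ...] = DEFAULT_SCALES
    modes: tuple[str, ...] = MODES
    top_n: int = 50
    network_top_n: int = 500
    interaction_threshold: float = 0.9
    core_fraction: float = 0.05
    cluster_cutoff: float = 10**7
    n_random: int = 100
    exclude_same_chromosome: bool = True
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        self.scales = tuple(int(s) for s in self.scales)
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")
        unknown = set(self.modes) - set(MODES)
        if unknown:
            raise ValueError(f"unknown modes {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def enumerate_ccm_tasks(
    arm_names: list[str],
    scales: tuple[int, ...] = DEFAULT_SCALES,
    modes: tuple[str, ...] = MODES,
) -> list[tuple[str, str, int, str]]:
    """All (arm_a, arm_b, scale, mode) tasks: C(n, 2) distinct arm pairs
    per scale and mode; self-pairs are never scored."""
    pairs = list(itertools.combinations(arm_names, 2))
    return [
        (a, b, scale, mode)
        for scale in scales
        for mode in modes
        for a, b in pairs
    ]


def _reported_lists(modes: tuple[str, ...]) -> dict[str, tuple[str, ...]]:
    out = {}
    for report, members in REPORTED_COMPARISONS.items():
        present = tuple(m for m in members if m in modes)
        if present:
            out[report] = present
    return out


def two_lineage_recovery(
    seed: int,
    n_samples: int = 60,
    amplitude: float = 1.0,
    noise_sd: float = 0.2,
    scale: int = 2_000_000,
    spacing: int = DEFAULT_SPACING,
    top_n: int = 10,
) -> dict:
    """Run the loss-loss analysis on the two-lineage positive control.

    Generates the lineage-specific co-deletion scenario at the given seed,
    runs grid interpolation, channel separation, scoring and smoothing at
    one scale over all arm pairs, and ranks the pooled peaks.  ``success``
    is True when the rank-1 and rank-2 peaks match two distinct planted
    within-lineage lesion pairs, each coordinate within 2 sigma of the
    planted lesion midpoints.
    """
    from cooccur.simulate import (
        generate_dataset,
        two_lineage_scenario,
        within_lineage_pairs,
    )

    arms, lesions = two_lineage_scenario(
        n_samples=n_samples, amplitude=amplitude, noise_sd=noise_sd
    )
    table, _ = generate_dataset(
        arms, lesions, n_samples=n_samples, probe_spacing=10_000,
        noise_sd=noise_sd, seed=seed,
    )
    tracks = cio.probe_tracks_from_table(table)
    grid = build_grid(arms, spacing)
    gm = interpolate_dataset(tracks, grid)
    gain, loss = separate_signals(gm)
    kernel = sample_kernel(scale / 6.0, spacing)
    chrom_of = {a.name: a.chromosome for a in arms}
    pool: list[Peak] = []
    for arm_a, arm_b, _, mode in enumerate_ccm_tasks(grid.arm_names, (scale,), ("loss-loss",)):
        sm = score_matrix(select_mode_columns(gain, loss, mode, arm_a, arm_b))
        ccm = convolve_ccm(
            sm, kernel, grid.arm_coords(arm_a), grid.arm_coords(arm_b),
            chrom_of[arm_a], chrom_of[arm_b],
        )
        pool.extend(extract_peaks(ccm, max_peaks=top_n))
    ranked = rank_global(pool, top_n, mode="loss-loss", scale_bp=scale)

    sigma = scale / 6.0
    planted = [
        frozenset(((a.chromosome, a.midpoint), (b.chromosome, b.midpoint)))
        for a, b in within_lineage_pairs(lesions)
    ]

    def match(peak: Peak):
        for pair in planted:
            (c1, m1), (c2, m2) = sorted(pair)
            ok_fwd = (
                peak.chrom_a == c1 and abs(peak.pos_a - m1) <= 2 * sigma
                and peak.chrom_b == c2 and abs(peak.pos_b - m2) <= 2 * sigma
            )
            ok_rev = (
                peak.chrom_a == c2 and abs(peak.pos_a - m2) <= 2 * sigma
                and peak.chrom_b == c1 and abs(peak.pos_b - m1) <= 2 * sigma
            )
            if ok_fwd or ok_rev:
                return pair
        return None

    top2 = ranked.peaks[:2]
    matches = [match(p) for p in top2]
    success = (
        len(top2) == 2
        and all(m is not None for m in matches)
        and matches[0] != matches[1]
    )
    return {"ranked": ranked, "success": success, "matches": matches, "planted": planted}


def run_pipeline(config: RunConfig, task_order: list[int] | None = None) -> dict:
    """Run the full analysis described by ``config``.

    Returns a result bundle with the ranked peak lists per (comparison,
    scale), enrichment results, networks per comparison, and the task
    count.  If ``config.outdir`` is set, TSV/BEDPE peak lists, enrichment
    TSVs, GraphML/SIF networks and a run manifest are written there; given
    identical config and seed the text outputs are byte-identical.
    ``task_order`` optionally permutes task execution (results are
    order-invariant; used to exercise that property).
    """
    if config.probes is None or config.arms is None:
        raise ValueError("config must provide probe and arm paths")
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    logger.info("reading inputs")
    tracks = cio.read_probe_table(config.probes)
    arms = cio.read_arms_bed(config.arms)
    grid = build_grid(arms, config.spacing)
    logger.info("grid: %d arms, %d positions", len(arms), grid.n_positions)
    gm = interpolate_dataset(tracks, grid)
    gain, loss = separate_signals(gm)

    tasks = enumerate_ccm_tasks(grid.arm_names, config.scales, config.modes)
    n_tasks = len(tasks)
    logger.info("enumerated %d CCM tasks", n_tasks)
    if task_order is not None:
        tasks = [tasks[i] for i in task_order]

    kernels = {scale: sample_kernel(scale / 6.0, config.spacing) for scale in config.scales}
    chrom_of = {a.name: a.chromosome for a in arms}
    per_key: dict[tuple[str, int], list[Peak]] = {}
    for arm_a, arm_b, scale, mode in tasks:
        pair = select_mode_columns(gain, loss, mode, arm_a, arm_b)
        sm = score_matrix(pair)
        ccm = convolve_ccm(
            sm,
            kernels[scale],
            grid.arm_coords(arm_a),
            grid.arm_coords(arm_b),
            chrom_of[arm_a],
            chrom_of[arm_b],
        )
        found = extract_peaks(ccm, max_peaks=max(config.top_n, config.network_top_n))
        per_key.setdefault((mode, scale), []).extend(found)
        logger.debug("%s x %s %s scale=%d: %d peaks", arm_a, arm_b, mode, scale, len(found))

    reports = _reported_lists(config.modes)
    peak_lists: dict[tuple[str, int], "object"] = {}
    network_lists: dict[str, "object"] = {}
    for report, members in reports.items():
        for scale in config.scales:
            pool = [p for m in members for p in per_key.get((m, scale), [])]
            ranked = rank_global(
                pool,
                config.top_n,
                exclude_same_chromosome=config.exclude_same_chromosome,
                mode=report,
                scale_bp=scale,
            )
            peak_lists[(report, scale)] = ranked
            if outdir:
                stem = f"peaks_{report}_scale{scale // 1_000_000}Mb"
                cio.write_peaks_tsv(ranked, outdir / f"{stem}.tsv")
                cio.write_peaks_bedpe(ranked, outdir / f"{stem}.bedpe")
        # network input: top network_top_n of the smallest scale
        scale0 = min(config.scales)
        pool0 = [p for m in members for p in per_key.get((m, scale0), [])]
        network_lists[report] = rank_global(
            pool0,
            config.network_top_n,
            exclude_same_chromosome=config.exclude_same_chromosome,
            mode=report,
            scale_bp=scale0,
        )

    genes = cio.read_genes_bed(config.genes) if config.genes else None
    interactions = cio.read_interactions(config.interactions) if config.interactions else None
    categories = {
        label: cio.read_gene_list(path) for label, path in config.categories.items()
    }

    enrichment_rows: list[dict] = []
    if genes is not None:
        universe = {g.gene_id for g in genes}
        for idx, ((report, scale), ranked) in enumerate(sorted(peak_lists.items())):
            if not len(ranked):
                continue
            sigma = scale / 6.0
            sets = peak_gene_sets(ranked, sigma, genes)
            selected = set().union(*[gs.genes_a | gs.genes_b for gs in sets])
            for label, cat in sorted(categories.items()):
                res = fisher_enrichment(selected, cat, universe, label=label)
                enrichment_rows.append(
                    {
                        "comparison": report, "scale_bp": scale, "test": f"category:{label}",
                        "n_selected": len(selected), "n_hits": res.table[0][0],
                        "p_value": res.p_value, "odds_ratio": res.odds_ratio,
                    }
                )
            if interactions is not None and selected:
                ratio, _, _ = interaction_ratio(sets, interactions, config.interaction_threshold)
                ratio_rand, res = random_loci_control(
                    ranked, arms, genes, interactions,
                    threshold=config.interaction_threshold,
                    n_random=config.n_random,
                    seed=config.seed + idx,
                    sigma_bp=sigma,
                    spacing=config.spacing,
                    distinct_chromosomes=config.exclude_same_chromosome,
                )
                enrichment_rows.append(
                    {
                        "comparison": report, "scale_bp": scale, "test": "interaction-ratio",
                        "n_selected": len(selected), "n_hits": res.table[0][0],
                        "p_value": res.p_value, "odds_ratio": res.odds_ratio,
                        "ratio_observed": ratio, "ratio_random": ratio_rand,
                    }
                )
    if outdir and enrichment_rows:
        import pandas as pd

        pd.DataFrame(enrichment_rows).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False, float_format=cio.FLOAT_FMT
        )

    networks: dict[str, dict] = {}
    for report, ranked in network_lists.items():
        if not len(ranked):
            continue
        loci = sorted({p.locus_a for p in ranked} | {p.locus_b for p in ranked})
        dm = locus_distance_matrix(loci)
        assignment = cluster_loci(dm, config.cluster_cutoff)
        graph = build_graph(loci, assignment, list(ranked))
        core = prune_core(graph, len(ranked), config.core_fraction)
        networks[report] = {"graph": graph, "core": core}
        if outdir:
            cio.write_network(graph, outdir / f"network_{report}.graphml", "graphml")
            cio.write_network(graph, outdir / f"network_{report}.sif", "sif")
            cio.write_network(core, outdir / f"core_{report}.graphml", "graphml")

    if outdir:
        import json

        manifest = {
            "config": asdict(config),
            "n_tasks": n_tasks,
            "n_arms": len(arms),
            "n_samples": len(tracks),
            "outputs": sorted(p.name for p in outdir.iterdir()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "peak_lists": peak_lists,
        "network_lists": network_lists,
        "enrichment": enrichment_rows,
        "networks": networks,
        "task_count": n_tasks,
        "grid": grid,
    }
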