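"""Genomic grid construction and probe-to-grid interpolation.

Array CGH probes are irregularly spaced along the genome.  All downstream
pairwise scoring works on an equally spaced genomic grid instead, one grid
per chromosome arm, so that every arm pair can be processed independently.
Probe measurements are transferred onto the grid with a kernel-weighted
regression using a triangular kernel of width twice the grid spacing: the
value at grid point ``g`` is the weighted mean of all probes within one
grid spacing of ``g``, with weight ``1 - |m - g| / spacing`` for a probe at
midposition ``m``.

Coordinates are 0-based throughout; arm intervals are half-open
``[start, end)`` for probe assignment, while grid points run from the arm
start in steps of the spacing up to and including the last step that fits
inside ``end``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_SPACING = 20_000
"""Default grid spacing in bp (20 kb)."""


@dataclass(frozen=True)
class ArmDefinition:
    """One chromosome arm: the unit of pairwise analysis.

    Parameters
    ----------
    chromosome : str
        Chromosome label, e.g. ``"1"`` or ``"chr1"``.
    arm : str
        Arm label, ``"p"`` or ``"q"``.
    start, end : int
        0-based half-open genomic interval of the arm in bp.
    """

    chromosome: str
    arm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.start >= self.end:
            raise ValueError(
                f"arm {self.chromosome}_{self.arm}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def name(self) -> str:
        return f"{self.chromosome}_{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


def validate_arms(arms: list[ArmDefinition]) -> None:
    """Check uniqueness of (chromosome, arm) and non-overlap within chromosomes."""
    if not arms:
        raise ValueError("empty arm list")
    seen: set[tuple[str, str]] = set()
    for a in arms:
        key = (a.chromosome, a.arm)
        if key in seen:
            raise ValueError(f"duplicate arm definition {a.name}")
        seen.add(key)
    by_chrom: dict[str, list[ArmDefinition]] = {}
    for a in arms:
        by_chrom.setdefault(a.chromosome, []).append(a)
    for chrom, chrom_arms in by_chrom.items():
        chrom_arms = sorted(chrom_arms, key=lambda a: a.start)
        for left, right in zip(chrom_arms, chrom_arms[1:]):
            if right.start < left.end:
                raise ValueError(
                    f"arms {left.name} and {right.name} overlap on chromosome {chrom}"
                )


@dataclass
class GenomicGrid:
    """Equally spaced genomic grid over a set of chromosome arms.

    Attributes
    ----------
    spacing : int
        Grid spacing in bp.
    arms : list of ArmDefinition
        Arm definitions, in the order their grid points are laid out.
    coords : ndarray of int
        Absolute bp coordinate of every grid point (concatenated arm blocks).
    arm_index : dict
        Maps arm name to the contiguous ``slice`` of its grid points.
    """

    spacing: int
    arms: list[ArmDefinition]
    coords: np.ndarray
    arm_index: dict[str, slice] = field(repr=False)

    @property
    def n_positions(self) -> int:
        return len(self.coords)

    @property
    def arm_names(self) -> list[str]:
        return [a.name for a in self.arms]

    def arm(self, name: str) -> ArmDefinition:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(f"unknown arm {name!r}")

    def arm_slice(self, name: str) -> slice:
        try:
            return self.arm_index[name]
        except KeyError:
            raise KeyError(f"unknown arm {name!r}") from None

    def arm_coords(self, name: str) -> np.ndarray:
        return self.coords[self.arm_slice(name)]

    def positions(self):
        """Yield ``(chromosome, arm, coordinate)`` for every grid point."""
        for a in self.arms:
            for c in self.coords[self.arm_index[a.name]]:
                yield (a.chromosome, a.arm, int(c))


@dataclass
class ProbeTrack:
    """Probe-level copy-number profile of one sample (log2 ratios)."""

    sample_id: str
    chromosomes: np.ndarray
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.chromosomes) == len(self.positions) == len(self.values)):
            raise ValueError("chromosomes, positions and values must have equal length")
        if np.any(~np.isfinite(self.values)):
            raise ValueError(f"sample {self.sample_id}: non-finite probe values")


@dataclass
class GridMatrix:
    """Tumors x grid-points matrix of interpolated log2 copy-number values.

    Grid points with no probe support are masked and carry value 0, keeping
    every downstream minimum and covariance finite.
    """

    sample_ids: list[str]
    grid: GenomicGrid
    values: np.ndarray
    mask: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def build_grid(arms: list[ArmDefinition], spacing: int = DEFAULT_SPACING) -> GenomicGrid:
    """Lay out an equally spaced grid over chromosome arms.

    Each arm contributes ``floor((end - start) / spacing) + 1`` grid points
    anchored at its start coordinate, so grids are arm-local and the arm-pair
    decomposition of the analysis is exact.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    validate_arms(arms)
    blocks: list[np.ndarray] = []
    arm_index: dict[str, slice] = {}
    offset = 0
    for a in arms:
        n = (a.end - a.start) // spacing + 1
        if a.length < spacing:
            raise ValueError(
                f"spacing {spacing} exceeds the length of arm {a.name} ({a.length} bp)"
            )
        coords = a.start + spacing * np.arange(n, dtype=np.int64)
        blocks.append(coords)
        arm_index[a.name] = slice(offset, offset + n)
        offset += n
    return GenomicGrid(
        spacing=spacing, arms=list(arms), coords=np.concatenate(blocks), arm_index=arm_index
    )


def interpolate_profile(
    probes: ProbeTrack, grid: GenomicGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate one probe track onto the grid with a triangular kernel.

    Returns ``(values, mask)``; masked grid points (no probe strictly within
    one grid spacing, or total weight zero) are set to 0.  Probes influence
    only grid points on their own arm, so no smoothing leaks across
    centromeres or chromosome boundaries.  A probe at exactly one spacing
    from a grid point gets weight 0 (open kernel support).
    """
    dg = grid.spacing
    num = np.zeros(grid.n_positions)
    den = np.zeros(grid.n_positions)
    assigned = np.zeros(len(probes.positions), dtype=bool)
    for a in grid.arms:
        sl = grid.arm_slice(a.name)
        n_arm = sl.stop - sl.start
        on_arm = (
            (probes.chromosomes == a.chromosome)
            & (probes.positions >= a.start)
            & (probes.positions < a.end)
        )
        assigned |= on_arm
        if not np.any(on_arm):
            continue
        m = probes.positions[on_arm]
        x = probes.values[on_arm]
        # Grid spacing equals the kernel half-width, so a probe touches at
        # most the two grid points flanking it.
        rel = (m - a.start) / dg
        j_lo = np.floor(rel).astype(np.int64)
        for j, w in (
            (j_lo, 1.0 - (rel - j_lo)),
            (j_lo + 1, 1.0 - (j_lo + 1 - rel)),
        ):
            ok = (j >= 0) & (j < n_arm) & (w > 0)
            np.add.at(num, sl.start + j[ok], w[ok] * x[ok])
            np.add.at(den, sl.start + j[ok], w[ok])
    n_dropped = int(np.sum(~assigned))
    if n_dropped:
        warnings.warn(
            f"sample {probes.sample_id}: dropped {n_dropped} probe(s) outside all arms",
            stacklevel=2,
        )
    mask = den == 0
    values = np.zeros(grid.n_positions)
    np.divide(num, den, out=values, where=~mask)
    return values, mask


def interpolate_dataset(tracks: list[ProbeTrack], grid: GenomicGrid) -> GridMatrix:
    """Interpolate every sample onto the grid; row i is sample i's profile."""
    ids = [t.sample_id for t in tracks]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    values = np.zeros((len(tracks), grid.n_positions))
    mask = np.zeros((len(tracks), grid.n_positions), dtype=bool)
    for i, t in enumerate(tracks):
        values[i], mask[i] = interpolate_profile(t, grid)
    return GridMatrix(sample_ids=ids, grid=grid, values=values, mask=mask)
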