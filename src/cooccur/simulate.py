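"""Synthetic aCGH data with planted copy-number lesions.

Two generators cover the testable structure of the method:

* :func:`generate_archetype_pairs` builds the four canonical two-locus
  measurement patterns — random noise, a constitutive member (one locus
  always aberrated), a truly co-occurring pair, and a mutually exclusive
  pair — as raw sample vectors for direct scoring.

* :func:`generate_dataset` builds a probe-level log2-ratio table over a
  toy genome with planted lesions.  Lesions sharing a ``group_id`` are
  planted in the same carrier samples, which makes lineage scenarios
  expressible: :func:`two_lineage_scenario` emulates the V(D)J positive
  control, where one lineage carries co-deletions at T-cell-receptor-like
  loci on two chromosomes and the other at immunoglobulin-like loci on
  three.

Noise is i.i.d. Gaussian on the log2 ratios; the emulated samples are
clonal cell lines, so no tumor-cell-fraction dilution is modeled (a purity
factor scaling amplitudes is available but defaults to 1).  Probe positions
are jittered by less than half the probe spacing so probes and grid points
are misaligned by default, exercising the triangular-kernel regression
nontrivially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cooccur.grid import ArmDefinition, validate_arms


@dataclass(frozen=True)
class LesionSpec:
    """A planted gain or loss on one arm.

    Lesions sharing ``group_id`` are planted in the same carrier samples.
    Either ``carrier_fraction`` (carriers drawn at random) or ``carriers``
    (explicit sample indices) selects who is affected.
    """

    chromosome: str
    arm: str
    start: int
    end: int
    sign: str  # "gain" | "loss"
    amplitude: float = 1.0
    carrier_fraction: float | None = None
    carriers: tuple[int, ...] | None = None
    group_id: str | None = None

    def __post_init__(self) -> None:
        if self.sign not in ("gain", "loss"):
            raise ValueError(f"sign must be 'gain' or 'loss', got {self.sign!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.start >= self.end:
            raise ValueError("lesion start must be < end")
        if self.carriers is None and self.carrier_fraction is None:
            raise ValueError("specify carrier_fraction or carriers")
        if self.carrier_fraction is not None and not 0 < self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in (0, 1]")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SimulationTruth:
    """What was planted: carrier sets per lesion, lineage labels, noise level."""

    sample_ids: list[str]
    lineages: dict[str, str]  # sample_id -> group label ("" if none)
    lesion_carriers: list[list[str]]  # parallel to the lesion list
    noise_sd: float
    probe_spacing: int
    seed: int | None


def generate_archetype_pairs(
    n_samples: int,
    amplitude: float = 2.0,
    noise_sd: float = 0.1,
    seed: int | None = None,
    carrier_fraction: float = 0.5,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """The four canonical (u, v) measurement-pair patterns.

    random
        Noise only in both vectors.
    constitutive
        u fixed at ``amplitude`` in every sample; v two-level.
    co-occurring
        u and v two-level with a shared carrier set (concerted change).
    mutually-exclusive
        u and v two-level with disjoint carrier sets.

    At ``noise_sd=0`` the co-occurring pair has population covariance
    ``amplitude**2 * f * (1 - f)`` for carrier fraction f.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    k = int(round(carrier_fraction * n_samples))
    carriers = np.zeros(n_samples)
    carriers[:k] = 1.0
    anti = 1.0 - carriers

    def noisy(base: np.ndarray) -> np.ndarray:
        return base + rng.normal(0.0, noise_sd, n_samples)

    return {
        "random": (noisy(np.zeros(n_samples)), noisy(np.zeros(n_samples))),
        "constitutive": (noisy(np.full(n_samples, amplitude)), noisy(amplitude * carriers)),
        "co-occurring": (noisy(amplitude * carriers), noisy(amplitude * carriers)),
        "mutually-exclusive": (noisy(amplitude * carriers), noisy(amplitude * anti)),
    }


def _resolve_carriers(
    lesions: list[LesionSpec], n_samples: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Carrier sample indices per lesion; grouped lesions share one draw."""
    group_draw: dict[str, np.ndarray] = {}
    out: list[np.ndarray] = []
    for les in lesions:
        if les.carriers is not None:
            idx = np.asarray(les.carriers, dtype=int)
            if np.any(idx < 0) or np.any(idx >= n_samples):
                raise ValueError(f"carrier index out of range for lesion on {les.chromosome}_{les.arm}")
        elif les.group_id is not None and les.group_id in group_draw:
            idx = group_draw[les.group_id]
        else:
            k = int(round(les.carrier_fraction * n_samples))
            idx = np.sort(rng.choice(n_samples, size=k, replace=False))
        if les.group_id is not None:
            group_draw.setdefault(les.group_id, idx)
        out.append(idx)
    return out


def _check_contradictions(lesions: list[LesionSpec], carriers: list[np.ndarray]) -> None:
    for i in range(len(lesions)):
        for j in range(i + 1, len(lesions)):
            a, b = lesions[i], lesions[j]
            if a.sign == b.sign:
                continue
            if (a.chromosome, a.arm) != (b.chromosome, b.arm):
                continue
            if a.start < b.end and b.start < a.end and np.intersect1d(
                carriers[i], carriers[j]
            ).size:
                raise ValueError(
                    f"contradictory overlapping lesions on {a.chromosome}_{a.arm} "
                    "share carrier samples"
                )


def generate_dataset(
    arms: list[ArmDefinition],
    lesions: list[LesionSpec],
    n_samples: int,
    probe_spacing: int = 10_000,
    noise_sd: float = 0.2,
    seed: int | None = None,
    purity: float = 1.0,
    sample_prefix: str = "S",
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Probe-level log2-ratio table with planted lesions, plus the truth.

    Probes are laid every ``probe_spacing`` bp with uniform positional
    jitter below half the spacing; baseline is 0; carriers of a lesion get
    ``±amplitude * purity`` added over the lesion interval; i.i.d. Gaussian
    noise is added everywhere.  Returns a DataFrame with columns
    ``chrom  pos  <sample...>`` and a :class:`SimulationTruth`.
    """
    validate_arms(arms)
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be positive")
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    arm_of = {(a.chromosome, a.arm): a for a in arms}
    for les in lesions:
        arm = arm_of.get((les.chromosome, les.arm))
        if arm is None:
            raise ValueError(f"lesion references unknown arm {les.chromosome}_{les.arm}")
        if les.start < arm.start or les.end > arm.end:
            raise ValueError(f"lesion [{les.start}, {les.end}) outside arm {arm.name}")

    rng = np.random.default_rng(seed)
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(n_samples)]
    carriers = _resolve_carriers(lesions, n_samples, rng)
    _check_contradictions(lesions, carriers)

    chroms: list[str] = []
    pos_blocks: list[np.ndarray] = []
    val_blocks: list[np.ndarray] = []
    for a in arms:
        base = np.arange(a.start + probe_spacing // 2, a.end, probe_spacing)
        jitter = rng.integers(
            -(probe_spacing // 2 - 1), probe_spacing // 2, size=len(base)
        )
        pos = np.clip(base + jitter, a.start, a.end - 1)
        pos = np.sort(pos)
        vals = np.zeros((len(pos), n_samples))
        for les, idx in zip(lesions, carriers):
            if (les.chromosome, les.arm) != (a.chromosome, a.arm):
                continue
            in_les = (pos >= les.start) & (pos < les.end)
            delta = les.amplitude * purity * (1.0 if les.sign == "gain" else -1.0)
            vals[np.ix_(in_les, idx)] += delta
        chroms.extend([a.chromosome] * len(pos))
        pos_blocks.append(pos)
        val_blocks.append(vals)
    values = np.concatenate(val_blocks, axis=0)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.shape)

    table = pd.DataFrame({"chrom": chroms, "pos": np.concatenate(pos_blocks)})
    for j, sid in enumerate(sample_ids):
        table[sid] = values[:, j]

    lineages = {sid: "" for sid in sample_ids}
    for les, idx in zip(lesions, carriers):
        if les.group_id is None:
            continue
        for i in idx:
            sid = sample_ids[i]
            if lineages[sid] == "":
                lineages[sid] = les.group_id
            elif les.group_id not in lineages[sid].split("+"):
                lineages[sid] += f"+{les.group_id}"
    truth = SimulationTruth(
        sample_ids=sample_ids,
        lineages=lineages,
        lesion_carriers=[[sample_ids[i] for i in idx] for idx in carriers],
        noise_sd=noise_sd,
        probe_spacing=probe_spacing,
        seed=seed,
    )
    return table, truth


def two_lineage_scenario(
    n_samples: int = 60,
    amplitude: float = 1.0,
    noise_sd: float = 0.2,
    lesion_size: int = 2_000_000,
    arm_length: int = 20_000_000,
) -> tuple[list[ArmDefinition], list[LesionSpec]]:
    """Arms and lesions emulating lineage-specific V(D)J co-deletions.

    Lineage "T" (first half of the samples) carries co-occurring losses at
    two loci on chromosomes 1 and 2; lineage "B" (second half) at three
    loci on chromosomes 3, 4 and 5.  Within-lineage locus pairs co-occur;
    cross-lineage pairs are mutually exclusive.  Defaults follow the study
    conditions used throughout the test suite: 60 samples, amplitude 1.0,
    noise sd 0.2 (amplitude-to-noise 5), 2 Mb lesions.
    """
    arms = [ArmDefinition(str(c), "q", 0, arm_length) for c in range(1, 6)]
    mid = arm_length // 2
    half = lesion_size // 2
    t_carriers = tuple(range(n_samples // 2))
    b_carriers = tuple(range(n_samples // 2, n_samples))

    def lesion(chrom: str, carriers: tuple[int, ...], group: str) -> LesionSpec:
        return LesionSpec(
            chromosome=chrom,
            arm="q",
            start=mid - half,
            end=mid + half,
            sign="loss",
            amplitude=amplitude,
            carriers=carriers,
            group_id=group,
        )

    lesions = [
        lesion("1", t_carriers, "T"),
        lesion("2", t_carriers, "T"),
        lesion("3", b_carriers, "B"),
        lesion("4", b_carriers, "B"),
        lesion("5", b_carriers, "B"),
    ]
    return arms, lesions


def within_lineage_pairs(
    lesions: list[LesionSpec],
) -> list[tuple[LesionSpec, LesionSpec]]:
    """All pairs of lesions sharing a group_id, on different chromosomes."""
    out = []
    for i in range(len(lesions)):
        for j in range(i + 1, len(lesions)):
            a, b = lesions[i], lesions[j]
            if (
                a.group_id is not None
                and a.group_id == b.group_id
                and a.chromosome != b.chromosome
            ):
                out.append((a, b))
    return out
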