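"""Separation of the interpolated matrix into gain and loss channels.

Negative and positive log2 ratios denote loss and gain of DNA.  The two are
scored separately so they cannot cancel when summed: the gain channel keeps
positive values, the loss channel keeps the absolute value of negative ones,
and the original matrix is exactly gain - loss.  Scoring an arm pair in one
of the four modes (gain-gain, loss-loss, gain-loss, loss-gain) then amounts
to picking the corresponding channel submatrix for each arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cooccur.grid import GenomicGrid, GridMatrix

MODES = ("gain-gain", "loss-loss", "gain-loss", "loss-gain")


@dataclass
class ChannelMatrix:
    """Non-negative gain or loss channel of a :class:`GridMatrix`."""

    channel: str  # "gain" | "loss"
    sample_ids: list[str]
    grid: GenomicGrid
    values: np.ndarray


@dataclass
class ModePair:
    """Channel submatrices (U, V) for one arm pair in one mode."""

    mode: str
    arm_a: str
    arm_b: str
    U: np.ndarray  # T x P_a
    V: np.ndarray  # T x P_b


def separate_signals(A: GridMatrix) -> tuple[ChannelMatrix, ChannelMatrix]:
    """Split into non-negative gain and loss channels (A == gain - loss)."""
    if not np.all(np.isfinite(A.values)):
        raise ValueError("grid matrix contains non-finite values")
    gain = np.maximum(A.values, 0.0)
    loss = np.maximum(-A.values, 0.0)
    return (
        ChannelMatrix("gain", A.sample_ids, A.grid, gain),
        ChannelMatrix("loss", A.sample_ids, A.grid, loss),
    )


def select_mode_columns(
    gain: ChannelMatrix,
    loss: ChannelMatrix,
    mode: str,
    arm_a: str,
    arm_b: str,
) -> ModePair:
    """Pick the (U, V) submatrices for ``(mode, arm_a, arm_b)``.

    U comes from the gain channel iff the mode starts with "gain"; V from the
    gain channel iff it ends with "gain".  Same-arm pairs are rejected: arm
    pairs are distinct by construction.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if arm_a == arm_b:
        raise ValueError(f"arm pair must be distinct, got {arm_a!r} twice")
    first, second = mode.split("-")
    src_a = gain if first == "gain" else loss
    src_b = gain if second == "gain" else loss
    sl_a = gain.grid.arm_slice(arm_a)
    sl_b = gain.grid.arm_slice(arm_b)
    return ModePair(
        mode=mode,
        arm_a=arm_a,
        arm_b=arm_b,
        U=src_a.values[:, sl_a],
        V=src_b.values[:, sl_b],
    )
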