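"""Pairwise co-occurrence scoring: summed minimum weighted by covariance.

The minimum operation is the continuous analogue of Boolean AND: for two
grid points the min-sum ``M = sum_t min(u_t, v_t)`` is large only when both
loci are aberrated in the same tumors.  M alone is dominated by loci that
are ubiquitously aberrated regardless of their partner, so it is weighted by
the covariance ``C`` of the two columns across tumors; the score is the
elementwise product ``S = M * C``.  A truly co-occurring pair has both a
large shared amplitude (M) and concerted variation (C); a constitutively
aberrated locus has C near 0, and a mutually exclusive pair has C < 0.

Negative scores (anti-covarying pairs) are retained for diagnostics; peak
extraction takes maxima, so they never rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cooccur.channels import ModePair


@dataclass
class ScoreMatrix:
    """Raw co-occurrence scores for one arm pair and mode.

    M is the min-sum matrix, C the covariance matrix, S = M * C elementwise.
    """

    arm_a: str
    arm_b: str
    mode: str
    M: np.ndarray
    C: np.ndarray
    S: np.ndarray


def min_sum(u: np.ndarray, v: np.ndarray) -> float:
    """Sum across tumors of the elementwise minimum of two columns."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("min_sum expects non-negative channel values")
    return float(np.minimum(u, v).sum())


def covariance(u: np.ndarray, v: np.ndarray, ddof: int = 0) -> float:
    """Covariance of two columns across tumors.

    Defaults to the population convention (divide by T); set ``ddof=1`` for
    the sample convention.  Ranking is invariant to this constant.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    T = len(u)
    if T < 2:
        raise ValueError("covariance requires at least 2 samples")
    return float((u - u.mean()) @ (v - v.mean()) / (T - ddof))


def score_matrix(pair: ModePair, ddof: int = 0) -> ScoreMatrix:
    """Score every grid-point pair of one arm pair in one mode.

    ``M[j, k] = min_sum(U[:, j], V[:, k])``, ``C[j, k]`` the covariance of
    the same columns, ``S = M * C``.  The min-sum is accumulated sample by
    sample so at most one P_a x P_b temporary is live at a time.
    """
    U, V = pair.U, pair.V
    T, Pa = U.shape
    Pb = V.shape[1]
    if Pa == 0 or Pb == 0:
        raise ValueError("empty arm in mode pair")
    if T < 2:
        raise ValueError("scoring requires at least 2 samples")
    M = np.zeros((Pa, Pb))
    for t in range(T):
        M += np.minimum(U[t][:, None], V[t][None, :])
    Uc = U - U.mean(axis=0)
    Vc = V - V.mean(axis=0)
    C = (Uc.T @ Vc) / (T - ddof)
    return ScoreMatrix(
        arm_a=pair.arm_a, arm_b=pair.arm_b, mode=pair.mode, M=M, C=C, S=M * C
    )
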