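"""Maximum tolerated contour (MTC) machinery.

A dual-agent dose grid with I levels of Agent A (rows) and J levels of
Agent B (columns) is partitioned by a *contour*: a binary monotone matrix
whose entries mark combinations with toxicity above (1) or below (0) the
target rate ``theta``.  Monotonicity of toxicity in both agents restricts
the eligible contours to ``C(I+J, I)`` matrices (20 for a 3x3 grid).

Given independent Beta posteriors for the per-combination toxicity
probabilities, each contour receives a posterior probability proportional
to the product over cells of ``p_ij`` (below-target posterior probability)
where the contour says "below", and ``1 - p_ij`` where it says "above".
The modal contour is the current MTC estimate; if its probability exceeds
a threshold ``lambda`` the grid is judged to contain no combination close
to ``theta`` and a mid-trial dose insertion is triggered.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np
from scipy import stats

__all__ = [
    "BetaPosteriorGrid",
    "ContourSet",
    "MTCEstimate",
    "DegenerateDistributionError",
    "enumerate_contours",
    "below_target_prob",
    "contour_distribution",
    "insertion_triggered",
    "overdose_measure",
]

_MAX_DIM = 6


class DegenerateDistributionError(ValueError):
    """All contour weights are exactly zero (conflicting 0/1 posteriors)."""


@dataclass(frozen=True)
class ContourSet:
    """All monotone binary contours for a grid shape, in canonical order.

    Canonical order is lexicographic on the flattened matrices, fixed once
    per shape so that distribution indices are stable across calls.
    """

    shape: tuple[int, int]
    matrices: np.ndarray  # (S, I, J) uint8, read-only

    def __len__(self) -> int:
        return self.matrices.shape[0]

    def __iter__(self):
        return iter(self.matrices)


@dataclass
class BetaPosteriorGrid:
    """Per-combination independent Beta posteriors and the target rate.

    ``a`` and ``b`` are the *posterior* shape matrices, i.e. prior
    hyperparameters already updated with any observed counts.
    """

    a: np.ndarray
    b: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ValueError("a and b must have the same shape")
        if np.any(self.a <= 0) or np.any(self.b <= 0):
            raise ValueError("beta hyperparameters must be positive")
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.a.shape

    def below_target_probs(self) -> np.ndarray:
        """P(pi_ij <= theta) for every combination (regularized inc. beta)."""
        return stats.beta.cdf(self.theta, self.a, self.b)


@dataclass
class MTCEstimate:
    """Posterior distribution over contours and its mode."""

    contour: np.ndarray
    probability: float
    full_distribution: np.ndarray
    index: int = field(default=-1)


@lru_cache(maxsize=64)
def enumerate_contours(I: int, J: int) -> ContourSet:
    """Enumerate every monotone binary I x J contour exactly once.

    A monotone contour has rows of the form ``0...01...1`` with the count
    of leading zeros nonincreasing down the rows, giving ``C(I+J, I)``
    matrices in total.  Returned in lexicographic order of the flattened
    matrices (all-zeros first, all-ones last).
    """
    if I < 1 or J < 1:
        raise ValueError("grid dimensions must be >= 1")
    if I > _MAX_DIM or J > _MAX_DIM:
        raise ValueError(f"grid dimensions above {_MAX_DIM} are not supported")
    row_templates = np.zeros((J + 1, J), dtype=np.uint8)
    for z in range(J + 1):
        row_templates[z, z:] = 1  # z leading zeros then ones
    mats = []
    for zeros in itertools.product(range(J + 1), repeat=I):
        if all(zeros[i] >= zeros[i + 1] for i in range(I - 1)):
            mats.append(row_templates[list(zeros)])
    stack = np.array(mats, dtype=np.uint8)
    order = np.lexsort(stack.reshape(len(stack), -1).T[::-1])
    stack = stack[order]
    stack.setflags(write=False)
    assert len(stack) == comb(I + J, I)
    return ContourSet(shape=(I, J), matrices=stack)


def below_target_prob(n: int, y: int, a: float, b: float, theta: float) -> float:
    """Posterior P(pi <= theta) under a Beta(a, b) prior and y DLTs in n.

    The conjugate posterior is Beta(a + y, b + n - y); the probability is
    its CDF at ``theta``.
    """
    if y < 0 or n < 0 or y > n:
        raise ValueError("need 0 <= y <= n")
    if a <= 0 or b <= 0:
        raise ValueError("beta hyperparameters must be positive")
    if not 0 < theta < 1:
        raise ValueError("theta must lie in (0, 1)")
    return float(stats.beta.cdf(theta, a + y, b + n - y))


def contour_distribution(
    grid: BetaPosteriorGrid,
    contours: ContourSet | None = None,
    *,
    p: np.ndarray | None = None,
) -> MTCEstimate:
    """Posterior distribution over contours given the Beta posterior grid.

    Each contour C_s gets unnormalized weight
    ``prod_ij (1 - p_ij)^C_s[i,j] * p_ij^(1 - C_s[i,j])``
    with ``p_ij = P(pi_ij <= theta)``; weights are normalized to the
    posterior contour distribution.  Modal ties break by canonical order.

    ``p`` may be supplied directly to skip recomputing the Beta CDFs.
    """
    if p is None:
        p = grid.below_target_probs()
    p = np.asarray(p, dtype=float)
    if contours is None:
        contours = enumerate_contours(*p.shape)
    if contours.shape != p.shape:
        raise ValueError("contour set shape does not match grid shape")
    C = contours.matrices
    terms = np.where(C.astype(bool), 1.0 - p, p)  # (S, I, J)
    weights = terms.reshape(len(C), -1).prod(axis=1)
    total = weights.sum()
    if total <= 0:
        raise DegenerateDistributionError(
            "all contour weights are zero; posterior is degenerate"
        )
    dist = weights / total
    idx = int(np.argmax(dist))  # argmax returns first (canonical-order) tie
    return MTCEstimate(
        contour=C[idx], probability=float(dist[idx]), full_distribution=dist, index=idx
    )


def insertion_triggered(estimate: MTCEstimate, lambda_: float) -> bool:
    """True iff the modal contour probability strictly exceeds ``lambda``.

    ``lambda_ = 1`` therefore never triggers (insertion procedure off).
    """
    return estimate.probability > lambda_


def overdose_measure(estimate: MTCEstimate, contours: ContourSet) -> np.ndarray:
    """Expected probability q_ij of each combination lying above the MTC.

    q_ij = sum_s C_s[i,j] * P(MTC = C_s); monotone nondecreasing in both
    indices because every contour is.
    """
    return np.tensordot(estimate.full_distribution, contours.matrices, axes=(0, 0))
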