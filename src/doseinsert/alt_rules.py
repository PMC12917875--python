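"""Interval-probability insertion rules (alternatives to the MTC trigger).

Both rules partition the toxicity scale into an underdosing region
R1 = [0, 0.16), an acceptable region R2 = [0.16, 0.33] and an overdosing
region R3 = (0.33, 1], and work from the per-combination posterior
probabilities of landing in R1 and R3.  Monotonicity of toxicity in each
agent is enforced on these probabilities by clamping each combination to
its lower neighbors.

Rule 1 triggers when *every* combination is confidently outside the
acceptable region: each combination has P(R1) > C1 or P(R3) > C2.  (The
per-combination conjunction of both conditions is available as a strict
mode but is unsatisfiable for cutoffs >= 0.5, since P(R1) + P(R3) <= 1.)

Rule 2 triggers as soon as *some* combination has P(R1) > C1 while a
neighbor one level up in either agent has P(R3) > C2, provided no treated
combination shows an observed DLT ratio inside [1/6, 1/3] — the more
aggressive strategy of the two.

Insertion locations for both rules are the gaps where a confidently
underdosed combination sits directly below a confidently overdosed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .insertion import InsertionPlan
from .state import DoseGrid, TrialState

__all__ = [
    "IntervalProbs",
    "interval_probs",
    "alt1_trigger",
    "alt2_trigger",
    "alt_insertion_locations",
]

UNDER_BOUND = 0.16
OVER_BOUND = 0.33
DLT_RATIO_RANGE = (1.0 / 6.0, 1.0 / 3.0)


@dataclass(frozen=True)
class IntervalProbs:
    """Monotonicity-enforced P(pi in R1) and P(pi in R3) per combination."""

    p_under: np.ndarray
    p_over: np.ndarray
    regions: tuple[float, float] = (UNDER_BOUND, OVER_BOUND)


def _enforce_monotone(p_under: np.ndarray, p_over: np.ndarray):
    """Clamp in increasing (i, j) order: P(R1) nonincreasing and P(R3)
    nondecreasing along both agents, each cell taking its neighbor's value
    on violation.  Idempotent, and a no-op on already-monotone inputs."""
    pu = p_under.copy()
    po = p_over.copy()
    I, J = pu.shape
    for i in range(I):
        for j in range(J):
            if i > 0:
                pu[i, j] = min(pu[i, j], pu[i - 1, j])
                po[i, j] = max(po[i, j], po[i - 1, j])
            if j > 0:
                pu[i, j] = min(pu[i, j], pu[i, j - 1])
                po[i, j] = max(po[i, j], po[i, j - 1])
    return pu, po


def interval_probs(state: TrialState) -> IntervalProbs:
    """Posterior interval probabilities from the Beta(a + y, b + n - y)
    posteriors, with monotonicity enforced."""
    a = state.a + state.y
    b = state.b + state.n - state.y
    p_under = stats.beta.cdf(UNDER_BOUND, a, b)
    p_over = 1.0 - stats.beta.cdf(OVER_BOUND, a, b)
    pu, po = _enforce_monotone(p_under, p_over)
    return IntervalProbs(p_under=pu, p_over=po)


def alt1_trigger(probs: IntervalProbs, c1: float, c2: float,
                 strict: bool = False) -> bool:
    """Rule-1 trigger: every combination confidently outside R2."""
    if strict:
        cell_ok = (probs.p_under > c1) & (probs.p_over > c2)
    else:
        cell_ok = (probs.p_under > c1) | (probs.p_over > c2)
    return bool(cell_ok.all())


def alt2_trigger(probs: IntervalProbs, state: TrialState, c1: float,
                 c2: float) -> bool:
    """Rule-2 trigger: some gap looks crossed and no treated combination
    has an observed DLT ratio inside [1/6, 1/3]."""
    treated = state.n > 0
    if treated.any():
        ratio = np.where(treated, state.y / np.maximum(state.n, 1), np.nan)
        lo, hi = DLT_RATIO_RANGE
        if np.any((ratio >= lo) & (ratio <= hi)):
            return False
    pu, po = probs.p_under, probs.p_over
    gap_a = (pu[:-1, :] > c1) & (po[1:, :] > c2)
    gap_b = (pu[:, :-1] > c1) & (po[:, 1:] > c2)
    return bool(gap_a.any() or gap_b.any())


def alt_insertion_locations(probs: IntervalProbs, c1: float, c2: float,
                            grid: DoseGrid | None = None) -> InsertionPlan:
    """Gaps to bisect: an underdosed combination (P(R1) > C1) directly
    below an overdosed one (P(R3) > C2) in either agent.  Gaps already
    bridged by a previous insertion are dropped when a grid is given."""
    pu, po = probs.p_under, probs.p_over
    a_gaps = {int(i) for i in
              np.nonzero(((pu[:-1, :] > c1) & (po[1:, :] > c2)).any(axis=1))[0]}
    b_gaps = {int(j) for j in
              np.nonzero(((pu[:, :-1] > c1) & (po[:, 1:] > c2)).any(axis=0))[0]}
    if grid is not None:
        a_gaps = {i for i in a_gaps if grid.levels_a[i + 1] - grid.levels_a[i] == 1.0}
        b_gaps = {j for j in b_gaps if grid.levels_b[j + 1] - grid.levels_b[j] == 1.0}
    return InsertionPlan(frozenset(a_gaps), frozenset(b_gaps))
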