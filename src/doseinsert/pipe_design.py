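"""PIPE escalation design (product of independent beta probabilities).

Escalation is contour-guided: after each cohort the posterior over
monotone contours is recomputed and the next cohort is randomized among
admissible combinations, weighting each by the inverse of its
(prior-augmented) sample size so that experimentation varies around the
estimated maximum tolerated contour.

Admissible combinations must satisfy the dose-skipping constraint (no
level more than one above the highest tried level of either agent, and
no simultaneous escalation of both agents into untried levels), pass the
overdose rule q_ij < epsilon — q_ij being the contour-averaged posterior
probability of sitting above the MTC — and be adjacent to the estimated
contour.  Two contour point estimates are supported: the *median*
contour, obtained by thresholding q at 1/2 (default — robust when many
combinations are untested), and the *modal* contour maximizing the joint
contour posterior.  A trial stops for safety when the lowest combination
itself fails the overdose rule.

At the end of the trial a single combination is recommended: among
combinations with at least ``min_patients_select`` patients lying
closest below the final contour estimate, the one with posterior mean
toxicity nearest the target (random tie-break).
"""

from __future__ import annotations

import numpy as np

from .contour import MTCEstimate
from .state import DesignConfig, TrialState

__all__ = [
    "contour_adjacency",
    "closest_below",
    "median_contour",
    "estimate_contour_matrix",
    "neighbor_reachable",
    "pipe_admissible",
    "pipe_next_dose",
    "pipe_select_final",
]


def median_contour(q: np.ndarray) -> np.ndarray:
    """Median contour: combination counted above the MTC iff q_ij >= 1/2.

    Monotone because q inherits monotonicity from the contours.
    """
    return (np.asarray(q) >= 0.5).astype(np.uint8)


def estimate_contour_matrix(estimate: MTCEstimate, q: np.ndarray,
                            config: DesignConfig) -> np.ndarray:
    """The contour point estimate the host design works with."""
    if config.contour_estimator == "median":
        return median_contour(q)
    if config.contour_estimator == "modal":
        return estimate.contour
    raise ValueError(f"unknown contour estimator {config.contour_estimator!r}")


def contour_adjacency(contour: np.ndarray, mode: str = "adjacent") -> np.ndarray:
    """Boolean mask of combinations adjacent to a contour estimate.

    Below-adjacent: entries 0 whose next level of either agent is above
    the contour.  Above-adjacent: entries 1 whose previous level of
    either agent is below it.  ``mode="closest-below"`` keeps only the
    below side.  All-zeros and all-ones contours have no adjacency;
    callers fall back to the neighborhood-constrained set.
    """
    C = np.asarray(contour).astype(bool)
    below = np.zeros_like(C)
    below[:-1, :] |= ~C[:-1, :] & C[1:, :]
    below[:, :-1] |= ~C[:, :-1] & C[:, 1:]
    if mode == "closest-below":
        return below
    above = np.zeros_like(C)
    above[1:, :] |= C[1:, :] & ~C[:-1, :]
    above[:, 1:] |= C[:, 1:] & ~C[:, :-1]
    return below | above


def closest_below(contour: np.ndarray) -> np.ndarray:
    """Combinations below the contour that touch it (grid border included).

    Used for final selection: 0-entries whose next level of either agent
    is above the contour or off the grid.  For the all-zeros contour this
    is the set of highest-dose combinations (last row / last column).
    """
    C = np.asarray(contour).astype(bool)
    I, J = C.shape
    up = np.ones((I, J), dtype=bool)
    up[:-1, :] = C[1:, :]
    right = np.ones((I, J), dtype=bool)
    right[:, :-1] = C[:, 1:]
    return ~C & (up | right)


def neighbor_reachable(state: TrialState) -> np.ndarray:
    """Dose-skipping constraint relative to all previously used combinations.

    A combination is reachable when each agent's level is at most one
    above the highest level of that agent tried so far, excluding the
    corner that would escalate both agents into untried levels at once
    (no diagonal escalation).  De-escalation is unrestricted.
    """
    I, J = state.shape
    used = state.used_combos()
    mi = max(i for i, j in used)
    mj = max(j for i, j in used)
    mask = np.zeros((I, J), dtype=bool)
    mask[:min(mi + 2, I), :min(mj + 2, J)] = True
    if mi + 1 < I and mj + 1 < J:
        mask[mi + 1, mj + 1] = False
    return mask


def pipe_admissible(state: TrialState, estimate: MTCEstimate, q: np.ndarray,
                    config: DesignConfig) -> set[tuple[int, int]]:
    """Admissible combinations for the next cohort.

    Intersection of the dose-skipping-reachable set with the
    overdose-safe set (q_ij < epsilon), filtered to combinations adjacent
    to the current contour estimate whenever that filter leaves anything;
    otherwise the unfiltered reachable-and-safe set is used, which keeps
    the trial progressing when the contour estimate lies outside the
    experimented region (e.g. the all-zeros contour at trial start).

    Empty result (in particular when d11 itself fails the overdose rule)
    signals termination to the caller.
    """
    if not state.history:
        return {(0, 0)}  # first cohort is forced at the lowest combination
    if q[0, 0] >= config.epsilon_pipe:
        return set()
    safe = q < config.epsilon_pipe
    base = neighbor_reachable(state) & safe
    C_est = estimate_contour_matrix(estimate, q, config)
    filtered = base & contour_adjacency(C_est, config.adjacency)
    chosen = filtered if filtered.any() else base
    return {(int(i), int(j)) for i, j in zip(*np.nonzero(chosen))}


def pipe_next_dose(admissible: set[tuple[int, int]], state: TrialState,
                   rng: np.random.Generator) -> tuple[int, int]:
    """Weighted randomization: probability proportional to 1/(n_ij + s).

    The prior sample size s keeps weights finite at n = 0 and matches the
    inverse-sample-size weighting of the PIPE design.
    """
    if not admissible:
        raise ValueError("admissible set is empty")
    combos = sorted(admissible)
    weights = np.array([1.0 / (state.n[c] + state.prior_ss) for c in combos])
    idx = rng.choice(len(combos), p=weights / weights.sum())
    return combos[idx]


def pipe_select_final(state: TrialState, estimate: MTCEstimate,
                      config: DesignConfig, rng: np.random.Generator,
                      q: np.ndarray | None = None) -> tuple[int, int] | None:
    """Single recommended combination at the end of the trial.

    Among combinations treated on at least ``min_patients_select``
    patients and lying closest below the final contour estimate, the one
    whose posterior mean toxicity (a + y) / (a + b + n) is nearest the
    target is selected, choosing uniformly at random among exact ties.
    Returns None when the trial stopped early or no combination
    qualifies.
    """
    if state.terminated:
        return None
    if q is None:
        from .contour import enumerate_contours, overdose_measure
        q = overdose_measure(estimate, enumerate_contours(*state.shape))
    C_est = estimate_contour_matrix(estimate, q, config)
    n_ok = state.n >= config.min_patients_select
    eligible = closest_below(C_est) & n_ok
    if not eligible.any():
        # no well-tried combination touches the contour from below; fall back
        # to any well-tried combination below it
        eligible = (C_est == 0) & n_ok
    if not eligible.any():
        return None
    post_mean = (state.a + state.y) / (state.a + state.b + state.n)
    dist = np.where(eligible, np.abs(post_mean - config.theta), np.inf)
    ties = np.argwhere(dist == dist.min())
    pick = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
    return (int(pick[0]), int(pick[1]))
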