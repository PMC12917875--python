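"""Mid-trial dose-level insertion: where to insert, and grid expansion.

Once a rule (MTC threshold or an alternative interval rule) triggers, new
dose levels are placed at the midpoint between existing adjacent levels
wherever the estimated contour crosses between them.  Extrapolation
outside the original dose range is forbidden, so an all-zeros or all-ones
contour never yields an insertion.  Expansion carries all observed counts
over, interpolates prior means and the true toxicity landscape, rescales
the per-combination prior sample size to 1/(I'*J'), and restricts the
immediately following cohort to combinations containing a new level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .state import DesignConfig, DoseGrid, Scenario, TrialState, beta_hyperparams

__all__ = [
    "InsertionPlan",
    "insertion_candidates",
    "expand_state",
    "expand_truth",
    "window_open",
]


@dataclass(frozen=True)
class InsertionPlan:
    """Gap indices to bisect: ``i in a_gaps`` means a new Agent-A level
    between current levels i and i+1 (0-based); analogously for B."""

    a_gaps: frozenset[int]
    b_gaps: frozenset[int]

    def __bool__(self) -> bool:
        return bool(self.a_gaps or self.b_gaps)


def insertion_candidates(contour: np.ndarray, grid: DoseGrid | None = None) -> InsertionPlan:
    """Gaps the estimated contour crosses, eligible for a midpoint insertion.

    A gap between Agent-A levels i and i+1 qualifies when the contour has a
    0 -> 1 transition between rows i and i+1 in some column (and similarly
    for Agent B across columns).  Gaps already bridged by a previously
    inserted level are dropped: a midpoint can only be inserted between two
    levels still one original-index unit apart.  All-zeros and all-ones
    contours yield an empty plan (no extrapolation).
    """
    C = np.asarray(contour)
    a_gaps = {int(i) for i in np.nonzero(((C[:-1, :] == 0) & (C[1:, :] == 1)).any(axis=1))[0]}
    b_gaps = {int(j) for j in np.nonzero(((C[:, :-1] == 0) & (C[:, 1:] == 1)).any(axis=0))[0]}
    if grid is not None:
        la, lb = grid.levels_a, grid.levels_b
        a_gaps = {i for i in a_gaps if la[i + 1] - la[i] == 1.0}
        b_gaps = {j for j in b_gaps if lb[j + 1] - lb[j] == 1.0}
    return InsertionPlan(frozenset(a_gaps), frozenset(b_gaps))


def _expand_matrix(M: np.ndarray, a_gaps: frozenset[int], b_gaps: frozenset[int],
                   fill=None) -> np.ndarray:
    """Insert rows then columns at the given gaps.

    New entries are midpoints of the flanking rows/columns (so a new-row x
    new-column cell ends up as the mean of its four diagonal originals),
    or ``fill`` when given (used for count matrices, which start at 0).
    """
    M = np.asarray(M)
    out = M.astype(float) if fill is None else M
    for i in sorted(a_gaps, reverse=True):
        row = (np.full(out.shape[1], fill, dtype=out.dtype) if fill is not None
               else (out[i, :] + out[i + 1, :]) / 2.0)
        out = np.insert(out, i + 1, row, axis=0)
    for j in sorted(b_gaps, reverse=True):
        col = (np.full(out.shape[0], fill, dtype=out.dtype) if fill is not None
               else (out[:, j] + out[:, j + 1]) / 2.0)
        out = np.insert(out, j + 1, col, axis=1)
    return out


def _index_maps(shape, a_gaps, b_gaps):
    """Old-index -> new-index maps and the sets of new row/column indices."""
    I, J = shape
    row_map = {}
    offset = 0
    new_rows = set()
    for i in range(I):
        row_map[i] = i + offset
        if i in a_gaps:
            new_rows.add(i + offset + 1)
            offset += 1
    col_map = {}
    offset = 0
    new_cols = set()
    for j in range(J):
        col_map[j] = j + offset
        if j in b_gaps:
            new_cols.add(j + offset + 1)
            offset += 1
    return row_map, col_map, new_rows, new_cols


def expand_state(state: TrialState, plan: InsertionPlan,
                 prior_policy: str = "rescale") -> TrialState:
    """Return a new TrialState on the enlarged grid.

    Observed counts are carried over (new combinations start at n = y = 0)
    and prior means for new combinations are midpoints of their flanking
    originals.  Under the default ``"rescale"`` policy every combination is
    re-assigned the prior sample size 1/(I'*J') of the enlarged grid, with
    Beta hyperparameters a = m*s, b = (1-m)*s regenerated from the prior
    mean m.  The next cohort is restricted to combinations containing at
    least one of the new levels, and the insertion flag is set.
    """
    if not plan:
        raise ValueError("insertion plan is empty")
    la, lb = state.grid.levels_a, state.grid.levels_b
    if any(i < 0 or i >= len(la) - 1 for i in plan.a_gaps) or \
       any(j < 0 or j >= len(lb) - 1 for j in plan.b_gaps):
        raise ValueError("plan references a nonexistent gap")

    new_la = list(la)
    for i in sorted(plan.a_gaps, reverse=True):
        new_la.insert(i + 1, (la[i] + la[i + 1]) / 2.0)
    new_lb = list(lb)
    for j in sorted(plan.b_gaps, reverse=True):
        new_lb.insert(j + 1, (lb[j] + lb[j + 1]) / 2.0)
    grid = DoseGrid(tuple(new_la), tuple(new_lb), state.grid.original_shape)

    n = _expand_matrix(state.n, plan.a_gaps, plan.b_gaps, fill=0)
    y = _expand_matrix(state.y, plan.a_gaps, plan.b_gaps, fill=0)
    prior_mean = _expand_matrix(state.prior_mean, plan.a_gaps, plan.b_gaps)

    if prior_policy == "rescale":
        prior_ss = 1.0 / prior_mean.size
        a, b = beta_hyperparams(prior_mean, prior_ss, state.prior_matching)
    elif prior_policy == "keep":
        prior_ss = state.prior_ss
        a = _expand_matrix(state.a, plan.a_gaps, plan.b_gaps)
        b = _expand_matrix(state.b, plan.a_gaps, plan.b_gaps)
    else:
        raise ValueError(f"unknown prior policy {prior_policy!r}")

    row_map, col_map, new_rows, new_cols = _index_maps(state.shape, plan.a_gaps,
                                                       plan.b_gaps)
    history = [((row_map[i], col_map[j]), cn, cy) for (i, j), cn, cy in state.history]
    I2, J2 = prior_mean.shape
    candidates = frozenset(
        (i, j) for i in range(I2) for j in range(J2)
        if i in new_rows or j in new_cols
    )
    return replace(
        state, grid=grid, n=n, y=y, prior_mean=prior_mean, prior_ss=prior_ss,
        a=a, b=b, history=history, insertion_done=True,
        insertion_cohort=len(state.history), restrict_to_new=candidates,
    )


def expand_truth(scenario: Scenario, plan: InsertionPlan) -> Scenario:
    """Expand a true-toxicity landscape by midpoint interpolation.

    New rows/columns take the mean of their flanking values; a new-row x
    new-column cell takes the mean of its four diagonal originals.
    Monotone inputs stay monotone (asserted by the Scenario constructor).
    """
    if not plan:
        return scenario
    truth = _expand_matrix(scenario.truth, plan.a_gaps, plan.b_gaps)
    return Scenario(truth=truth, name=scenario.name)


def window_open(n_treated: int, config: DesignConfig,
                insertion_done: bool = False) -> bool:
    """True while a mid-trial insertion is still permitted.

    Insertions are prohibited before ``insertion_window[0]`` patients have
    been treated, after ``insertion_window[1]`` patients, and (by default)
    after one insertion has already been made.
    """
    lo, hi = config.insertion_window
    if insertion_done and config.single_insertion:
        return False
    return lo <= n_treated <= hi
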