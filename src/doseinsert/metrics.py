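"""Operating characteristics: selection classification, accuracy, utility.

Selections are classified by the *true* toxicity of the selected
combination: correct in [0.275, 0.325], acceptable in [0.16, 0.33]
(correct is a subset), subtherapeutic in [0, 0.16), toxic in (0.33, 1].
Trials without a selection count in every denominator.

The Accuracy Index rewards selection distributions concentrated near the
target:

    AI = 100 - 100 * I * J * sum_ij (pi_ij - theta)^2 rho_ij
                            / sum_ij (pi_ij - theta)^2

with rho_ij the proportion of trials selecting combination (i, j).  It is
evaluated on the original grid; trials that selected an inserted
combination contribute that combination's interpolated true toxicity to
the numerator while I*J and the denominator stay fixed at the original
shape, keeping runs with and without insertions comparable.  The Utility
Index is PCS + PAS - 2 * PTS (percentage points).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .state import Scenario

__all__ = [
    "CORRECT_RANGE",
    "ACCEPTABLE_RANGE",
    "OCSummary",
    "classify_combo",
    "accuracy_index",
    "utility_index",
    "summarize",
]

logger = logging.getLogger(__name__)

CORRECT_RANGE = (0.275, 0.325)
ACCEPTABLE_RANGE = (0.16, 0.33)


def classify_combo(pi_true: float) -> str:
    """Partition of [0, 1]: subtherapeutic / acceptable / correct / toxic.

    'acceptable' here means acceptable-but-not-correct; correct implies
    acceptable when aggregating.
    """
    if not 0 <= pi_true <= 1:
        raise ValueError("true toxicity must lie in [0, 1]")
    if pi_true < ACCEPTABLE_RANGE[0]:
        return "subtherapeutic"
    if pi_true > ACCEPTABLE_RANGE[1]:
        return "toxic"
    if CORRECT_RANGE[0] <= pi_true <= CORRECT_RANGE[1]:
        return "correct"
    return "acceptable"


def accuracy_index(selection_freq: np.ndarray, truth: Scenario | np.ndarray,
                   theta: float) -> float:
    """Accuracy Index for a selection-frequency matrix over a truth grid.

    ``selection_freq`` entries are proportions of trials selecting each
    combination; trials with no selection simply leave the total below 1.
    Returns 100 when every true toxicity equals theta (all selections are
    then perfect; the ratio is 0/0).
    """
    pi = truth.truth if isinstance(truth, Scenario) else np.asarray(truth, float)
    rho = np.asarray(selection_freq, dtype=float)
    if rho.shape != pi.shape:
        raise ValueError("selection frequencies must match the truth grid shape")
    if np.any(rho < 0) or rho.sum() > 1 + 1e-9:
        raise ValueError("selection frequencies must be proportions summing to <= 1")
    w = (pi - theta) ** 2
    denom = w.sum()
    if denom == 0:
        logger.info("accuracy_index: all true toxicities equal theta; returning 100")
        return 100.0
    return 100.0 - 100.0 * pi.size * float((w * rho).sum()) / float(denom)


def utility_index(pcs: float, pas: float, pts: float) -> float:
    """PCS + PAS - 2 * PTS, all in percentage points."""
    return pcs + pas - 2.0 * pts


@dataclass
class OCSummary:
    """Aggregated operating characteristics over simulated trials.

    Proportions are stored as percentages; ``pas`` includes correct
    selections, so ``pcs <= pas`` always.
    """

    pcs: float
    pas: float
    pss: float
    pts: float
    none_rate: float
    insertion_rate: float
    accuracy_index: float
    utility_index: float
    mean_n_acceptable: float
    mean_n_toxic: float
    n_trials: int
    selection_freq: np.ndarray = field(repr=False)
    scenario: str = ""
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "scenario": self.scenario,
            "PCS (%)": self.pcs,
            "PAS (%)": self.pas,
            "PSS (%)": self.pss,
            "PTS (%)": self.pts,
            "No selection (%)": self.none_rate,
            "Insertions (%)": self.insertion_rate,
            "Accuracy Index (%)": self.accuracy_index,
            "Utility Index (%)": self.utility_index,
            "Mean n acceptable": self.mean_n_acceptable,
            "Mean n toxic": self.mean_n_toxic,
            "n_trials": self.n_trials,
        }
        row.update(self.extra)
        return row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_row()])


def _maximal_grid_index(level: float) -> int:
    # original level v -> 2(v-1); inserted midpoints land on odd indices
    return int(round(2.0 * (level - 1.0)))


def summarize(results: list, truth: Scenario, theta: float = 0.30) -> OCSummary:
    """Aggregate per-trial results into operating characteristics.

    ``results`` are TrialResult objects from the engine; ``truth`` is the
    *original* (unexpanded) scenario.  Exposure means classify every
    treated combination — including inserted ones — by its true
    (interpolated) toxicity.  The selection-frequency matrix lives on the
    maximal (2 I0 - 1) x (2 J0 - 1) grid so inserted selections are visible.
    """
    if not results:
        raise ValueError("no trial results to summarize")
    n_trials = len(results)
    I0, J0 = truth.shape
    rho_max = np.zeros((2 * I0 - 1, 2 * J0 - 1))
    counts = {"correct": 0, "acceptable": 0, "subtherapeutic": 0, "toxic": 0}
    n_none = 0
    n_inserted = 0
    sq_err = 0.0
    acc_exposure = 0.0
    tox_exposure = 0.0
    lo, hi = ACCEPTABLE_RANGE
    for r in results:
        if r.inserted:
            n_inserted += 1
        ft = r.final_truth
        acc_exposure += r.exposure_n[(ft >= lo) & (ft <= hi)].sum()
        tox_exposure += r.exposure_n[ft > hi].sum()
        if r.selection is None:
            n_none += 1
            continue
        counts[classify_combo(r.selection_true_tox)] += 1
        sq_err += (r.selection_true_tox - theta) ** 2
        ia = _maximal_grid_index(r.selection_levels[0])
        jb = _maximal_grid_index(r.selection_levels[1])
        rho_max[ia, jb] += 1.0 / n_trials

    pcs = 100.0 * counts["correct"] / n_trials
    pas = 100.0 * (counts["correct"] + counts["acceptable"]) / n_trials
    pss = 100.0 * counts["subtherapeutic"] / n_trials
    pts = 100.0 * counts["toxic"] / n_trials
    none_rate = 100.0 * n_none / n_trials

    w_denom = ((truth.truth - theta) ** 2).sum()
    if w_denom == 0:
        ai = 100.0
    else:
        ai = 100.0 - 100.0 * truth.truth.size * (sq_err / n_trials) / w_denom
    return OCSummary(
        pcs=pcs, pas=pas, pss=pss, pts=pts, none_rate=none_rate,
        insertion_rate=100.0 * n_inserted / n_trials,
        accuracy_index=ai, utility_index=utility_index(pcs, pas, pts),
        mean_n_acceptable=acc_exposure / n_trials,
        mean_n_toxic=tox_exposure / n_trials,
        n_trials=n_trials, selection_freq=rho_max, scenario=truth.name,
    )
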