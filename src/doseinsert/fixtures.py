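"""Built-in toxicity scenarios, operational priors, and case-study data.

Scenarios A1-A3 are 3x3 landscapes with *no* acceptable combination in
the starting grid (the hard case an insertion method exists for); Z1 and
Z2 are the landscapes used to calibrate the BLRM operational priors.
The case-study data are the observed DLT counts of a phase I neratinib +
temsirolimus combination trial, together with the procedure that turns
them into fixed per-combination response sequences for a design replay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .blrm_design import BLRMPriors
from .state import Scenario

__all__ = [
    "SCENARIO_NAMES",
    "load_scenario",
    "load_scenario_yaml",
    "pipe_prior",
    "blrm_priors",
    "CaseStudyData",
    "case_study_data",
    "reduced_case_study",
    "ResponseBook",
    "case_study_responses",
]

_SCENARIOS = {
    "A1": [[0.10, 0.45, 0.50], [0.45, 0.50, 0.60], [0.50, 0.60, 0.65]],
    "A2": [[0.05, 0.10, 0.45], [0.10, 0.45, 0.50], [0.45, 0.50, 0.60]],
    "A3": [[0.05, 0.05, 0.10], [0.05, 0.10, 0.45], [0.10, 0.45, 0.50]],
    "Z1": [[0.30, 0.40, 0.50], [0.40, 0.50, 0.65], [0.50, 0.60, 0.70]],
    "Z2": [[0.10, 0.20, 0.25], [0.20, 0.25, 0.30], [0.40, 0.50, 0.60]],
}

SCENARIO_NAMES = tuple(_SCENARIOS)


def load_scenario(name: str) -> Scenario:
    """Built-in true-toxicity scenario by name (A1-A3, Z1-Z2).

    Other landscapes (e.g. grids with acceptable combinations already
    present) are user-suppliable via :func:`load_scenario_yaml`.
    """
    try:
        return Scenario(truth=np.array(_SCENARIOS[name]), name=name)
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIO_NAMES)}"
        ) from None


def load_scenario_yaml(path) -> Scenario:
    """User-supplied landscape from YAML with keys ``name`` and ``truth``."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return Scenario(truth=np.array(spec["truth"], dtype=float),
                    name=str(spec.get("name", "custom")))


def pipe_prior(shape: tuple[int, int] = (3, 3)):
    """Operational PIPE prior: means, prior sample size, overdose threshold.

    Prior means rise by 0.025 per level of either agent from 0.05 at the
    lowest combination (0.05 ... 0.15 on a 3x3 grid); every combination
    carries prior sample size 1/(I*J), and the overdose rule threshold is
    epsilon = 0.5.
    """
    I, J = shape
    means = 0.05 + 0.025 * (np.add.outer(np.arange(I), np.arange(J)))
    return means, 1.0 / (I * J), 0.5


def blrm_priors() -> BLRMPriors:
    """Operational BLRM priors for the 3x3 grid (calibrated constants)."""
    return BLRMPriors()


@dataclass(frozen=True)
class CaseStudyData:
    """Observed DLT counts of the neratinib + temsirolimus trial.

    Rows are neratinib doses, columns temsirolimus doses; combinations
    never used have n = 0.  52 evaluable patients, 10 DLTs in total.
    """

    neratinib_mg: tuple[int, ...]
    temsirolimus_mg: tuple[int, ...]
    n: np.ndarray
    y: np.ndarray


def case_study_data() -> CaseStudyData:
    """Full 4x4 dosing grid of the case study."""
    n = np.array([[2, 4, 5, 4], [4, 4, 5, 6], [4, 8, 2, 0], [4, 0, 0, 0]])
    y = np.array([[0, 0, 1, 0], [1, 1, 0, 3], [0, 1, 1, 0], [2, 0, 0, 0]])
    return CaseStudyData(neratinib_mg=(120, 160, 200, 240),
                         temsirolimus_mg=(15, 25, 50, 75), n=n, y=y)


def reduced_case_study() -> CaseStudyData:
    """3x3 reduction used for the replay: the lowest temsirolimus dose and
    the highest neratinib dose are dropped."""
    full = case_study_data()
    return CaseStudyData(neratinib_mg=full.neratinib_mg[:3],
                         temsirolimus_mg=full.temsirolimus_mg[1:],
                         n=full.n[:3, 1:].copy(), y=full.y[:3, 1:].copy())


class ResponseBook:
    """Fixed ordered patient responses per combination for a design replay.

    For each combination of the reduced 3x3 grid the first n_ij responses
    are a random permutation of the observed y_ij DLTs and n_ij - y_ij
    non-DLTs (the same permutation for every design replayed with the same
    seed).  The remaining responses draw each patient an individual DLT
    probability from Beta(1 + y_ij, 1 + n_ij - y_ij) and then a Bernoulli
    response.  Combinations never used in the study — including any level
    inserted mid-replay — use Beta(3, 3) individual probabilities,
    reflecting that such combinations were avoided as unsafe.

    Responses are keyed by grid-level positions so they survive grid
    expansion, and consumed in order as cohorts are treated.
    """

    def __init__(self, max_n: int = 48, rng: np.random.Generator | None = None):
        self.max_n = max_n
        self._rng = np.random.default_rng() if rng is None else rng
        self.data = reduced_case_study()
        self._lists: dict[tuple[float, float], np.ndarray] = {}
        self._used: dict[tuple[float, float], int] = {}
        for i in range(3):
            for j in range(3):
                key = (float(i + 1), float(j + 1))
                self._lists[key] = self._build(self.data.n[i, j], self.data.y[i, j])
                self._used[key] = 0

    def _build(self, n: int, y: int) -> np.ndarray:
        resp = np.zeros(self.max_n, dtype=int)
        head_len = min(n, self.max_n)
        if n > 0:
            head = np.concatenate([np.ones(y, dtype=int), np.zeros(n - y, dtype=int)])
            resp[:head_len] = self._rng.permutation(head)[:head_len]
            p_tail = self._rng.beta(1 + y, 1 + n - y, size=self.max_n - head_len)
        else:
            p_tail = self._rng.beta(3, 3, size=self.max_n)
        resp[head_len:] = (self._rng.random(self.max_n - head_len) < p_tail).astype(int)
        return resp

    def responses(self, levels: tuple[float, float]) -> np.ndarray:
        if levels not in self._lists:  # inserted combination: never tested
            self._lists[levels] = self._build(0, 0)
            self._used[levels] = 0
        return self._lists[levels]

    def draw(self, levels: tuple[float, float], k: int) -> np.ndarray:
        """Consume the next ``k`` ordered responses at a combination."""
        resp = self.responses(levels)
        used = self._used[levels]
        if used + k > self.max_n:
            raise RuntimeError("response list exhausted (> max_n at one combination)")
        out = resp[used:used + k]
        self._used[levels] = used + k
        return out


def case_study_responses(max_n: int = 48,
                         rng: np.random.Generator | None = None) -> ResponseBook:
    """Build the fixed response sequences for a case-study replay."""
    return ResponseBook(max_n=max_n, rng=rng)
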