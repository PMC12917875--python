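"""Shared trial-state containers: dose grids, scenarios, configs, counts."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .contour import BetaPosteriorGrid

__all__ = ["DoseGrid", "Scenario", "DesignConfig", "TrialState", "beta_hyperparams"]


@lru_cache(maxsize=4096)
def _beta_from_median(med: float, ss: float) -> tuple[float, float]:
    f = lambda a: stats.beta.cdf(med, a, ss - a) - 0.5
    a = optimize.brentq(f, 1e-12 * ss, (1 - 1e-12) * ss, xtol=1e-14)
    return a, ss - a


def beta_hyperparams(location: np.ndarray, ss: float,
                     matching: str = "median") -> tuple[np.ndarray, np.ndarray]:
    """Beta hyperparameters with total mass ``ss`` per combination.

    ``matching="median"`` numerically solves for (a, b) with a + b = ss and
    prior median equal to ``location`` — the convention of the PIPE design,
    where the tiny prior mass makes the distribution U-shaped so the
    hyperparameter *split* (close to a = b = ss/2) matters far more than
    the nominal location.  ``matching="mean"`` uses the moment solution
    a = m * ss directly.
    """
    location = np.asarray(location, dtype=float)
    if matching == "mean":
        a = location * ss
    elif matching == "median":
        a = np.array([_beta_from_median(float(m), float(ss))[0]
                      for m in location.ravel()]).reshape(location.shape)
    else:
        raise ValueError(f"unknown prior matching {matching!r}")
    return a, ss - a


def _is_monotone(m: np.ndarray) -> bool:
    return bool(np.all(np.diff(m, axis=0) >= 0) and np.all(np.diff(m, axis=1) >= 0))


@dataclass(frozen=True)
class DoseGrid:
    """Ordered dose levels of both agents, tracking mid-trial insertions.

    Levels are stored as positions on the original index scale: original
    levels sit at 1, 2, ..., I0 and an inserted level at the midpoint
    (e.g. 1.5).  This makes "gap already bridged" checks trivial: a new
    level may only go between two levels exactly one unit apart.
    """

    levels_a: tuple[float, ...]
    levels_b: tuple[float, ...]
    original_shape: tuple[int, int]

    def __post_init__(self):
        for levels, n0 in ((self.levels_a, self.original_shape[0]),
                           (self.levels_b, self.original_shape[1])):
            if list(levels) != sorted(levels) or len(set(levels)) != len(levels):
                raise ValueError("dose levels must be strictly increasing")
            if len(levels) > 2 * n0 - 1:
                raise ValueError("grid exceeds maximal (2*I0-1, 2*J0-1) shape")

    @classmethod
    def initial(cls, I: int, J: int) -> "DoseGrid":
        return cls(tuple(float(i) for i in range(1, I + 1)),
                   tuple(float(j) for j in range(1, J + 1)), (I, J))

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.levels_a), len(self.levels_b))

    @property
    def inserted_a(self) -> tuple[bool, ...]:
        return tuple(lv != int(lv) for lv in self.levels_a)

    @property
    def inserted_b(self) -> tuple[bool, ...]:
        return tuple(lv != int(lv) for lv in self.levels_b)

    def n_inserted(self) -> int:
        return sum(self.inserted_a) + sum(self.inserted_b)


@dataclass(frozen=True)
class Scenario:
    """True toxicity landscape pi_ij, monotone in both agents."""

    truth: np.ndarray
    name: str = ""

    def __post_init__(self):
        t = np.asarray(self.truth, dtype=float)
        t.setflags(write=False)
        object.__setattr__(self, "truth", t)
        if np.any(t < 0) or np.any(t > 1):
            raise ValueError("true toxicity probabilities must lie in [0, 1]")
        if not _is_monotone(t):
            raise ValueError("scenario must be monotone nondecreasing in both agents")

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth.shape


@dataclass(frozen=True)
class DesignConfig:
    """Trial and design configuration with the simulation-study defaults."""

    theta: float = 0.30
    lambda_: float = 0.6             # MTC threshold; 1 disables insertions
    cohort_size: int = 3
    max_n: int = 48
    insertion_window: tuple[int, int] = (18, 42)
    single_insertion: bool = True    # at most one insertion timepoint
    epsilon_pipe: float = 0.5        # PIPE overdose threshold on q_ij
    min_patients_select: int = 6
    adjacency: str = "adjacent"      # or "closest-below"
    contour_estimator: str = "median"  # or "modal"
    # BLRM / EWOC
    ewoc_zeta: float = 0.33
    ewoc_epsilon: float = 0.40
    blrm_samples: int = 2000
    blrm_burn_in: int = 1000
    blrm_plugin: bool = True         # plug posterior parameter means into the model
    classical_interaction: bool = False
    # alternative insertion rules
    c1: float = 0.7
    c2: float = 0.7
    alt_strict: bool = False

    def __post_init__(self):
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if not 0 <= self.lambda_ <= 1:
            raise ValueError("lambda_ must lie in [0, 1]")
        if self.adjacency not in ("adjacent", "closest-below"):
            raise ValueError("adjacency must be 'adjacent' or 'closest-below'")
        if self.contour_estimator not in ("median", "modal"):
            raise ValueError("contour_estimator must be 'median' or 'modal'")


@dataclass
class TrialState:
    """Per-combination counts and Beta prior bookkeeping for one trial.

    ``a`` and ``b`` hold the *prior* hyperparameters; the posterior used by
    the contour machinery is Beta(a + y, b + n - y).
    """

    grid: DoseGrid
    n: np.ndarray
    y: np.ndarray
    prior_mean: np.ndarray
    prior_ss: float
    a: np.ndarray
    b: np.ndarray
    history: list = field(default_factory=list)  # (combo, cohort_n, cohort_dlts)
    insertion_done: bool = False
    insertion_cohort: Optional[int] = None
    terminated: bool = False
    termination_reason: Optional[str] = None
    restrict_to_new: Optional[frozenset] = None  # next-cohort candidates
    prior_matching: str = "median"

    @classmethod
    def from_prior(cls, prior_mean: np.ndarray, prior_ss: float,
                   matching: str = "median") -> "TrialState":
        prior_mean = np.asarray(prior_mean, dtype=float)
        I, J = prior_mean.shape
        a, b = beta_hyperparams(prior_mean, float(prior_ss), matching)
        return cls(
            grid=DoseGrid.initial(I, J),
            n=np.zeros((I, J), dtype=int),
            y=np.zeros((I, J), dtype=int),
            prior_mean=prior_mean,
            prior_ss=float(prior_ss),
            a=a,
            b=b,
            prior_matching=matching,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.n.shape

    @property
    def n_treated(self) -> int:
        return int(self.n.sum())

    def treat(self, combo: tuple[int, int], cohort_n: int, dlts: int) -> None:
        if self.terminated:
            raise RuntimeError("cannot treat patients on a terminated trial")
        if not 0 <= dlts <= cohort_n:
            raise ValueError("need 0 <= dlts <= cohort size")
        self.n[combo] += cohort_n
        self.y[combo] += dlts
        self.history.append((combo, cohort_n, dlts))

    def posterior_grid(self, theta: float) -> BetaPosteriorGrid:
        return BetaPosteriorGrid(a=self.a + self.y, b=self.b + self.n - self.y,
                                 theta=theta)

    def used_combos(self) -> set[tuple[int, int]]:
        return {combo for combo, _, _ in self.history}

    def copy(self) -> "TrialState":
        return replace(
            self, n=self.n.copy(), y=self.y.copy(), prior_mean=self.prior_mean.copy(),
            a=self.a.copy(), b=self.b.copy(), history=list(self.history),
        )
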