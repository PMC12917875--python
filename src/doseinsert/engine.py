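"""Trial and study orchestration.

A single simulated trial loops: treat a cohort at the current combination
(outcomes drawn against the scenario's true toxicity), update the Beta
posterior bookkeeping, check the insertion rule (inside the patient
window, before any escalation decision), then let the host design (PIPE
or BLRM) pick the next combination.  Directly after an insertion the next
cohort is restricted to combinations containing a new dose level.

Replicated studies use one random substream per (scenario, replicate):
patient outcomes are pre-drawn as per-combination uniform sequences on
the maximal expandable grid, so runs at different MTC thresholds share
outcome streams (common random numbers) and a threshold of 1 is bitwise
identical to turning the insertion rule off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import fixtures
from .alt_rules import alt1_trigger, alt2_trigger, alt_insertion_locations, interval_probs
from .blrm_design import (BLRMPriors, _patient_gain, blrm_fit, blrm_select_final,
                          ewoc_admissible)
from .contour import contour_distribution, enumerate_contours, insertion_triggered, overdose_measure
from .insertion import expand_state, expand_truth, insertion_candidates, window_open
from .metrics import classify_combo, summarize
from .pipe_design import neighbor_reachable, pipe_admissible, pipe_next_dose, pipe_select_final
from .state import DesignConfig, Scenario, TrialState

__all__ = ["TrialResult", "run_trial", "run_study", "replay_case_study"]

DESIGNS = ("pipe", "blrm")
INSERTION_RULES = ("mtc", "alt1", "alt2", "off")


@dataclass
class TrialResult:
    """Outcome of one simulated (or replayed) trial."""

    selection: Optional[tuple[int, int]]
    selection_levels: Optional[tuple[float, float]]
    selection_true_tox: float
    classification: Optional[str]
    exposure_n: np.ndarray
    exposure_y: np.ndarray
    final_truth: np.ndarray
    inserted: bool
    insertion_cohort: Optional[int]
    termination_reason: str
    n_treated: int
    seed: object = None
    trace: list = field(default_factory=list)


class _UniformOutcomes:
    """Per-combination uniform streams on the maximal grid.

    Each combination owns an ordered sequence of max_n uniforms keyed by
    its level positions; a patient's DLT indicator is u < pi_true.  The
    streams are drawn up-front so they do not depend on the escalation
    path or on whether/when an insertion happens.
    """

    def __init__(self, original_shape, max_n, rng):
        I0, J0 = original_shape
        self._u = rng.random((2 * I0 - 1, 2 * J0 - 1, max_n))
        self._used = np.zeros((2 * I0 - 1, 2 * J0 - 1), dtype=int)

    def draw(self, levels, k, pi_true):
        ia = int(round(2 * (levels[0] - 1)))
        jb = int(round(2 * (levels[1] - 1)))
        used = self._used[ia, jb]
        u = self._u[ia, jb, used:used + k]
        self._used[ia, jb] = used + k
        return (u < pi_true).astype(int)


def _check_insertion(state, truth, config, rule, trace):
    """Evaluate the insertion rule; return (state, truth, inserted?)."""
    if rule == "mtc":
        est = contour_distribution(state.posterior_grid(config.theta))
        if not insertion_triggered(est, config.lambda_):
            return state, truth, False
        plan = insertion_candidates(est.contour, state.grid)
        prob = est.probability
    else:
        probs = interval_probs(state)
        if rule == "alt1":
            trig = alt1_trigger(probs, config.c1, config.c2, config.alt_strict)
        else:
            trig = alt2_trigger(probs, state, config.c1, config.c2)
        if not trig:
            return state, truth, False
        plan = alt_insertion_locations(probs, config.c1, config.c2, state.grid)
        prob = None
    if not plan:
        return state, truth, False  # all-zeros/all-ones contour: nothing to bisect
    state = expand_state(state, plan)
    truth = expand_truth(truth, plan)
    if trace is not None:
        trace.append({"event": "insertion", "cohort": len(state.history),
                      "a_gaps": sorted(plan.a_gaps), "b_gaps": sorted(plan.b_gaps),
                      "modal_prob": prob, "new_shape": state.shape})
    return state, truth, True


def _restricted(choice_set, state, safe_mask):
    """Apply the post-insertion next-cohort restriction with fallbacks.

    Prefer design-admissible combinations containing a new level; fall
    back to overdose-safe new-level combinations if none, and to the
    unrestricted admissible set only if no new-level combination is safe.
    """
    R = state.restrict_to_new
    if R is None:
        return choice_set
    inter = choice_set & R
    if inter:
        return inter
    safe_new = {c for c in R if safe_mask[c]}
    return safe_new if safe_new else choice_set


def run_trial(design: str, insertion_rule: str, scenario: Scenario,
              config: DesignConfig | None = None,
              seed: int | np.random.SeedSequence = 0, *,
              blrm_prior_spec: BLRMPriors | None = None,
              response_book=None, collect_trace: bool = False) -> TrialResult:
    """Simulate (or replay) one dual-agent dose-finding trial.

    Outcomes come from Binomial draws against the scenario truth, or from
    a :class:`~doseinsert.fixtures.ResponseBook` when ``response_book`` is
    given (case-study replay; the scenario then only provides the grid
    shape and classification is suppressed).  The same
    (design, rule, scenario, config, seed) always yields the same result.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    if insertion_rule not in INSERTION_RULES:
        raise ValueError(f"insertion_rule must be one of {INSERTION_RULES}")
    config = config or DesignConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    outcome_ss, design_ss = ss.spawn(2)
    design_rng = np.random.default_rng(design_ss)

    prior_mean, prior_ss_val, _eps = fixtures.pipe_prior(scenario.shape)
    state = TrialState.from_prior(prior_mean, prior_ss_val)
    truth = scenario
    replay = response_book is not None
    outcomes = None if replay else _UniformOutcomes(
        scenario.shape, config.max_n, np.random.default_rng(outcome_ss))
    priors = blrm_prior_spec or fixtures.blrm_priors()
    trace: list = []
    next_combo: tuple[int, int] = (0, 0)

    while not state.terminated and state.n_treated < config.max_n:
        combo = next_combo
        k = min(config.cohort_size, config.max_n - state.n_treated)
        levels = (state.grid.levels_a[combo[0]], state.grid.levels_b[combo[1]])
        if replay:
            dlts = int(response_book.draw(levels, k).sum())
        else:
            dlts = int(outcomes.draw(levels, k, truth.truth[combo]).sum())
        state.treat(combo, k, dlts)
        if collect_trace:
            trace.append({"event": "cohort", "cohort": len(state.history),
                          "combo": combo, "levels": levels, "n": k, "dlts": dlts,
                          "total_n": state.n_treated})

        if insertion_rule != "off" and window_open(state.n_treated, config,
                                                   state.insertion_done):
            state, truth, _ = _check_insertion(
                state, truth, config, insertion_rule,
                trace if collect_trace else None)

        if state.n_treated >= config.max_n:
            break

        if design == "pipe":
            est = contour_distribution(state.posterior_grid(config.theta))
            contours = enumerate_contours(*state.shape)
            q = overdose_measure(est, contours)
            if q[0, 0] >= config.epsilon_pipe:
                state.terminated = True
                state.termination_reason = "toxicity_stop"
                break
            admissible = pipe_admissible(state, est, q, config)
            if not admissible:
                state.terminated = True
                state.termination_reason = "no_admissible"
                break
            choice_set = _restricted(admissible, state, q < config.epsilon_pipe)
            state.restrict_to_new = None
            next_combo = pipe_next_dose(choice_set, state, design_rng)
        else:
            post = blrm_fit(state, priors, config.blrm_samples, design_rng,
                            burn_in=config.blrm_burn_in, plugin=config.blrm_plugin,
                            classical_interaction=config.classical_interaction)
            mask = neighbor_reachable(state) & ewoc_admissible(post, priors)
            choice = {(int(i), int(j)) for i, j in zip(*np.nonzero(mask))}
            if not choice:
                state.terminated = True
                state.termination_reason = (
                    "toxicity_stop" if post.pi_exceed[0, 0] > priors.ewoc_epsilon
                    else "no_admissible")
                break
            choice = _restricted(choice, state, ewoc_admissible(post, priors))
            state.restrict_to_new = None
            sel_mask = np.zeros(state.shape, dtype=bool)
            for c in choice:
                sel_mask[c] = True
            nxt = _patient_gain(post.pi_mean, sel_mask, config.theta)
            next_combo = nxt

    # final selection
    selection = None
    if not state.terminated:
        if design == "pipe":
            est = contour_distribution(state.posterior_grid(config.theta))
            q = overdose_measure(est, enumerate_contours(*state.shape))
            selection = pipe_select_final(state, est, config, design_rng, q=q)
        else:
            post = blrm_fit(state, priors, config.blrm_samples, design_rng,
                            burn_in=config.blrm_burn_in, plugin=config.blrm_plugin,
                            classical_interaction=config.classical_interaction)
            selection = blrm_select_final(post, state, config)

    if selection is not None:
        sel_levels = (state.grid.levels_a[selection[0]],
                      state.grid.levels_b[selection[1]])
        if replay:
            sel_tox, classification = float("nan"), None
        else:
            sel_tox = float(truth.truth[selection])
            classification = classify_combo(sel_tox)
    else:
        sel_levels, sel_tox, classification = None, float("nan"), None

    return TrialResult(
        selection=selection, selection_levels=sel_levels,
        selection_true_tox=sel_tox, classification=classification,
        exposure_n=state.n, exposure_y=state.y, final_truth=truth.truth,
        inserted=state.insertion_done, insertion_cohort=state.insertion_cohort,
        termination_reason=state.termination_reason or "completed",
        n_treated=state.n_treated, seed=ss, trace=trace,
    )


def run_study(design: str, insertion_rule: str, scenarios, lambdas,
              n_reps: int = 1000, base_seed: int = 0,
              config: DesignConfig | None = None, *,
              share_outcome_streams: bool = True,
              blrm_prior_spec: BLRMPriors | None = None,
              theta: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Replicated operating-characteristics study over scenarios x lambdas.

    Returns a tidy DataFrame (one row per scenario x lambda) and the dict
    of full :class:`OCSummary` objects keyed by (scenario name, lambda).
    With ``share_outcome_streams`` (default) the same patient-outcome
    substream is reused across lambda values for each replicate, so the
    lambda = 1 column doubles as the insertions-off reference.
    """
    config = config or DesignConfig()
    scenarios = [fixtures.load_scenario(s) if isinstance(s, str) else s
                 for s in scenarios]
    rows, summaries = [], {}
    for s_idx, scen in enumerate(scenarios):
        for lam in lambdas:
            cfg = _with_lambda(config, lam)
            results = []
            for rep in range(n_reps):
                key = [base_seed, s_idx, rep]
                if not share_outcome_streams:
                    key.append(int(round(lam * 1000)))
                ss = np.random.SeedSequence(key)
                results.append(run_trial(design, insertion_rule, scen, cfg, ss,
                                         blrm_prior_spec=blrm_prior_spec))
            summ = summarize(results, scen, cfg.theta)
            summ.extra.update({"lambda": lam, "design": design,
                               "rule": insertion_rule})
            summaries[(scen.name, lam)] = summ
            rows.append(summ.to_row())
    return pd.DataFrame(rows), summaries


def _with_lambda(config: DesignConfig, lam: float) -> DesignConfig:
    from dataclasses import replace
    return replace(config, lambda_=lam)


def replay_case_study(design: str = "pipe", config: DesignConfig | None = None,
                      seed: int = 1, insertion_rule: str = "mtc") -> TrialResult:
    """Replay the neratinib + temsirolimus case study on the reduced 3x3 grid.

    Patient outcomes come from the fixed per-combination response
    sequences built from the observed trial data; the returned result
    carries a full cohort-by-cohort trace including any insertion event.
    """
    config = config or DesignConfig(
        lambda_=0.6 if design == "pipe" else 0.8)
    ss = np.random.SeedSequence([seed, 7])
    book_rng = np.random.default_rng(ss.spawn(1)[0])
    book = fixtures.case_study_responses(max_n=config.max_n, rng=book_rng)
    placeholder = Scenario(truth=np.full((3, 3), 0.5), name="case-study")
    return run_trial(design, insertion_rule, placeholder, config, seed,
                     response_book=book, collect_trace=True)
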