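"""Two-dimensional Bayesian logistic regression model (BLRM) with EWOC.

The joint toxicity probability of combination (i, j) combines two
single-agent logistic curves,

    logit(psi_A) = alpha1 + alpha2 * dA,   logit(psi_B) = beta1 + beta2 * dB,

through the no-interaction probability p+ = 1 - (1 - psi_A)(1 - psi_B)
and an interaction odds multiplier

    odds_ij = odds+_ij * exp(eta * log(1 + exp(dA) * exp(dB))),

where dA, dB are standardized doses.  alpha2 and beta2 are log-normal
(sampled on the log scale), so toxicity is monotone in each agent for
eta >= 0.  Escalation follows a patient-gain rule (posterior mean
toxicity closest to the target from below) restricted by a neighborhood
constraint and the escalation-with-overdose-control (EWOC) rule
P(pi_ij > zeta) <= epsilon.

Posterior sampling uses adaptive random-walk Metropolis-within-Gibbs on
(alpha1, log alpha2, beta1, log beta2, eta), run as a few parallel chains
for a split-chain convergence check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit

from .pipe_design import neighbor_reachable
from .state import DesignConfig, TrialState

__all__ = [
    "BLRMPriors",
    "BLRMPosterior",
    "joint_tox_prob",
    "blrm_fit",
    "ewoc_admissible",
    "blrm_next_dose",
    "blrm_select_final",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BLRMPriors:
    """Normal priors on (alpha1, log alpha2), (beta1, log beta2), eta and the
    per-agent prior toxicity probabilities (operational defaults from a
    cyclic calibration on a 3x3 grid).

    Standardized doses are chosen for *compatibility* with the prior
    toxicity probabilities: unless given explicitly, each agent's dose
    d satisfies expit(mu_intercept + E[slope] * d) = prior toxicity
    probability, with E[slope] the prior (log-normal) mean of the slope.
    """

    mu_alpha: tuple[float, float] = (-2.0, 0.5)
    sd_alpha: tuple[float, float] = (1.0, 0.5)
    mu_beta: tuple[float, float] = (-2.0, 0.5)
    sd_beta: tuple[float, float] = (1.0, 0.5)
    mu_eta: float = 0.0
    sd_eta: float = 0.5
    prior_tox_a: tuple[float, ...] = (0.10, 0.25, 0.40)
    prior_tox_b: tuple[float, ...] = (0.10, 0.25, 0.40)
    std_doses_a: tuple[float, ...] = None
    std_doses_b: tuple[float, ...] = None
    ewoc_zeta: float = 0.33
    ewoc_epsilon: float = 0.40

    def __post_init__(self):
        if any(s <= 0 for s in (*self.sd_alpha, *self.sd_beta, self.sd_eta)):
            raise ValueError("prior standard deviations must be positive")
        from scipy.special import logit
        if self.std_doses_a is None:
            slope = np.exp(self.mu_alpha[1] + self.sd_alpha[1] ** 2 / 2)
            d = (logit(np.asarray(self.prior_tox_a)) - self.mu_alpha[0]) / slope
            object.__setattr__(self, "std_doses_a", tuple(d))
        if self.std_doses_b is None:
            slope = np.exp(self.mu_beta[1] + self.sd_beta[1] ** 2 / 2)
            d = (logit(np.asarray(self.prior_tox_b)) - self.mu_beta[0]) / slope
            object.__setattr__(self, "std_doses_b", tuple(d))
        for d in (self.std_doses_a, self.std_doses_b):
            if list(d) != sorted(d) or len(set(d)) != len(d):
                raise ValueError("standardized doses must be strictly increasing")


@dataclass
class BLRMPosterior:
    """Retained parameter draws and per-combination posterior summaries."""

    samples: np.ndarray          # (S, 5): alpha1, alpha2, beta1, beta2, eta
    pi_mean: np.ndarray          # posterior mean toxicity per combination
    pi_exceed: np.ndarray        # P(pi_ij > zeta) per combination
    rhat: np.ndarray             # split-chain R-hat per sampled coordinate


def joint_tox_prob(params, d_a, d_b, classical_interaction: bool = False):
    """Joint toxicity probability of a combination under the 5-parameter model.

    ``params`` is (alpha1, alpha2, beta1, beta2, eta); inputs broadcast, so
    vectorized evaluation over draws and dose pairs is supported.  Computed
    in log-odds space to avoid overflow.  With ``classical_interaction``
    the odds multiplier is exp(eta * dA * dB) instead of the
    exp(eta * log(1 + exp(dA) exp(dB))) form.
    """
    a1, a2, b1, b2, eta = params
    d_a = np.asarray(d_a, dtype=float)
    d_b = np.asarray(d_b, dtype=float)
    za = a1 + a2 * d_a
    zb = b1 + b2 * d_b
    log_q = log_expit(-za) + log_expit(-zb)       # log P(no tox on either agent)
    p_dagger = -np.expm1(log_q)
    with np.errstate(divide="ignore"):
        log_odds0 = np.log(p_dagger) - log_q      # -inf when p_dagger == 0
    if classical_interaction:
        interaction = eta * d_a * d_b
    else:
        interaction = eta * np.logaddexp(0.0, d_a + d_b)
    return expit(log_odds0 + interaction)


def standardized_doses(priors: BLRMPriors, grid) -> tuple[np.ndarray, np.ndarray]:
    """Standardized doses on a (possibly expanded) grid.

    Original levels take the prior-calibrated values; inserted levels take
    the midpoint of their neighbors (linear interpolation on the original
    level index).
    """
    I0, J0 = grid.original_shape
    da = np.interp(grid.levels_a, np.arange(1, I0 + 1), priors.std_doses_a)
    db = np.interp(grid.levels_b, np.arange(1, J0 + 1), priors.std_doses_b)
    return da, db


def _log_posterior(x: np.ndarray, y, n_minus_y, d_a, d_b, priors: BLRMPriors,
                   classical: bool) -> np.ndarray:
    """Unnormalized log posterior, vectorized over chains.

    ``x`` has shape (chains, 5) on the sampling scale
    (alpha1, log alpha2, beta1, log beta2, eta).
    """
    a1, la2, b1, lb2, eta = x.T
    mu = np.array([priors.mu_alpha[0], priors.mu_alpha[1], priors.mu_beta[0],
                   priors.mu_beta[1], priors.mu_eta])
    sd = np.array([priors.sd_alpha[0], priors.sd_alpha[1], priors.sd_beta[0],
                   priors.sd_beta[1], priors.sd_eta])
    lp = -0.5 * (((x - mu) / sd) ** 2).sum(axis=1)
    if len(d_a):
        pi = joint_tox_prob(
            (a1[:, None], np.exp(la2)[:, None], b1[:, None], np.exp(lb2)[:, None],
             eta[:, None]), d_a[None, :], d_b[None, :], classical)
        pi = np.clip(pi, 1e-12, 1 - 1e-12)
        lp = lp + (y * np.log(pi) + n_minus_y * np.log1p(-pi)).sum(axis=1)
    return lp


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor per coordinate.

    ``draws`` has shape (chains, iterations, 5); each chain is split in
    half to double the chain count before the usual between/within
    variance ratio.
    """
    c, t, k = draws.shape
    half = t // 2
    segs = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    means = segs.mean(axis=1)
    W = segs.var(axis=1, ddof=1).mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / W)


def blrm_fit(state: TrialState, priors: BLRMPriors, n_samples: int = 2000,
             rng: np.random.Generator | None = None, *, burn_in: int = 1000,
             n_chains: int = 4, plugin: bool = True,
             classical_interaction: bool = False) -> BLRMPosterior:
    """Sample the 5-parameter posterior given all per-combination counts.

    ``n_samples`` retained draws are pooled over ``n_chains`` chains after
    ``burn_in`` iterations each; per-coordinate step sizes adapt during
    burn-in toward a 0.44 acceptance rate.  Non-convergence (split R-hat
    above 1.1) logs a warning but still returns the result.

    ``pi_mean`` is, by default, the plug-in estimate obtained by
    substituting the posterior mean of each parameter into the model;
    ``plugin=False`` averages the toxicity surface over the draws instead.
    ``pi_exceed`` always averages over the draws.
    """
    if n_samples < 100:
        raise ValueError("n_samples too small for a meaningful posterior")
    rng = np.random.default_rng() if rng is None else rng
    da_levels, db_levels = standardized_doses(priors, state.grid)
    obs = np.nonzero(state.n > 0)
    y_obs = state.y[obs].astype(float)
    nmy_obs = (state.n - state.y)[obs].astype(float)
    da_obs = da_levels[obs[0]]
    db_obs = db_levels[obs[1]]

    mu0 = np.array([priors.mu_alpha[0], priors.mu_alpha[1], priors.mu_beta[0],
                    priors.mu_beta[1], priors.mu_eta])
    sd0 = np.array([priors.sd_alpha[0], priors.sd_alpha[1], priors.sd_beta[0],
                    priors.sd_beta[1], priors.sd_eta])
    x = mu0 + sd0 * rng.standard_normal((n_chains, 5)) * 0.1
    lp = _log_posterior(x, y_obs, nmy_obs, da_obs, db_obs, priors,
                        classical_interaction)
    step = np.tile(sd0, (n_chains, 1))
    keep_per_chain = -(-n_samples // n_chains)
    kept = np.empty((n_chains, keep_per_chain, 5))
    accept = np.zeros((n_chains, 5))
    adapt_block = 50

    for it in range(burn_in + keep_per_chain):
        for k in range(5):
            prop = x.copy()
            prop[:, k] += step[:, k] * rng.standard_normal(n_chains)
            lp_prop = _log_posterior(prop, y_obs, nmy_obs, da_obs, db_obs,
                                     priors, classical_interaction)
            acc = np.log(rng.random(n_chains)) < lp_prop - lp
            x[acc] = prop[acc]
            lp[acc] = lp_prop[acc]
            accept[:, k] += acc
        if it < burn_in and (it + 1) % adapt_block == 0:
            rate = accept / adapt_block
            step *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
            accept[:] = 0.0
        if it >= burn_in:
            kept[:, it - burn_in] = x

    rhat = _split_rhat(kept)
    if np.any(rhat > 1.1):
        logger.warning("BLRM sampler convergence suspect: max split R-hat %.3f",
                       float(np.nanmax(rhat)))

    pooled = kept.reshape(-1, 5)[:n_samples]
    draws = pooled.copy()
    draws[:, 1] = np.exp(draws[:, 1])
    draws[:, 3] = np.exp(draws[:, 3])

    DA, DB = np.meshgrid(da_levels, db_levels, indexing="ij")
    pi_draws = joint_tox_prob(
        (draws[:, 0, None, None], draws[:, 1, None, None],
         draws[:, 2, None, None], draws[:, 3, None, None],
         draws[:, 4, None, None]),
        DA[None], DB[None], classical_interaction)
    pi_exceed = (pi_draws > priors.ewoc_zeta).mean(axis=0)
    if plugin:
        mean_params = draws.mean(axis=0)
        pi_mean = joint_tox_prob(tuple(mean_params), DA, DB, classical_interaction)
    else:
        pi_mean = pi_draws.mean(axis=0)
    return BLRMPosterior(samples=draws, pi_mean=pi_mean, pi_exceed=pi_exceed,
                         rhat=rhat)


def ewoc_admissible(posterior: BLRMPosterior, priors: BLRMPriors) -> np.ndarray:
    """EWOC mask: combination admissible iff P(pi_ij > zeta) <= epsilon."""
    return posterior.pi_exceed <= priors.ewoc_epsilon


def _patient_gain(pi_mean: np.ndarray, mask: np.ndarray,
                  theta: float) -> tuple[int, int] | None:
    """Admissible combination with posterior mean toxicity closest to theta
    from below; falls back to the smallest posterior mean when every
    admissible combination exceeds theta.  Ties break in index order."""
    if not mask.any():
        return None
    vals = np.where(mask, pi_mean, np.nan)
    below = np.where(vals <= theta, vals, -np.inf)
    if np.any(below > -np.inf):
        idx = np.unravel_index(np.nanargmax(below), vals.shape)
    else:
        idx = np.unravel_index(np.nanargmin(vals), vals.shape)
    return (int(idx[0]), int(idx[1]))


def blrm_next_dose(posterior: BLRMPosterior, state: TrialState,
                   config: DesignConfig,
                   priors: BLRMPriors) -> tuple[int, int] | None:
    """Next combination under the patient-gain rule, or None to terminate.

    Candidates must satisfy the neighborhood constraint and EWOC; among
    them the posterior mean toxicity closest to the target from below
    wins.  ``None`` means no combination is admissible and the trial stops.
    """
    if not state.history:
        return (0, 0)
    mask = neighbor_reachable(state) & ewoc_admissible(posterior, priors)
    return _patient_gain(posterior.pi_mean, mask, config.theta)


def blrm_select_final(posterior: BLRMPosterior, state: TrialState,
                      config: DesignConfig) -> tuple[int, int] | None:
    """Final recommendation: patient-gain criterion over combinations with
    at least ``min_patients_select`` patients; None when none qualify."""
    mask = state.n >= config.min_patients_select
    return _patient_gain(posterior.pi_mean, mask, config.theta)
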