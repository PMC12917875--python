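# Methods

This note records the statistical model behind `doseinsert`, the defaults
and what they mean, what the simulation engine does and does not emulate,
and the design decisions taken where the methodology leaves genuine room.

## Model and assumptions

Patients receive a combination (i, j) from an I × J grid of two agents with
binary DLT outcomes, y_ij ~ Binomial(n_ij, π_ij). The insertion layer makes
only two assumptions:

1. **Independent conjugate posteriors.** Each π_ij carries its own
   Beta(a_ij, b_ij) prior, updated to Beta(a_ij + y_ij, b_ij + n_ij − y_ij).
   Independence is what lets the layer detect sharp jumps in toxicity that a
   rigid parametric surface would smooth away.
2. **Monotonicity in each agent.** Toxicity is nondecreasing in the dose of
   either agent. This is encoded not in the per-cell posteriors but in the
   contour space: only monotone binary matrices are eligible MTC
   candidates, C(I+J, I) of them for an I × J grid.

The contour posterior weighs each eligible contour by the product of
per-cell probabilities of being on the side the contour claims. The
insertion trigger fires when the modal contour's posterior probability
strictly exceeds λ; the crossings of the modal contour determine which
midpoints are inserted. All-zeros and all-ones contours trigger nothing:
extrapolating outside the original dose range is forbidden.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| θ (`theta`) | 0.30 | target DLT probability |
| λ (`lambda_`) | 0.6 | MTC threshold; 1 disables insertions; values below 0.5 are not recommended (two contours can be equally likely when some π_ij ≈ θ) |
| cohort size | 3 | patients per escalation step |
| max n | 48 | total sample size |
| insertion window | (18, 42) | patients treated before/after which insertions are prohibited |
| ε (`epsilon_pipe`) | 0.5 | PIPE overdose bound on q_ij |
| ζ, ε (`ewoc_zeta/epsilon`) | 0.33, 0.40 | EWOC: require P(π_ij > ζ) ≤ ε |
| C₁ = C₂ (`c1`, `c2`) | 0.7 (rule 1), 0.6 (rule 2) | interval-rule cutoffs |
| min patients to select | 6 | a combination must carry ≥ 6 patients to be recommendable |
| PIPE prior | means 0.05–0.15, prior sample size 1/(I·J) | operational prior of the 3 × 3 grid |
| BLRM priors | α₁, β₁ ~ N(−2, 1); log α₂, log β₂ ~ N(0.5, 0.25); η ~ N(0, 0.25) | operational priors; prior toxicity probabilities (0.10, 0.25, 0.40) per agent |

## PIPE prior hyperparameters

The PIPE prior is specified by a location and a per-combination prior
sample size s = 1/(I·J). With so little prior mass the Beta distribution is
U-shaped and the *split* of mass between the two modes, a/(a+b), dominates
everything downstream. `beta_hyperparams` therefore solves numerically for
(a, b) with a + b = s and prior **median** equal to the stated location —
the convention of the PIPE design software, under which an untested
combination has posterior mean near 0.45 rather than near its nominal prior
mean. The moment solution a = m·s is available (`matching="mean"`) but is
not the default: besides mismatching the PIPE convention, it makes untested
cells vote "safe" with probability ≈ 0.9, which after a grid expansion
floods the contour posterior toward the all-zeros contour and disables the
overdose rule exactly when it is most needed.

After an insertion every combination — old and new — is re-assigned the
prior sample size 1/(I′·J′) of the enlarged grid (as small as 1/25 for
5 × 5), with prior means of new combinations interpolated as midpoints of
their flanking originals (new-row × new-column cells: the mean of the four
diagonal originals, which is what row-then-column midpoint interpolation
produces). Observed counts are carried over unchanged.

## PIPE escalation internals

The published description of the host design leaves several internals
open; each choice below is exposed in `DesignConfig` so the alternatives
can be run.

* **Contour point estimate** (`contour_estimator`): the design works with
  the *median* contour — q_ij, the contour-averaged posterior probability
  of sitting above the MTC, thresholded at 1/2 — rather than the modal
  contour (also available). With weak U-shaped priors the modal contour is
  unstable when many combinations are untested, while q aggregates over
  the whole contour posterior and inherits monotonicity. The insertion
  trigger and insertion locations always use the modal contour, which is
  how the insertion method itself is defined.
* **Dose-skipping constraint**: reachable combinations are those with each
  agent at most one level above the highest level of that agent tried so
  far, excluding the corner that escalates both agents into untried levels
  simultaneously (no diagonal escalation). De-escalation is unrestricted.
* **Adjacency** (`adjacency`): candidates are filtered to combinations
  adjacent to the contour estimate on either side (`"adjacent"`, default)
  or only from below (`"closest-below"`). When the filter would empty the
  reachable-and-safe set — e.g. the all-zeros contour at trial start — the
  unfiltered reachable-and-safe set is used so the trial can proceed.
* **Weighted randomization** uses weights 1/(n_ij + s); the prior sample
  size s keeps weights finite for untested combinations (and makes them
  strongly preferred, which is the point of the rule).
* **Final selection**: among combinations with ≥ 6 patients touching the
  final contour estimate from below (grid border counts as touching), the
  posterior mean toxicity closest to θ wins, with uniform random
  tie-breaking; if no well-tried combination touches the contour, any
  well-tried combination below it qualifies. Trials stopped for safety
  recommend nothing.

## BLRM internals

* **Standardized doses** are constructed for compatibility with the prior
  toxicity probabilities: d̃ solves expit(μ_intercept + E[slope]·d̃) = p
  with E[slope] the log-normal prior mean of the slope. Explicit values can
  be supplied instead. Inserted levels take the midpoint of their
  neighbors' standardized doses; operational priors are unchanged by an
  insertion.
* **Sampler**: adaptive random-walk Metropolis-within-Gibbs on
  (α₁, log α₂, β₁, log β₂, η), four parallel chains, 1000 burn-in
  iterations each, 2000 pooled retained draws, per-coordinate step sizes
  adapted toward a 0.44 acceptance rate during burn-in. A split-chain R̂
  above 1.1 logs a warning but does not abort.
* **Plug-in vs averaging** (`blrm_plugin`): per the host design, posterior
  *parameter* means are plugged into the model to produce the working
  toxicity estimates; full posterior averaging of the surface is available
  behind the flag. EWOC probabilities always average over draws.
* **Interaction form** (`classical_interaction`): the odds multiplier is
  exp(η·log(1 + e^{d̃_A} e^{d̃_B})) as specified; the classical
  exp(η·d̃_A·d̃_B) is available behind the flag.
* **Patient gain**: the admissible combination with posterior mean toxicity
  closest to θ *from below*; when every admissible combination exceeds θ,
  the one with the smallest posterior mean is used (the escalation rule is
  otherwise undefined in that state). Ties break in index order.

## Alternative insertion rules

Both rules split the probability scale into R1 = [0, 0.16),
R2 = [0.16, 0.33], R3 = (0.33, 1] and monotonize the posterior interval
probabilities by clamping each combination to its lower neighbors (a sweep
in increasing index order; idempotent). Rule 1 triggers when every
combination is confidently outside R2. Read literally, its two printed
conditions must hold *jointly* per combination, which is unsatisfiable for
cutoffs ≥ 0.5 since P(R1) + P(R3) ≤ 1; the implementation reads them
disjunctively per combination (each combination confidently underdosed
*or* overdosed), which matches the single-agent method the rule extends.
The literal conjunction is available via `alt_strict`. Rule 2 triggers on
any single crossed gap, additionally vetoed when any treated combination
has an observed DLT ratio inside [1/6, 1/3]; that veto belongs to rule 2
only.

## The simulation engine

The engine emulates the simulation study's conditions: truth matrices from
the built-in scenarios, Binomial cohort outcomes, starting combination at
the lowest dose pair, and midpoint-interpolated true toxicities for
inserted levels. Patient outcomes are pre-drawn as per-combination uniform
sequences on the maximal expandable (2I−1) × (2J−1) grid, so runs at
different λ share outcome streams (common random numbers): the λ = 1 run
is bitwise identical to running with the insertion rule off, and λ
comparisons are not confounded by outcome noise. Fully independent streams
per λ are available (`share_outcome_streams=False`).

What the generator does **not** emulate: patient heterogeneity beyond the
cell-level DLT probability, accrual timing and late-onset toxicity,
correlation between the two agents' toxicities beyond monotonicity, and
any efficacy endpoint. Passing tests therefore certify the adaptive logic
and its operating characteristics under the stated dose-toxicity
landscapes, not performance on real trial data.

The case-study replay instead consumes fixed per-combination response
sequences built from the published DLT table: observed outcomes first (in
a seed-fixed permutation shared by both host designs), then synthetic
patients with individual risks drawn from Beta(1 + y, 1 + n − y), and
Beta(3, 3) risks at combinations the original trial never used (including
any level inserted mid-replay) — reflecting that those combinations were
avoided as unsafe.

Replication defaults: PIPE studies use 1000 replicates per configuration
(the study's own count; ~5 s per 1000 trials), BLRM studies default to 200
because each cohort requires a full MCMC fit.

## Numerical choices

* Beta CDFs via the regularized incomplete beta function; no Monte Carlo in
  the insertion layer.
* Contour sets are enumerated once per shape (lexicographic canonical
  order, cached), so distribution indices are stable.
* Contour-posterior ties break by canonical order; they are measure-zero
  for real data.
* A posterior in which no monotone contour has positive weight (a cell
  certainly above the MTC dominated by one certainly below) raises
  `DegenerateDistributionError` rather than returning NaNs.
* The Accuracy Index is evaluated on the original grid; trials selecting
  an inserted combination contribute its interpolated true (π − θ)² to the
  numerator with I·J and the denominator fixed at the original shape,
  keeping runs with and without insertions on one scale (an expanded-grid
  normalization would change the index's meaning between arms). When every
  true toxicity equals θ the index is defined as 100. Trials without a
  selection stay in every denominator.

## Known limitations

* Only two-agent grids; at most one insertion timepoint by default
  (configurable); insertions only at midpoints between existing levels,
  never outside the original range; continuous-dose insertion is out of
  scope.
* Scenario fixtures cover the no-acceptable-combination landscapes (A1–A3)
  and the BLRM calibration landscapes (Z1–Z2); other landscapes are
  user-supplied via YAML.
* The host designs are reconstructions from their published descriptions;
  internals the descriptions leave open (contour point estimate,
  dose-skipping formalization, selection fallbacks) are this package's own
  choices, documented above and switchable. Operating characteristics are
  reproduced qualitatively and, for exposure and insertion rates, closely;
  selection-quality metrics in scenarios whose true contour sits deep in
  the grid are sensitive to these internals.
* Prior calibration searches (for the PIPE operational prior and the BLRM
  hyperparameters) are out of scope; their resulting values ship as
  constants.
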