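# doseinsert

Mid-trial dose-level insertion for dual-agent phase I oncology dose-finding
trials, built around the **maximum tolerated contour (MTC)** rule, with two
host escalation designs (the PIPE design and the two-dimensional BLRM with
overdose control), two alternative interval-probability insertion rules, and
a seeded simulation engine for operating characteristics.

## The problem

A combination phase I trial searches a predefined I × J grid of dose pairs
for the combination whose dose-limiting-toxicity (DLT) probability π_ij is
closest to a target θ (typically 0.30). If the protocol grid was chosen
badly, *no* combination may be close to θ: every pre-specified dose pair is
either subtherapeutic or toxic, and the trial ends with a poor
recommendation regardless of how well the escalation design performs.
`doseinsert` implements a formal, data-driven remedy: detect this situation
mid-trial and insert new dose levels at the midpoints between existing ones.

## The method

Each π_ij is modeled independently with a conjugate Beta prior, so after
n_ij patients and y_ij DLTs the posterior is Beta(a_ij + y_ij,
b_ij + n_ij − y_ij), and

  p_ij = P(π_ij ≤ θ | data)

is a Beta CDF. A *contour* C is a binary monotone I × J matrix marking
combinations above (1) / below (0) the MTC; monotonicity of toxicity in
both agents limits the eligible contours to C(I+J, I) matrices (20 on a
3 × 3 grid). Each contour receives posterior probability

  P(MTC = C | data) ∝ ∏_ij (1 − p_ij)^{C_ij} · p_ij^{1 − C_ij}.

If the modal contour's probability exceeds a threshold λ, a single contour
explains the data so well that no combination can be close to θ — an
**insertion is triggered**. Wherever the modal contour crosses between two
adjacent dose levels of an agent, the midpoint dose is inserted (never
outside the original dose range). The grid, the priors (rescaled to a prior
sample size of 1/(I′ × J′)) and, in simulation, the true toxicity landscape
are all expanded; the next cohort must include a new level, after which the
host design resumes. λ = 1 turns the procedure off; insertions are only
allowed in a patient window (default 18–42 of a maximum 48) and at one
timepoint per trial.

The procedure is design-agnostic. Two hosts are provided:

* **PIPE** — model-assisted escalation over the same Beta grid: weighted
  randomization (inverse sample size) among combinations adjacent to the
  estimated contour, an overdose rule on the contour-averaged probability
  q_ij of sitting above the MTC, and selection of the combination closest
  below the final contour with posterior mean toxicity nearest θ.
* **BLRM** — a five-parameter Bayesian logistic model with single-agent
  curves logit(ψ) = α₁ + α₂·d̃ and an interaction odds multiplier
  exp(η·log(1 + e^{d̃_A} e^{d̃_B})), sampled by adaptive
  Metropolis-within-Gibbs, with escalation-with-overdose-control
  (P(π_ij > 0.33) ≤ 0.40) and patient-gain escalation.

Two alternative insertion triggers based on posterior probabilities of an
underdosing region [0, 0.16) and an overdosing region (0.33, 1] are included
for comparison (`insertion_rule="alt1" / "alt2"`).

## Worked example

```python
import doseinsert as di

# posterior probability of being below target after 0/12 DLTs, uniform prior
di.below_target_prob(n=12, y=0, a=1, b=1, theta=0.30)   # 0.9903

# operating characteristics of PIPE + MTC insertions on Scenario A1
df, _ = di.run_study("pipe", "mtc", ["A1"], [0.6, 1.0],
                     n_reps=200, base_seed=7)
```

prints (columns abridged):

```
scenario  lambda  PCS (%)  PAS (%)  PSS (%)  PTS (%)  Insertions (%)  Mean n acceptable
      A1     0.6     26.0     26.0     42.0     28.5            47.0               7.71
      A1     1.0      0.0      0.0     74.5     22.0             0.0               0.00
```

Scenario A1 contains *no* combination with acceptable toxicity
(true DLT range [0.16, 0.33]), so with insertions off (λ = 1) no trial can
select one: PCS = PAS = 0 and zero patients are treated at acceptable
combinations. With the MTC rule at λ = 0.6, 47% of trials insert midpoint
doses (whose interpolated true toxicity 0.275 is on target) and about a
quarter of all trials end by selecting a correct combination, with ~7.7
patients per trial treated at acceptable combinations.

The same engine replays a real neratinib + temsirolimus case study from its
published DLT table:

```bash
doseinsert replay-case-study --design pipe --seed 1
doseinsert simulate --design pipe --rule mtc --scenario A1 \
    --lambda 0.6 --reps 1000 --seed 7 --out results.csv
```

## Layout

| module | contents |
|---|---|
| `doseinsert.contour` | contour enumeration, Eq. for the contour posterior, trigger, overdose measure q |
| `doseinsert.insertion` | insertion plans, grid/prior/truth expansion, patient window |
| `doseinsert.pipe_design` | PIPE admissibility, weighted randomization, selection |
| `doseinsert.blrm_design` | five-parameter BLRM, MCMC sampler, EWOC, patient gain |
| `doseinsert.alt_rules` | interval-probability triggers (alternatives 1 and 2) |
| `doseinsert.metrics` | PCS/PAS/PSS/PTS, Accuracy and Utility indices, exposure |
| `doseinsert.fixtures` | built-in scenarios, operational priors, case-study data |
| `doseinsert.engine` | trial loop, replicated studies, case-study replay |
| `doseinsert.cli` | `doseinsert simulate`, `doseinsert replay-case-study` |

See `docs/methods.md` for modeling assumptions, parameter defaults, and the
design decisions taken where the methodology leaves room.
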