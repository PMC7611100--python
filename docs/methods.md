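# Methods

`selearn` models trial-by-trial learning in a social-evaluation task and
estimates how the parameters of that learning relate to a symptom score (the
Brief Fear of Negative Evaluation scale, BFNE). Because the behavioural dataset
this kind of analysis is usually run on is not publicly deposited, the package
pairs every analysis stage with a synthetic-cohort generator that reproduces
the study design, so the whole pipeline is testable end to end.

## The task

Six evaluative contexts ("personas") cross a referent — whether a computer
persona is judging the participant ("self") or an unknown other — with an
approval rule (like / neutral / dislike). Each persona is played as one
contiguous block of 32 binary choices between a positive and a negative word,
with feedback; the probability that the positive word is correct is 0.8 / 0.5 /
0.2 under the like / neutral / dislike rules. The simulator supports i.i.d.
Bernoulli schedules (default) and exact-ratio schedules (`fixed_ratio`, which
rounds 0.8 × 32 to 26 positives). Block order is a seeded random permutation
per participant; the original counterbalancing is not modelled. Learned state
is reset at each block start; trait-like and initial-bias parameters apply to
every block, since both model families index learning by context.

## Model families

**Associative (Rescorla–Wagner).** Action values Q(a, s) for choosing the
positive/negative word in context s update by λ·(r − Q) on the chosen action
only, with feedback r ∈ {0, 1} coded as correctness (so Q is an expected
correctness, not a signed reward). The learning rate can depend on the referent
and on the *outcome word's* valence (not the chosen word's), giving the 1λ, 2λ
(valence), 3λ (self-positive / self-negative / other) and 4λ variants. Choice
is a softmax over propensities (Q(+,s) + ρ)/τ vs Q(−,s)/τ, where ρ is a
constant positivity bias and τ > 0 decision noise. An initial-bias parameter
q0 sets the starting value of Q(+, s) in every context (shared across contexts;
a per-referent version was considered and rejected as over-parameterised at 32
trials per block). ρ and q0 can each be disabled, reproducing every variant of
the family with or without "additional" parameters.

**Belief-update (beta-Bernoulli).** The belief that a persona approves is a
beta distribution with pseudo-counts α, β split into a fixed trait component
(the activated self- or other-schema) and a decaying state component updated by
outcomes: decay by η then add one count to the matching valence
(decay-then-increment; the alternative order is observationally close but has
fixed point η/(1−η) instead of 1/(1−η) — the chosen order makes 1/(1−η) the
working-memory capacity exactly). Choice uses only the mean belief
p = α/(α+β): propensities p/τ vs (1−p)/τ. The complementary propensity for the
negative word is a design choice — the winning link function specifies only the
positive-word propensity; using the complement mirrors the two-propensity
softmax of the associative family and makes α = β give exactly 0.5.
Variants share or separate trait evidence and η by referent, with optional
initial state evidence (α_init, β_init) shared across contexts. A non-canonical
alternative link (`link="uncertainty_scaled"`, which shrinks both propensities
by N/(N+1) so thin evidence raises decision variability) is available as a hook
for simulation and scalar likelihood work; the fitting kernels implement only
the mean-only link, which is the form retained by model comparison.

Degenerate beliefs (zero total evidence) are defined as p = 0.5 with a warning
during simulation, and are an error during fitting — the fitting transforms
(below) exclude that region anyway. η = 1 is admitted internally because it
makes the state evidence exactly the conjugate Beta–Bernoulli pseudo-counts,
which is the oracle used in tests; fitting constrains η to (0, 1).

A local correspondence connects the families: with η = 1, one positive outcome
moves the mean belief by (1 − p)/(N + 1) where N = α + β — a delta rule toward
1 with effective learning rate 1/(N + 1). Large positive self-evidence hence
mimics a small self-negative learning rate; `effective_learning_rate` exposes
this and the tests verify the monotonicity numerically.

## Likelihood kernels

One implementation of each family's likelihood serves simulation cross-checks,
maximum likelihood and MCMC: a vectorised kernel that evaluates the per-trial
log-likelihood matrix for a stack of sessions, iterating over the 32 trial
positions with all subject-blocks as the batch dimension (blocks are
conditionally independent given the parameters, so each block is a row). The
kernel also returns the analytic gradient of each subject's total
log-likelihood, obtained by propagating state sensitivities through the same
recursion; agreement with the scalar trial-by-trial operations (to 1e-12) and
with finite differences (to ~1e-5) is enforced by tests. An optional trial mask
restricts the likelihood (and its gradient) to a subset of trials while the
masked trials still drive the learning dynamics — this is what exact
leave-one-trial-out refits use.

Parameters are fitted on an unconstrained scale through range-safe bijections:
inverse-logit for learning rates and memory decay, exp for decision noise,
trait and initial evidence, identity for ρ and q0. Slopes and SDs of the
population layer are therefore in unconstrained units.

## Maximum likelihood

Per-subject ML estimation runs L-BFGS-B on the unconstrained scale with
analytic gradients, jointly over all subjects (the objective is separable, so
the joint optimum is the per-subject optimum and the batch makes the kernel
efficient), best-of-N seeded Latin-hypercube restarts (default 10), bounds of
±7 on logit-scale, [e⁻⁶, e⁴] on log-scale and ±5 on identity-scale parameters
to keep degenerate sessions (e.g. all-positive choosers) finite. Deterministic
given the seed.

## Symptom-linked hierarchical model

For each cognitive parameter θ (unconstrained scale):

    θ_i ~ Normal(w · z(BFNE_i) + θ0, σ)

with priors w ~ Normal(0, 1), θ0 ~ Normal(0, 2), σ ~ half-Cauchy(2.5). BFNE is
z-scored within the cohort, so w is per SD of BFNE; this choice (the covariate
could equally enter raw) changes only the numeric scale of w and is flagged
because it matters when comparing slope magnitudes across analyses. σ is
independent of BFNE. Each parameter of the chosen variant gets its own slope;
any slope can be frozen at zero.

Sampling is a Metropolis-within-Gibbs scheme written for this structure:

- **Subject step:** all subjects' parameter vectors move together by a
  Hamiltonian (leapfrog) step using the kernel's analytic gradients, with the
  current population SDs as a diagonal preconditioner; acceptance is per
  subject; the step multiplier adapts during warmup toward 75% acceptance.
- **(w, θ0):** exact conjugate bivariate-normal Gibbs draw given θ and σ. The
  centered parameterization is used deliberately — it is what makes this
  conditional conjugate.
- **σ:** random-walk Metropolis on log σ against the residuals (likelihood-free,
  so it is iterated ten times per sweep).
- **Interweaved non-centered moves:** per parameter, (a) a scale move that
  rescales that column's subject residuals jointly with σ, and (b) a location
  move that shifts the column jointly with (w, θ0). Each costs one likelihood
  evaluation and is accepted jointly. These cut across the funnel-shaped
  coupling between population scale/location and subject parameters that the
  centered Gibbs steps alone traverse slowly.

Defaults are 4 chains, 1000 warmup and 1000 kept draws (≈ 4000–8000 posterior
samples); the tests and the acceptance script run 1–2 chains with 150–500
warmup/draws, which is sufficient for the sign, coverage and ranking checks
they make. Convergence is monitored by the Gelman–Rubin statistic (threshold
1.05) and effective sample size via arviz; non-convergence is recorded as a
warning on the returned fit, not an exception. Per-trial pointwise
log-likelihoods of every kept draw are stored for model comparison.

On simulated cohorts the sampler recovers the generating slopes: e.g. with 120
subjects and the demo belief population, the posterior mean of w(α_self) lands
within ~0.05 of the generating −0.47, and null-slope cohorts give ~95% CI
coverage of zero (tested at reduced scale).

## Model comparison and evaluation

- **PSIS-LOO** via arviz on the stored pointwise log-likelihoods, per trial by
  default (per subject via `unit="subject"`): trial-level units give far more
  stable Pareto-k diagnostics at these data sizes. Pairwise differences use
  paired pointwise contributions; a fraction of Pareto k > 0.7 above 10%
  triggers a warning. Agreement with exact leave-one-trial-out cross-validation
  (refit per fold with the trial masked) is tested on a small instance.
- **Individual evidence classes** from ML log-likelihood differences with the
  conventional ±3 (mild) and ±6 (strong) boundaries.
- **Spearman correlations** between fitted parameters across families
  (scipy), checked against a rank-then-Pearson oracle.
- **Generative performance:** simulate datasets from a population (default 10
  datasets of 200 subjects; the ideal-experiment scale of 100 × 1000 is a
  parameter), compute percent-positive per subject × persona, fit a linear
  mixed model `pct ~ BFNE × referent × persona` with a random intercept per
  participant (statsmodels MixedLM, BFGS with a Powell fallback), and record
  each contrast's coefficient and significance (p < 0.05, no multiplicity
  correction) per dataset. BFNE enters on its raw scale. Reference levels are
  the **self** referent and the **dislike** persona: with the self reference,
  the BFNE main effect is the BFNE slope in self blocks and the self/other
  contrast is the shift for the other referent — the coding under which the
  expected sign pattern (negative BFNE main effect, negative self/other shift,
  positive BFNE × self/other, negative three-way) is internally consistent with
  the mechanism of a self-specific BFNE effect. Random slopes were considered
  and left out: six observations per subject cannot support them.

## Synthetic cohorts

BFNE scores default to the instrument's range 12–60 (an assumption — the
12-item, 5-point scale; configurable) with the study's stratified design: a
third of subjects from the bottom quartile of the range, a third from the top,
a third mid-range. Per-subject parameters come from the population layer above;
the demo populations use the reported per-parameter slopes of the selected
models (e.g. +0.11 on the self-negative learning rate, −0.47 on the positive
self-evidence, per SD of BFNE) as plausible effect sizes, with intercepts and
SDs describing a population with moderately positive self- and other-schemas
(trait evidence ≈ 4–5 counts), learning rates ≈ 0.3, memory ≈ 0.85 and decisive
choices (τ ≈ 0.12–0.25). These are recovery-study conditions, not reproduction
targets: the original study's real-data coefficient magnitudes are out of
scope.

What the generator does *not* emulate: word-level stimuli and reaction times,
the original counterbalancing, BFNE measurement error, item-level responses,
dropout, and any misspecification between the fitted and generating model
(cohorts are generated from the same families that are fitted, except where a
test deliberately crosses families). Passing tests therefore demonstrate
internal consistency and statistical power of the pipeline under the assumed
design — not that the models are true of real participants.

## Numerical choices and limitations

- Softmaxes are computed with max-subtraction / log1p forms; likelihoods floor
  probabilities at 1e-300 before logs.
- exp-transforms clip their argument at ±50 to avoid overflow during MCMC
  excursions.
- MLE ties across restarts resolve to the first-found optimum; fits report a
  per-subject convergence flag.
- The initial-bias parameters of both families are weakly identified at 32
  trials per block (the belief family's α_init/β_init especially); their
  posterior summaries at small n are wide, and mixing for their population SDs
  is the slowest in the sampler. This mirrors the recoverability limits the
  analysis is known to have.
- Exact-ratio schedules make outcomes dependent within a block; all likelihood
  code conditions on outcomes, so this affects only the generator.
- `sessions_to_arrays` (and hence the fitting stack) requires equally shaped
  sessions; ragged designs would need the scalar likelihood path.
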