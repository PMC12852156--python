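# Methods

## The game battery and the strategy space

Six one-shot games share a common skeleton: a target (P2) either steals 20
pence from a victim or does nothing; the focal player (P1) may then pay a
fee of 10 to impose a fine of 30 on P2 (both destroyed). The variants are:
initial advantageous inequity for P1 (A); equal-after-theft endowments (B);
the same game with the steal decision made by the computer, removing intent
(C); a 1:1 fee-fine ratio (D); initial disadvantageous inequity relative to
the target's post-steal payoff (E); and a third-party game in which P2
steals from a bystander P3 while P1 observes with a larger endowment (F).
All payoffs are integer pence and are deliberately not floored at zero: a
fined non-stealing target in game A ends at −20, and that value is needed
for the relative-payoff predicates to come out right. Real bonus payments
would be floored; that is outside this package's scope.

Nine motives are formalized as predicates over (game, stole) using
stage-two payoffs (after the steal choice) and stage-three payoffs (with
punishment enacted):

| motive | punishes iff |
| --- | --- |
| deterrent | stole ∧ intentional ∧ victim is self |
| norm-enforcing | stole ∧ intentional |
| revenge | stole ∧ victim is self |
| avoid DI | self < target before punishing ∧ self ≥ target after |
| egalitarian | punishment strictly reduces total inequality |
| seek AI | self ≤ target before ∧ self > target after |
| competitive | punishment strictly increases self − target |
| antisocial | ¬stole |
| never punish | never |

Evaluating all nine on the twelve decision contexts yields the 9 × 12
prediction matrix; the test suite pins it bit-for-bit to its published
tick/cross form. Three choices here were genuinely open and are resolved as
follows. *Inequality metric*: the sum of pairwise absolute payoff
differences over all players — the simplest integer-valued metric
consistent with every egalitarian prescription (variance would give the
same pattern). *Boundary conventions*: avoid-DI counts post-punishment
equality as "disadvantage avoided" (forced by game E's 40 vs 40), and
seek-AI counts pre-punishment equality as "no advantage yet" (forced by
games B/C's 50 vs 50). *Competitive reference*: relative position is
measured against the punished target P2, including in the third-party game.
An extra deterministic row punishing only third-party theft (game F, steal)
can be appended for the extended, ten-deterministic-strategy model; it is
an empirically common pattern, not derivable from the nine motives.

## Latent-state mixture model

Participants carry a latent strategy s from the deterministic set plus a
random-choice class. With implementation error rate δ ∈ [0, ½), a
deterministic strategy's prescribed decision is observed flipped with
probability δ, so Pr(punish | s, j) is 1−δ at ticks and δ at crosses;
random choice has probability ½ everywhere. At δ = ½ every deterministic
row would equal the random row, so the upper bound is a hard validity
constraint. Membership is a softmax over per-strategy linear predictors,
with a separate intercept vector per country, α_sc ~ Normal(0, 1), over all
S strategies with no reference category; the additive non-identifiability
of the softmax is absorbed by the prior and only the probabilities p — never
α — are reported. A continuous covariate is z-standardized and enters with
per-country, per-strategy slopes β_sc ~ Normal(0, 0.2) (a deliberately
strong regularizer — on the standardized scale a slope of 0.2 is already a
meaningful shift in log-odds); a categorical covariate gets its own
intercept vector per (country, level) cell. One covariate per model;
separate models per predictor are the intended workflow.

### Likelihood factorization — an identifiability caveat

Two factorizations of the mixture likelihood are implemented.

*Participant-level* (default): the latent strategy is marginalized once per
participant, L_i = Σ_s p_si Π_j Bernoulli(y_ij | Pr(punish|s,j)). This is
the canonical treatment of a latent discrete state and respects the fact
that one person's twelve decisions share one strategy.

*Decision-level*: the mixture is applied independently at every decision,
y_ij ~ Bernoulli(Σ_s p_s Pr(punish|s,j)) — the way the model is usually
written down. Under this factorization the data inform p only through the
twelve marginal punish rates per country, and the 10 × 12 contaminated
kernel has **affine rank 7**: a 2-dimensional family of distinct strategy
mixes produces identical likelihoods. The practical symptom is
prior-dependent, inconsistent estimates — in our experiments, errors near
0.07 at n = 2000/country with perfectly converged chains, and an upwardly
biased free-δ. The decision-level mode is therefore retained for likelihood
computation and comparison (the two modes agree exactly on point-mass
mixtures, which the tests exploit), but estimation defaults to the
participant-level mode, and the validation harness's `mode_comparison`
makes the contrast measurable.

Missing decisions (e.g. per-game comprehension exclusions) contribute
nothing to either likelihood; participants are never dropped wholesale.

### Computation

Posteriors are sampled with an affine-invariant ensemble sampler (emcee)
using differential-evolution moves, vectorized over walkers. For the
participant-level likelihood without covariates, participants are collapsed
into weighted pattern classes (the per-strategy likelihood depends only on
the count of decisions agreeing with each prescription), which makes the
cost of a likelihood evaluation independent of n for all practical
purposes. Walkers are initialized in a small ball around the posterior mode
(L-BFGS-B) and grouped into four pseudo-chains for diagnostics. A fit runs
the configured warmup, then extends sampling in blocks until max R-hat
≤ 1.01 and min bulk ESS ≥ 400, up to a fixed cap of extensions; failure to
meet the gates raises a `ConvergenceWarning` and marks the fit
unconverged rather than failing silently. Stored draws are thinned to bound
memory; diagnostics are computed before thinning. The free-δ variant gives
δ a Uniform(0, ½) prior — a flagged package choice, with the bound required
for identifiability. The default configuration (2000 samples, 1000 warmup,
4 chains) mirrors standard practice for this model class; the ensemble
extends itself as needed, so these numbers are a floor, not a promise of
convergence.

## Synthetic cohorts

The generator draws each participant's strategy from a per-country
frequency simplex (or from participant-specific softmax probabilities when
a covariate is specified, x ~ Normal by default), then emits decisions by
the same contamination process the model assumes. Defaults mirror the study
conditions: two countries of ~1000 participants for cohort-scale runs, an
n = 100 single-country template at δ = 0.05 for the validation design, and
δ = 0.05 throughout. The true validation mix is not published; the
package's documented default mix (never-punish 0.45, egalitarian 0.12,
avoid-DI 0.08, random choice 0.15, the rest small but non-zero) is a
realistic stand-in chosen once. Ground-truth labels live in a sidecar
table, never in the decision CSV, so fitting code cannot leak truth.

What the generator does **not** emulate: comprehension failures and
attention-based exclusions, dropout, within-participant learning or order
effects, and any deviation from the ten-strategy space (e.g. probabilistic
blends of motives). Passing recovery tests therefore demonstrate that the
inference machinery is correct under the model's own assumptions — not that
real cohorts contain only these strategies.

## Validation experiments

`recovery_experiment` generates R seeded replicates, fits each, and records
truth vs posterior median and 95% interval per strategy and country.
At the n = 100 validation design with 20 replicates, per-strategy 95%
interval coverage is ≥ 0.90 (long-run coverage is close to nominal:
0.92–1.00 per strategy over 60 replicates); at n = 2000/country a single
fit's medians land within 0.03 of the truth and a free-δ fit on δ = 0.05
data recovers δ ≈ 0.05. These are the quantities `scripts/acceptance.py`
recomputes. Experiment problem sizes (20 replicates, 2000/country) are
chosen to make the checks sharp yet desk-runnable.

## Known limitations

- Exact classification is all-or-nothing; at δ = 0.05 only ≈ 0.95¹² ≈ 54%
  of deterministic-strategy participants match their own row exactly, so
  raw counts understate strategy prevalence — precisely the gap the latent
  model closes.
- The decision-level factorization is unidentified (see above); its
  presence is diagnostic, not an estimation option.
- The ensemble sampler's gates are necessary, not sufficient: as with any
  MCMC diagnostic, pathological multimodality could in principle pass
  unnoticed, though the collapsed likelihood here is smooth and unimodal in
  all experiments run.
- Partial-vector classification ("match on observed subset") returns NA on
  ambiguity; with many missing decisions this is conservative.
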