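# Methods

## Task model

A session is 180 trials in three 60-trial blocks, built from twelve
15-trial sets. Each set's computer numbers are a fixed multiset: the
active triple of consecutive numbers three times each plus every other
number once. Between sets the triple shifts +1 if the subject took at
least two thirds of the gambles offered against the triple's numbers in
the preceding set, −1 if at most one third, clamped to 1..9. Only trials
whose number belonged to the triple count toward the thresholds; with no
such trials the triple is left unchanged. Within a set each deck is
scheduled five times under two constraints chosen here (the original
design is described only as pseudorandom): no deck appears more than
twice consecutively, and the set's sorted numbers are dealt to the decks
round-robin from a random starting deck, so all decks face near-identical
number multisets. Outcomes are symmetric ±1; monetary framing is
presentation only.

Deck composition is not published beyond the ±30-percentage-point success
offsets, so the low/high decks are mixtures `(1−q)·uniform + q·point-mass`
on 1 or 9. Against a uniform computer number with fair-coin ties the
success probability is linear in `q`, giving an exact solution
(`q = 0.675` for the 30-point offset); offsets beyond the family's reach
(≥ 4/9) are rejected. "30% more/less likely" is read as percentage
points (0.5 → 0.8/0.2), matching a symmetric design; equal-number ties
are resolved by a fair coin on every tied trial rather than
deterministically in half of them. Two sessions are independent runs
(fresh decks, fresh schedule, Q reset): deck identities on the second
day are unrelated to the first.

The simulator never produces missed responses; the CSV reader accepts
them (`choice = NA`, outcome −1) and all analyses skip them.

## Model space

Eight nested models map trial state to gamble evidence (see README for
equations). Conventions that the equations do not pin down:

- The computer number enters both the evidence and the adjusted
  prediction error in its scaled form, N ∈ [−1, 1].
- Learning rates attach to the *outcome's* valence: in the sensitivity
  models the prediction error uses ρ±·r, but η⁺/η⁻ is still selected by
  the sign of the raw r. The sensitivity models are supplementary
  variants described only verbally in the source literature; placing ρ
  inside δ (the learning target becomes ±ρ) is this package's choice,
  isolated behind the `asymmetric_sensitivity` flag.
- Q carries across blocks within a session, resets between sessions, and
  never changes on declined or missed trials.
- Fixed-point bounds follow from r ∈ {−1, +1}, N ∈ [−1, 1], η ∈ [0, 1]:
  |Q| ≤ 1 for the plain models, |Q| ≤ 2 for the adjusted ones; the
  likelihood needs no probability clamping because evidence is finite and
  log-probabilities are computed with `logaddexp`.

## Hierarchical fitting

Priors: Beta(a, b) for learning rates (initialized a = b = 1), Normal(μ,
σ) for the gambling bias (0, 1), Gamma(κ, θ) for the nonnegative weights
(1, 1). Each EM iteration draws a fresh batch of S settings from the
current priors (default S = 10⁵; validation studies here use 10³–10⁴),
evaluates every subject's log-likelihood under every setting (vectorized
over settings), converts them to per-subject normalized importance
weights in log space, and refits each prior to the pooled weighted sample
— every subject contributing total mass one — by weighted method of
moments. Degenerate refits fall back to a widened version of the previous
prior (warned); the Normal σ is floored at 0.01.

The evidence monitored for stopping is the sum over subjects of the log
mean likelihood over the current batch; iteration stops when it improves
by less than 0.1 (cap 50 iterations, warned if reached). Per-subject
estimates are likelihood-weighted means of the final batch, which
shrinks weakly informed subjects toward the group mean. The exact
stopping rule and refit estimator are unstated in the source literature;
resampling EM with moment matching was chosen for robustness and
testability (the weighted moments of the refit distribution equal the
weighted sample moments by construction). Fitting always pools all
subjects regardless of group labels, and sessions are fitted separately.

## Model comparison

λ is estimated per subject as the mean likelihood over S settings drawn
from the *fitted* priors (max-shifted log-sum-exp), summed in log across
subjects; iBIC = −2 ln λ + κ ln n with n the number of non-missed
choices. Because fitting is hierarchical, κ defaults to the group-level
count — two hyperparameters per prior distribution — with a per-subject
alternative (`kappa_rule="subject"`) reported alongside every score.
Model recovery simulates cohorts from each candidate's generating priors
and scores the whole candidate set; generating priors for the asymmetric
models are deliberately asymmetric (η⁺ ~ Beta(6, 2), η⁻ ~ Beta(2, 6)) so
that nested symmetric models are genuinely distinguishable at small n.

## Trial-by-trial regression

x₂ and x₃ accumulate strictly previous outcomes of the current deck
(decisions precede their own outcome), weighted by the computer number:
+N per win, −(10 − N) per loss. Both are range-normalized onto [−1, 1]
per subject-session (constant regressors map to 0); an absolute-maximum
variant and raw sums are available. Fits are plain maximum-likelihood
logistic regressions; subjects with fewer than five accepted or declined
trials, non-convergence, or coefficients beyond ±30 (quasi-separation)
are flagged and excluded from group summaries. The asymmetry index is
β₂ − β₃ on the common normalized scale: both coefficients are positive
when outcomes have their intuitive effects, so equal sensitivity gives
zero. The precise composite is not printed in the source literature;
this definition is the package's, and it is deliberately simple.

## Synthetic cohorts and calibration

The default generating population uses mid-range learning rates
(Beta(4, 4)), a centred gambling bias (Normal(0, 0.5)) and temperature
weights Gamma(4, 1). The temperature scale was calibrated so that
simulated cohorts match the choice determinism reported for real cohorts
on this task (≈ 88% of choices assigned probability > 0.5 by the fitted
model): Gamma(4, 1) weights put simulated agents at ≈ 86–87%
percent-correct, whereas weights with mean 2 give only ≈ 77% and produce
markedly less identifiable parameters. The same calibrated weights are
used in the validation studies (parameter recovery, model recovery,
asymmetry-correlation), whose learning rates are instead drawn uniform
on [0, 1] to cover the whole admissible range. Simulated cohorts
reproduce the task's qualitative signatures: deck-wise gamble rates
separate (high > even > low), and group-level regression t-statistics at
n = 66 (number ≈ 13, success ≈ 8, failure ≈ 9) are close to those
reported for real cohorts.

The drug/placebo emulation shifts the drug group's Beta means for η⁺
(down) and η⁻ (up) by Δ/2 each at fixed concentration a + b. The
valence-by-group interaction, (drug: η⁺−η⁻) − (placebo: η⁺−η⁻), is
tested by permuting group labels (default 2000 permutations, two-sided,
add-one correction) rather than a repeated-measures ANOVA: the
hierarchical fit is label-blind, so permutation gives an assumption-light
exact test at these sample sizes.

## Simulation-study sizes

Validation runs are sized for a single CPU: parameter recovery uses 66
agents and S = 10⁴ (learning-rate recovery r ≈ 0.9); model recovery uses
10 subjects per cohort, two replicates per generating model and reduced
sample counts (the confusion matrix is nonetheless diagonal); the
net-reward grid simulates 200–500 sessions per learning rate on a 0.05
grid (a 1000-session reference run peaks at η = 0.30 with a plateau to
≈ 0.45); the asymmetry-correlation study uses five datasets of 66
agents. The five datasets are generated from the learning models, with
single-rate models promoted to their asymmetric counterparts (3 → 5,
4 → 6) so that η⁺ and η⁻ can vary independently per agent, plus the
richest sensitivity variant.

## Known limitations

- The regression asymmetry β₂ − β₃ tracks the generating learning
  asymmetry strongly but imperfectly (r ≈ 0.5–0.7 across regimes here):
  β₂ is non-monotone in η⁺ — beyond η ≈ 0.5 deck values saturate on
  recent outcomes, which a cumulative regressor cannot represent — and
  per-session range-normalization factors add agent-specific scale
  noise. A control in which choices are generated directly from the
  cumulative-evidence process recovers r ≈ 0.81–0.96, so the bound is a
  property of the measure, not the estimation pipeline.
- Under the adjusted models, selective sampling (gambling mostly against
  favourable numbers) makes wins unsurprising and losses surprising,
  dragging mean deck values negative; zero-bias populations therefore
  gamble a few points below 50% even under the adaptive schedule, whose
  1/3–2/3 dead band cannot correct deviations inside the band.
- Synthetic agents are stationary: no attention lapses, fatigue,
  perseveration or session-order effects. Passing recovery tests shows
  the pipeline is consistent for data generated by these models, not
  that real behaviour follows them.
- Per-subject uncertainty is not retained (only weighted means, as in
  the fitting procedure emulated); group inferences rest on
  between-subject variability.
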