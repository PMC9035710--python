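# Methods

`revlearn` reimplements, as a tested pipeline on synthetic cohorts, the
computational core of a study linking resting dorsal-striatal choline
(measured by 1H-MRS) to serial reversal-learning performance: the task's
generative engine, two Rescorla–Wagner models, hierarchical Bayesian model
fitting and comparison, behavioural error metrics, and the
correlation/hierarchical-regression analysis. No human data are consumed;
the synthetic-cohort generator states the world the analysis assumes.

## Task engine

Two images; the correct one wins +50 points with probability 0.8 and loses
−50 otherwise, the incorrect one has the inverse contingency. 360 trials
per session. Outcomes are pseudo-randomised: for each *role*
(correct/incorrect choice), every block of 20 consecutive selections
contains exactly 16/4 (or 4/16) wins, and no more than 6 identical outcomes
occur consecutively within a role's stream. Criterion is choosing the
correct image on 5 of the last 6 trials; while criterion is held for k
consecutive trials the contingencies reverse with probability k/10 (clamped
at 1), sampled per trial after feedback and taking effect from the next
trial. A miss (no response) earns nothing, counts as not-correct in the
criterion window, and consumes no queued outcome.

Choices the published description leaves open, decided here once:

- outcome queues attach to roles, not images, and persist across
  reversals, so block balance stays well defined over the whole session;
  the run-length constraint is enforced across block boundaries;
- the criterion is evaluable as soon as 5 trials have elapsed (5 correct
  choices from trial 1 satisfy it) — the minimal consistent extension of
  the 5-of-6 rule to the start of the task;
- after a reversal the criterion window is cleared, so criterion within the
  new event reflects the new contingencies only;
- one global generator per session drives all randomness in a documented
  order (initial image assignment; block refills when a queue is consumed;
  one uniform variate per criterion-held trial for the reversal draw).

## Reinforcement-learning models

Softmax choice p(k) ∝ exp(βV_k) with inverse temperature β ≥ 0; value
update V_k ← V_k + α·δ with prediction error δ = λ − V_k. The single-rate
model has one α; the dual-rate model applies α+ when δ > 0 and α−
otherwise (δ = 0 routed to α−, the literal "otherwise"). Outcomes are
coded λ = +1 (win) / −1 (loss): the ±50 point magnitude is absorbed into
β, which keeps β on the scale of the published estimates — at the
published group means this coding reproduces the published mean of ~257
correct choices per session. Initial values are 0 for both options. Missed
trials contribute no likelihood term and trigger no update. For fitting,
parameters are mapped to an unconstrained space (logit for α's, log for
β), where the Gaussian priors live. The per-trial likelihood loop is
compiled with numba; a pure-python reference implementation is kept and
tested against it.

## Hierarchical Bayesian fitting and model comparison

Subject-level fits are Laplace approximations: MAP under a Gaussian prior
(mean 0, variance 6.25 per unconstrained parameter), L-BFGS from 10 random
prior draws, Hessian by central finite differences (step 1e-4), and

    log p(D) ≈ log p(D|θ*) + log p(θ*) + (d/2) log 2π − ½ log det H.

Group-level inference iterates four steps to convergence (max |change| in
group means and responsibilities < 1e-4, at most 50 iterations):
(1) responsibility-weighted means and second moments of the subject
estimates — the second moments include each subject's Laplace posterior
variance, without which the group variance contracts indefinitely instead
of reaching a fixed point; (2) group Gaussian update, the mean regularised
toward 0 by the subject-level hyperprior; (3) deterministic warm-started
subject re-fits under the current group Gaussian as prior; (4)
responsibilities ∝ exp(log evidence + ψ(α_m) − ψ(Σα)) from a Dirichlet
(α0 = 1) posterior over model frequencies. Re-fits use the full
likelihood, not a responsibility-weighted one, so per-model evidences stay
comparable in step 4. When models compete closely the iteration converges
slowly and can hit the iteration cap; the result is returned with a
convergence flag and trace. Exact agreement with any particular toolbox is
not claimed; recovery behaviour is what the tests pin down.

Exceedance probabilities are Monte-Carlo estimates over the Dirichlet
posterior (1e5 draws, seeded; ties split equally), cross-checked against
the closed-form Beta-CDF for two models. The probability that evidence
differences arose by chance is computed by comparing the variational free
energy of the fitted mixture against the equal-frequency null, and the
protected exceedance probability is PXP = EP·(1 − p0) + p0/M.

## Behavioural metrics

Sessions are segmented into learning events at reversals. Perseverative
errors: post-reversal choices of the previously correct image before the
first choice of the newly correct image ("switching" = that first choice —
the simplest operational reading). Regressive errors: relapses to the
previously correct image after the switch, before the next reversal.
Misses are excluded from both counts and do not end the perseverative run.
The first event has no previous strategy; its counts are reported as
absent, not zero. Trials-to-criterion counts trials from event start to
the criterion trial inclusive.

## Synthetic cohort

Subjects draw dual-rate parameters from group Gaussians in unconstrained
space; defaults back-transform to the published group means (α+ 0.4605,
α− 0.9786, β 1.8533) with SD 0.5. Each subject plays a full 360-trial
session. Choline is generated *from* behaviour — the direction of the
regression being tested — as base (0.797 mM) + 0.22 mM × Σ w_j z_j +
N(0, 0.04 mM), with predictors z-scored within cohort and default
standardised weights taken from the published stage-3 pattern (reversals
−0.400, α+ −0.303, α− +0.328, β 0, perseverative −0.619, regressive
−0.574). The residual SD of 0.04 mM was chosen so the planted stage-3
model explains ≈98% of choline variance, matching the published fit, and
was fixed before any calibration test was run. GPC+PC (mean 0.854, SD
0.241 mM) mixes cohort-standardised choline with independent noise so the
population correlation equals −0.912 exactly. NAA is independent of
everything (mean 8.7, SD 1.0 mM — typical striatal values; the source
study prints none). Positivity is enforced by resampling the noise (exact
truncated-normal in the deep tail), never by clipping.

What the generator does **not** emulate: MR acquisition and quantitation
noise, tissue-fraction corrections, response times, practice trials, or
any nonlinear behaviour–metabolite coupling. A green calibration test
therefore establishes that the analysis recovers what was planted in this
linear-Gaussian world, not that the biological claims are correct.

## Statistical pipeline

Pearson r with t = r√(n−2)/√(1−r²) on n−2 df and Fisher-z 95% CIs
(cross-checked against scipy). Hierarchical regression: nested stages
(GPC+PC; + reversals; + α+, α−, β, perseverative, regressive), each fitted
by OLS with intercept; standardised βs by refitting on z-scored
variables; F-change = (ΔR²/Δk)/((1−R²_full)/(n−k_full−1)), verified
against the statsmodels nested-model F test. Diagnostics: VIF by
auxiliary regressions (threshold 10), Durbin–Watson, Cook's distance
(cross-checked against a leave-one-out refit oracle; a numerically exact
fit returns all-zero distances). Exact collinearity raises an error rather
than silently dropping a column, so staged tables never desynchronise.
Two-sided tests throughout; star thresholds .05/.01/.001; no
multiple-testing correction by default (a Holm-adjusted view can be
derived from the emitted p-values).

Calibration design: under the zero-weight null the F-change p-value is
uniform conditional on any fixed design, so the type-I suite redraws only
the neurochemistry (1000 times) over one simulated n=100 behavioural
design; sign recovery uses 20 fresh behavioural cohorts × 5 neurochemistry
redraws (noise enters only in the neurochemistry stage).

## Known limitations

- Per-subject α− is weakly identified in the stated world: with the group
  mean at 0.9786, subjects' α− ∈ ~[0.93, 0.99] all behave almost
  identically (a loss essentially overwrites the value estimate), so no
  fitting method can rank subjects reliably from 360 trials. Group-level
  α− recovery is accurate; per-subject rank correlation is not, and the
  corresponding recovery test documents this honestly. An oracle
  experiment (fitting with the true generating prior) bounds the
  achievable rank correlation at ≈0.25 for α− and ≈0.55 for α+ at 360
  trials; both rise above 0.9 at 2000 trials.
- The group-level iteration can be slow to converge when candidate models
  fit near-identically; results carry an explicit convergence flag.
- The cohort generator constrains only means, SDs, one correlation and the
  planted signs; joint higher-order structure of real behaviour and
  neurochemistry is out of scope.
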