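# revlearn

Simulation and analysis tools for **serial probabilistic reversal
learning** and its relationship to resting striatal neurochemistry.
The package is aimed at computational-cognitive-neuroscience researchers
who want a fully synthetic, end-to-end testbed for this class of study:
a generative task engine, Rescorla–Wagner agents, hierarchical Bayesian
model fitting and comparison, behavioural error metrics, a cohort
generator with planted metabolite effects, and the staged-regression
analysis — with every stage unit-tested against independent oracles.

## The task and models

Two images; the correct one wins +50 points with probability 0.8 (the
incorrect one loses with the same probability), balanced exactly over
20-selection blocks with no more than 6 identical consecutive outcomes
per role. After choosing the correct image on 5 of the last 6 trials,
contingencies reverse with probability k/10 per trial of maintained
criterion. Sessions are 360 trials.

Choice behaviour is modelled with a softmax policy and Rescorla–Wagner
value updates,

    p_t(k) = exp(β V_t(k)) / Σ_i exp(β V_t(i))
    V_{t+1}(k) = V_t(k) + α δ_t,      δ_t = λ_t − V_t(k)

either with a single learning rate α, or with separate rates α⁺ (δ > 0)
and α⁻ (δ ≤ 0). Subjects are fitted by Laplace-approximate MAP under
N(0, 6.25) priors on unconstrained parameters, aggregated by an
empirical-Bayes mean-field scheme with per-subject model
responsibilities, and compared by protected exceedance probability.
Behavioural flexibility is summarised as perseverative and regressive
errors per learning event, and a three-stage hierarchical regression
(with VIF, Durbin–Watson and Cook's-distance diagnostics) relates
behaviour to synthetic choline concentrations, with NAA as a specificity
control. See `docs/methods.md` for the full model account.

## Worked example

```python
import revlearn as rl

cfg = rl.CohortConfig(seed=42)            # 13 subjects, 360 trials each
records, table = rl.generate_cohort(cfg)  # sessions + cohort table

res = rl.HBIModel([r.session for r in records]).fit(seed=43)
print(res.summary())
```

```
   model    freq      EP     PXP  N(argmax)
  single   0.274   0.032   0.231          3
    dual   0.726   0.968   0.769         10
null probability (chance): 0.424

[dual] group means (back-transformed): [0.46729798 0.94713358 1.98738826]
```

The dual-rate model wins the comparison (PXP 0.77, highest
responsibility for 10 of 13 subjects), and the recovered group means
(α⁺ ≈ 0.467, α⁻ ≈ 0.947, β ≈ 1.99) sit close to the generating values
(0.4605, 0.9786, 1.8533). The regression stage:

```python
print(rl.run_paper_analysis(table, response="choline_mM").summary())
```

```
Hierarchical regression predicting choline_mM (N = 13)
...
Stage 3                                          0.983  0.967/ 0.921   0.149
  gpcpc_mM            0.185    0.300     0.830
  reversals          -0.030   -0.489    -1.524
  alpha_pos          -0.578   -0.413    -2.371
  alpha_neg          11.694    0.709     2.532
  beta                0.025    0.168     0.965
  perseverative      -0.332   -0.862    -3.056 *
  regressive         -0.111   -0.532    -1.567
------------------------------------------------------------------------
Durbin-Watson = 2.083; max VIF = 19.95; Cook's D > 1 for 2 observation(s)
```

Stage 3 explains 96.7% of choline variance, and the coefficient signs
reproduce the planted pattern (negative for α⁺, perseverative and
regressive errors; positive for α⁻) — at n = 13 individual coefficients
are noisy, which is exactly the small-sample behaviour the pipeline's
calibration suite quantifies at larger n.

A command-line interface wraps the same stages:

```sh
revlearn pipeline --seed 7 --out out/      # cohort -> fits -> analysis
revlearn cohort --out out/cohort
revlearn fit --sessions out/cohort/sessions --models single,dual --out out/fit
revlearn regress --cohort out/cohort/cohort.csv --response choline --out out/reg
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the complete default pipeline (13-subject synthetic cohort,
session simulation, hierarchical model fitting and comparison,
behavioural metrics, and both the choline and NAA regressions) from
scratch under the given seed and writes the results JSON to the given
path.
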