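# Methods

## Model

Within a session, trial outcomes X₁…Xₙ take values in the five-state space
{R, NR, premature, incorrect, omission} (canonical order; S = 5).  Two
nested models are fitted from the observed transition-frequency table
O[i,j] = #{t : Xₜ₋₁ = i, Xₜ = j}:

* first-order chain: P̂[i,j] = O[i,j] / O[i,·], assuming homogeneity
  (time-constant transition probabilities) within the fitted span;
* zeroth-order (independence) model: p̂(j) from a single margin of the
  table, with expected transition frequencies E[i,j] = p̂(j)·O[i,·].

Transitions never cross a session boundary; pooling across sessions or
animals sums the per-session tables.  Start-state totals are counted over
trials 1..n−1 (trials that have a successor), which keeps the row margins of
O and E exactly consistent; the alternative all-trials denominator differs
by at most one count per state and is available via the `margin`
option (`"start"`, `"end"`, `"all-trials"`).  The default margin is
`"end"` (trials 2..n), which makes E the classic product formula
E[i,j] = O[·,j]·O[i,·]/n.  Never-visited start states give undefined
(NaN-flagged) probability rows; no smoothing is applied anywhere, and
undefined rows are simply absent from the statistics (their O and E are
zero).

## Tests

* **W (full table).**  W = 2 Σ O·ln(O/E) with 0·ln 0 = 0; cells with
  E = 0 and O > 0 are a degenerate-table error (cannot happen with the
  end margin, where E[i,j] = 0 forces O[i,j] = 0).  Referred to χ² with
  (S−1)² = 16 degrees of freedom regardless of undefined rows.  The reject
  flag uses the fixed-critical-value rule (26.30 at α = 0.05); the p-value
  is reported but does not drive the decision.
* **Restricted χ² (one column).**  Pearson form over transitions into the
  target state, default dof = 5 (configurable to 4 for the
  constrained-column argument), critical value 11.07 at α = 0.05.
* **Y profile.**  Y[i] = (O[i,t] − E[i,t])/√E[i,t]; undefined where
  E = 0.  Sign convention: positive = more transitions than independence
  predicts.
* **Split-half.**  Sessions are split at ⌊n/2⌋ by trial count (elapsed-time
  splitting is not modelled); halves are pooled across sessions and fitted
  assuming within-half homogeneity.  The report carries each half's
  transition matrix and W test plus the maximum absolute difference of the
  into-target probabilities over rows defined in both halves.  No formal
  two-sample criterion is imposed — the summary is descriptive.  Sessions
  shorter than 4 trials are excluded with a warning.

## Synthetic world

The generator emulates the statistical structure the analysis assumes, not
rodent behaviour per se:

* **Policy layer.**  Actions (correct, incorrect, omission, premature) are
  drawn i.i.d. (`independence` kind) or conditioned on the previous trial
  *outcome* (`first_order` kind; 5 conditioning states so R-vs-NR history
  can causally matter).  Default action mix (0.65, 0.10, 0.10, 0.15):
  ≈87 % accuracy among responses and 10 % omissions — a stable, well-trained
  animal — with a typical 15 % baseline premature rate.  Chosen once for
  realism; all calibration results below are reported under it.
* **Task layer.**  Each *correct action* consumes the next slot of the
  reward schedule and becomes R or NR.  The schedule is built in 20-trial
  blocks, each containing exactly round(20·p(R)) rewarded slots in
  seeded-random order.  Consuming one slot per correct action (rather than
  per trial) guarantees the planned R:NR ratio among correct trials, which
  is the contingency the analyses condition on.
* **Cohorts.**  Per-subject policies are the base policy perturbed on the
  log-odds scale (Normal(0, sd), softmax-renormalised), one session per
  condition, all seeded through `numpy.random.SeedSequence` spawning.
* **Latencies** (optional) are lognormal with a log-mean shifted by the
  policy's premature propensity — enough to exercise the macro
  premature-vs-latency correlation utility, with no claim of realism.
  ITI and time-out are metadata only; within-session drift, satiety,
  time-caps and perseverative responding are not modelled.  A green
  simulation test therefore establishes correctness of the estimators and
  decision rules under the stated stochastic world, not behavioural
  validity.

## Statistical behaviour at desk scale (measured, not asserted)

Two nominal small-sample targets are *not* met by the G statistic at
200-trial sessions under the default mix, and the corresponding acceptance
tests are left failing rather than tuned:

* **Type-I calibration.**  Across 2000 null (independence-policy) sessions
  of 200 trials, the W test at α = 0.05 rejects at rate ≈0.09 against a
  nominal 0.03–0.07 band.  With the realistic margins the rare outcomes
  give expected cells ≈2, where the G statistic is known to be liberal:
  i.i.d. sequences at the same margins give 0.081 (so ≈0.01 of the excess is
  the blockwise schedule's slight negative R/NR dependence), n = 1000 gives
  0.050, and balanced 0.2 margins give 0.063.  W itself agrees with an
  independent likelihood-ratio computation to 1e-13, so this is a property
  of the statistic at this sample size.  Practical implication: pool
  sessions (as the pipeline does per condition) before testing.
* **Power.**  A +0.25 premature→premature carry-over at n = 200 is detected
  in ≈52 % of replicates, not >95 %.  The implied noncentrality is
  λ = n·π(1−π)·Σⱼ(bⱼ−P_premature,ⱼ)²/pⱼ ≈ 13 for any realistic baseline
  premature rate, whereas χ²₁₆ at critical value 26.30 needs λ ≈ 32 for
  95 % power; the target is unattainable at this n.  The qualitative
  signature — the largest positive Y at premature→premature — is recovered
  in 98 % of the same replicates.

## Numerical choices

* χ² quantiles/tails from `scipy.stats.chi2`; probability-sum tolerances
  1e-12, frequency-sum tolerances 1e-9.
* Quartile screen (HI/MID/LI): `numpy.percentile` linear interpolation;
  values strictly above the 75th / below the 25th percentile are HI / LI,
  boundary-equal values go to MID so the extremes stay strict.  The set of
  screening sessions is an explicit argument, not hard-coded.
* Trial indices are 1-based and dense; the trial-log CSV carries
  `subject,session,trial,outcome,p_reward,iti_s,timeout_s[,latency_ms]`.
  The session cap is not serialised, so a read session's cap is
  max(n, 100); round-trips are exact whenever the cap equals the session
  length or the default 100.
* Determinism: every stochastic component takes an explicit seed; identical
  config + seed reproduce sessions and the whole report bundle
  byte-for-byte (no timestamps in outputs).

## Known limitations

Only first-order structure is estimable (no higher-order chains, no
latency-conditioned transitions); no exact small-sample or permutation
versions of the tests; no multiple-testing correction across conditions;
the split-half comparison is descriptive; raw operant-chamber event files
are not parsed.
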