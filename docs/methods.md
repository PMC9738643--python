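# Methods

## The inference model

The package treats a differential diagnosis as a discrete probability
distribution over an **exhaustive, mutually exclusive** set of candidate
primary causes. With priors $P(D_i)$ and per-finding conditionals
$P(F_j \mid D_i)$, the posterior after observing findings
$F_1,\dots,F_n$ is

$$P(D_i \mid F_{1..n}) \propto P(D_i) \prod_{j} P(F_j \mid D_i),$$

normalized to 100%. This is the naive-Bayes form: findings are assumed
conditionally independent given the diagnosis. Elicitors are
accordingly instructed to rate each finding in isolation; correlated
findings (e.g. two imaging modalities seeing the same lesion) will
double-count evidence, and that is a modelling limitation, not a bug in
the arithmetic.

Everything external is on a 0–100 percent scale because that is how the
estimates are elicited and printed. Internally only ratios matter: the
posterior is invariant to rescaling any one finding's conditional
column, so there is no need to convert percents to probabilities
anywhere in the update. Products are accumulated as sums of logs; a
five-finding case already yields percent-scale products near $10^9$
and longer chains overflow double precision, while log space does not.
The raw product is exponentiated only for table display (and may print
as `inf` for pathologically long chains; the posterior itself cannot).

**Zeros.** A single zero prior or conditional pins a posterior at zero
permanently, which is almost never what an elicitor means by
"basically impossible". Zeros are therefore rejected at construction
with an explanatory error; a `floor`/`clamp` option substitutes the 1%
elicitation floor with a logged warning instead. The floor itself (1%)
reflects the resolution limit of individual clinical experience —
frequencies below 1 in 100 are not distinguishable by someone who has
seen fewer than 100 similar cases.

**Chaining.** When the reference time point moves (pre-surgical workup
→ post-surgical course), the first stage's posterior becomes the second
stage's prior, carried forward **unrounded**. Chaining is then exactly
associative: a chained two-stage update equals one update over the
union of findings, which the tests verify both algebraically (property
test) and on the bundled case.

## Elicitation and pooling

Per-expert estimates live in `[1, 100]`; validation reports violations
cell-by-cell (floor, range, missing) without raising, so a whole panel
can be checked in one pass. Prior vectors are expected to sum to ~100;
drift up to ±2 percentage points is accepted silently because rounded
composites legitimately drift (the bundled case's printed composite
priors sum to 100.7), and larger drift draws an advisory. An explicit
`renormalized()` exists; nothing renormalizes automatically, so printed
tables can be reproduced exactly.

Panels are pooled cell-wise. The default and recommended pool is the
arithmetic mean (linear opinion pool), which is what produces the
bundled case's composite tables; geometric-mean and median pools are
available for sensitivity exploration only and are never defaults.

**Precision of printed composites.** A composite that is the mean of
three integer estimates is an exact multiple of 1/3; printing it at one
decimal loses up to ~0.033. `reconstruct_unrounded` snaps printed
values back to the nearest third when they are within rounding distance
of one, recovering the full-precision inputs that reproduce the case's
printed product columns to <0.01% (stage 1) and ≤0.6% (stage 2 — one
printed conditional there, 6.1, is not a third-multiple and its exact
value is unrecoverable from the printed digits, leaving one row 0.54%
off). Posterior percents are insensitive to this at printed precision
except one stage-1 row (disseminated idiopathic myofasciitis) that
rounds to 7% from the printed inputs and to the printed 6% from the
reconstructed ones; the fixture-integrity tests therefore recompute
derived columns from the reconstructed composites.

## The decision model

Two choices (treat / no treat) × two states (disease / no disease) give
four leaf utilities on a 0–100 rating scale ("relative utility": a
composite of survival and cost). `untreated_no_disease` defaults to
100 by construction — no disease, no intervention, no cost — anchoring
the scale's top. Expected values are linear in the disease probability
$p$, so the two choice lines cross at exactly one point, the treatment
threshold $p^* = 1/(1+B/H)$ with benefit
$B = U_{td} - U_{ud}$ and harm $H = U_{un} - U_{tn}$. The
implementation cross-checks the closed form against the expected-value
crossing to $10^{-9}$ on every call.

Numerical choices:

* **Indifference**: $|EV_{treat} - EV_{no\,treat}| < 10^{-9}$ (on the
  0–100 scale) reports a three-valued `"indifferent"` verdict rather
  than an arbitrary tie-break, matching the interpretation that at
  exactly the threshold neither strategy is preferable.
* **Dominance**: $B \le 0$ or $H \le 0$ means the lines never cross in
  (0, 100); `treatment_threshold` raises a structured error naming the
  dominant/dominated configuration, and the sensitivity sweep reports
  `"always treat"` / `"never treat"` instead of a crossing (a curve
  touching zero only at a grid endpoint counts as dominance).
* **Sweep crossing**: located by linear interpolation between the
  bracketing grid points; because the difference is linear, the
  interpolated crossing equals the closed-form threshold to floating
  precision for any grid that brackets it.
* **Rounding**: all arithmetic is full precision; rounding to whole
  percents/points is display-only.

Multi-diagnosis posteriors collapse to the binary tree via
$p = P(\text{target diagnosis})$, $1-p = $ everything else — valid
because the differential is exhaustive and mutually exclusive.

## Synthetic data

`simulate_panel` generates expert panels around a known ground-truth
belief:

* **Priors**: Dirichlet with concentration mass $c$ spread over the
  true prior proportions (default $c = 200$, chosen to give a spread of
  roughly ±2–4 points on mid-sized priors — comparable to the
  disagreement a real three-clinician panel shows on most cells, while
  keeping generated values inside the elicitable range almost always).
* **Conditionals**: true value × a log-normal multiplier with unit mean
  on the linear scale (default $\sigma = 0.3$, about ×/÷ 1.35 per
  expert). Unit mean makes the arithmetic-mean pool unbiased, so the
  composite converges to the truth as the panel grows — the parameter-
  recovery property the tests verify at n ∈ {3, 10, 30, 100}.
* Values are clamped into [1, 100] and **clamp events are counted** on
  the returned sample, so heavy-noise regimes that distort the model
  are visible.

`simulate_case` draws one patient: given the true diagnosis, each
finding independently "matches" the clinical picture with its
conditional probability; the evidence likelihood is $c$ for a matching
finding and $100 - c$ (floored at 1) for a non-matching one. Cohorts
draw true diagnoses from the renormalized priors.

Both generators are pure functions of an explicit seed.

What the generators do **not** emulate: correlated expert errors
(real panels share literature and training), systematic over/under-
confidence, correlated findings within a patient, and elicitation-scale
artifacts (digit preference, anchoring on round numbers). Tests passing
on synthetic panels therefore demonstrate the pipeline's statistical
correctness under the stated noise model, not that three real experts
suffice for precise posteriors — on the bundled case they visibly do
not, which is part of the point.

## Problem sizes

Everything in the bundled case is desk-scale (7 diagnoses × 8 findings;
milliseconds). The test suite's stochastic checks use panels up to 100
experts and cohorts of 1,000 simulated cases, sizes at which the
law-of-large-numbers assertions have comfortable margins; the whole
suite runs in a few seconds.

## Known limitations

* Conditional independence of findings (discussed above) is the big
  structural assumption; no dependence modelling is offered.
* Binary decision tree only is tested end-to-end; the utilities type
  does not yet model three-way choices (e.g. treat / test / wait), and
  test-treatment thresholds are out of scope.
* Aggregation is cell-wise opinion pooling; no calibration weighting or
  behavioural (Delphi-style) aggregation.
* Utilities are rating-scale elicitations taken at face value;
  standard-gamble or time-tradeoff elicitation is out of scope.
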