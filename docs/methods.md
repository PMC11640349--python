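# Methods

This note documents the models, the numerical choices and the synthetic
data generator in enough detail to judge what the package's tests do and
do not demonstrate.

## Curves from event logs

Trials are timed button-press logs (`start`, `tds_select`, `liking_score`,
`stop`).  Trial time is normalized by the trial duration so the stop maps
to exactly 1.0, and curves are evaluated on an even grid of `m = 101`
points on [0, 1] (configurable).  101 points resolve a 20–30 s trial at
0.2–0.3 s — finer than panelists press buttons — while keeping ESN
sequences short.

Dominance and liking both use *left-closed carry-forward*: a press takes
effect at its own timestamp, and at an exact press time the new value
wins.  Before a trial's first TDS press no attribute is dominant (the
trial contributes 0 to every proportion, so early row sums are below 1);
before the first liking press the recorded score is 0, including inside
averages.  These conventions make single-trial curves exact step
functions, and averaging commutes with gridding.

A selection may legally coincide with the start event (press at t = 0);
two events of the *same* kind may not share a timestamp.

## Augmentation

The resampling unit is the participant, not the trial: each participant's
repeated trials are first averaged into one curve pair, then a bootstrap
dataset draws N of N participants with replacement and averages the drawn
pairs.  This preserves the within-participant coupling between what a
panelist perceives and what they like — the only source of information
linking attributes to liking once the shared time profile is removed.
Defaults are 1600 training / 160 validation datasets in 16 disjoint folds
of 100 / 10 (one fold per ensemble model); a single master seed spawns one
child generator per fold, so the collection is a pure function of
(panel, sizes, seed).  Validation folds are disjoint from training folds
by construction.

## Echo state network

* Update: `x(k) = (1−α) x(k−1) + α tanh(W x(k−1) + W_in u(k) + b)`,
  zero initial state, no washout (sequences are only 101 steps and
  predictions are needed from t = 0).
* `W`: exactly `round(c_r · N²)` nonzeros (uniform(−1,1)) at random
  positions, rescaled so its largest-magnitude eigenvalue equals the
  configured spectral radius (dense eigendecomposition; N = 128 is cheap).
  The exact-count mask makes the connectivity invariant testable.
* `W_in`: exactly `round(c_in · N·n)` nonzeros, **balanced across input
  columns** so every attribute channel reaches the reservoir even at
  connectivity 0.01 (a fully unconnected channel would be invisible to
  the model and make its sensitivity probe meaningless); entries
  uniform(−1,1) × input scaling.  `b`: uniform(−1,1) × bias scaling.
* No input→output bypass and no output feedback.
* Readout: ridge by normal equations on the stacked states plus a
  constant-1 column; the intercept is unpenalized (liking scores have a
  large positive mean).  A singular system with ridge 0 raises an error
  advising a positive coefficient.
* Defaults / search ranges: α = 0.01 and ρ = 0.90 fixed (searchable by
  config); input scaling ∈ [0.01, 1.43], bias scaling ∈ [0.03, 18.30]
  (log-uniform), input connectivity ∈ [0.01, 0.10], reservoir
  connectivity ∈ [0.05, 0.88], ridge ∈ [0.01, 3.48] (log-uniform).
  Defaults for single-model use are the (geometric) midpoints of these
  ranges.  Tuning is plain random search (budget 200 by default, 50 in
  the reduced-scale pipeline test), selecting the minimum mean per-curve
  validation RMSE, ties to the earlier sample.

## Evaluation

Metrics are computed per validation curve over the time grid:
`RMSE = sqrt(mean (obs−pred)²)` and `R² = 1 − SS_res/SS_tot`.  A constant
observed curve has undefined R² and is flagged rather than scored.
Distributions are summarized Tukey-style: quartiles by linear
interpolation, whiskers at the most extreme data within 1.5 × IQR of the
box, points beyond them reported as outliers, arithmetic mean alongside.

## Sensitivity analysis

Step inputs are constant full-grid sequences (length m, matching
training, so the probe explores the same transient regime): one attribute
at 1, or a pair at 0.5 each; column sums are always 1.  The response
maximum is taken over the whole output, initial transient included, and
is not clipped to [1, 9].  The n(n+1)/2 unordered pairs fill a symmetric
matrix with the elemental sensitivities on the diagonal
(`y(a,a) = y(a)` by construction, so the b = a term of the interactive
sum vanishes identically).

Ensemble aggregation over K models: mean and 95 % CI (Student t, df =
K−1) for every pair; for `s(a)` additionally the paired two-tailed
t-statistic against 0 and Bonferroni-corrected p-values (factor n).  Zero
variance with nonzero mean reports an infinite t rather than failing.

The package ships the published eight-attribute strawberry reference
table of ensemble-mean `y(a,b)` values; feeding it through
`interactive_sensitivity` reproduces the published `s(a)` values exactly
at 2-decimal rounding, which is what `scripts/acceptance.py` recomputes.

## Synthetic panel generator

The generator exists so the whole pipeline can be exercised against a
known ground truth.  It emulates the study protocol — 31 participants,
TDS task and liking task three times each, 20–30 s trials — but its
parameters are plausibility choices, not estimates from any real panel.

**Press behavior** is a semi-Markov chain: initial latency lognormal
(median 1 s, σ = 0.6 log-s); first attribute from an initial distribution
concentrated on sweet/juicy/watery; zero-diagonal stochastic transitions
in which an "early" flavor group (aromatic, juicy, sweet, fruity, watery)
leaks 30 % per transition into a "late" group (light, green, sour) that
mostly stays late — reproducing the early-sweet/late-sour shape of real
strawberry dominance curves; gamma(2, 1.5 s) dwell times (mean 3 s).

**Liking** follows a latent first-order hedonic state with time constant
τ = 2 s toward `baseline + w[dominant attribute]`, baseline 5.  The
latent is initialized at its *first* target (the first impression), so a
panel with equal weights produces a constant latent and a single rating.
Ground-truth weights (score units): sweet +1.8, fruity +1.4, juicy +1.0,
aromatic +0.2, watery 0.0, sour −0.2, light −1.2, green −1.6 — a spread
comparable to the published elemental-sensitivity spread.  Reporting
layer: the first rating trails the first dominance onset by a lognormal
delay (median ≈ 3 s, σ = 0.8 log-s; some panelists take much longer,
which is what produces the gradual rise of the average curve from 0 to
its mid-trial plateau); re-ratings occur when the rounded, clamped latent
moves at least 1 step from the last entered score; entered scores carry
Gaussian noise (sd 0.3) before rounding and clamping to 1–9.

**Heterogeneity.**  Each participant gets (i) a per-attribute usage
propensity `g_a ~ lognormal(0, 1.2)` multiplying the transition-matrix
columns and the initial distribution (renormalized) — TDS panelists
genuinely differ enormously in citation rates — and (ii) multiplicative
hedonic-weight noise (sd 0.3).  This between-participant covariation of
behavior and liking is the *only* identifying signal for the attribute
weights once the shared time profile is removed; with a nearly
homogeneous panel the weights are unidentifiable from 31 participants
(verified with an oracle regression during development), and no regressor
could recover them.

**What the generator does not emulate**: swallowing/bite mechanics,
fatigue or drift across trials, correlation between a participant's TDS
and liking *trials* beyond shared propensities, non-stationary hedonic
weights, or panel-level outliers.  Passing tests therefore demonstrate
pipeline correctness and recoverability under this generative model, not
performance on real panels.

## Known limitations

* With the fixed leaking rate 0.01 and spectral radius 0.90 on a 101-point
  grid, every reservoir mode has a time constant of ≥ ~50 steps, while
  the liking dynamics evolve on ~8 steps (τ = 2 s of a ~25 s trial).  The
  readout therefore fits the fast components through the input channels
  themselves, and per-attribute credit assignment is weakly identified:
  step-response sensitivities of a *single* model carry noise on the
  order of ±1 score unit.  Ensembles of 16 models average much of this
  away; the reduced 3-model ensemble used in the fast end-to-end test
  reliably recovers the strongest weights (sweet positive, green
  negative) but not always the mid-sized ones (fruity, light) — the
  dedicated pipeline acceptance test documents this quantitatively.
* Single-attribute step probes (dominance 1.0 held for the whole trial)
  are far outside the training distribution of averaged panel curves;
  tanh saturation makes single steps compress more than pair steps,
  adding a positive skew to `s` for weakly identified attributes.
* Quartiles use linear interpolation between order statistics; other
  conventions shift box summaries slightly.
* The problem sizes used by the test suite (300/30 datasets, 3 models,
  budget 50, 10 seeds end-to-end; 10 000 draws for distributional checks)
  were chosen as the smallest sizes at which the checked quantities are
  stable.
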