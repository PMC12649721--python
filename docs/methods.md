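# Methods

## Model

Each motor-performance parameter is modelled independently from a
cross-sectional cohort of children aged 5–18. The observation model is

    y_i = f(age_i; a0, a1, a4) + a2·sex_i + a3·hand_i + ε_i,
    E|ε_i| = c0 + c1·age_i,

where `f` is either `a0·exp(a1·age)` (exponential family) or
`a0·age² + a1·age` (quadratic family), sex and hand are dummy-coded 0/1
covariates entering as additive offsets, and the noise is symmetric about
zero with an expected absolute deviation that is linear in age. The
exponential family is selected iff every observed value is strictly
positive; zeros or negative values force the quadratic family, because the
exponential fit's initial estimates come from a straight-line fit to
`ln y` (log-linearisation), which needs a positive response. When the
values hug zero (minimum below 5% of the maximum), 0.9·min(y) is
subtracted before the logs and restored as the offset's initial estimate;
otherwise the offset starts at 0. These thresholds only seed the
optimizer — the final coefficients come from damped (Levenberg–Marquardt)
least squares with an analytic Jacobian, at most 1000 residual
evaluations, and an SSE-change tolerance of 1e−10.

Key assumptions: development is monotone-or-quadratic in age with no
interaction between age and the dummies (the sex/hand offsets are
constant across age); both hands develop along the same curve, differing
only by the hand offset; observations are independent across rows (the
two hand rows of one participant are treated as independent).

## Cross-validated model selection

Both the mean curve and the absolute-residual line are selected by 10-fold
cross-validation: a seeded permutation splits the rows into 10 near-equal
groups; each fold's model is trained on the other nine and scored by
R² = 1 − SSE/SST on the held-out fold (SST about the held-out mean; a
negative held-out R² is allowed); the fold model with the maximal held-out
R² is returned as-is, without refitting on the full data. Ties break to
the lowest fold index for determinism. Folds that fail to fit are excluded
from the contest and logged. The residual-line contest uses the mean-curve
seed offset by +1, so the two splits are different but both reproducible.

## Age-specific spread and z-scores

With normal noise, E|ε| = σ·√(2/π), so the fitted mean absolute residual
m(age) converts to a spread estimate

    s(age) = √(π/2) · n/(n−DOF) · m(age).

The printed source formula for this scaling is typographically ambiguous
about whether the bias factor n/(n−DOF) sits inside or outside the square
root; we default to outside (the classical MAD→SD factor √(π/2) times a
multiplicative bias correction) and expose `scaling_root_inside` to switch.
At the study's n (hundreds) the two differ by under 1%. DOF counts the
coefficients consumed before the spread is estimated: the mean curve's (5
with the hand term, 4 without) plus 2 for the residual line, i.e. 7 or 6;
`scaling_dof_curve_only` switches to counting only the curve's. m(age) is
floored at 1e−9 of the response range so s stays positive if the line
dips below zero at an extreme age. z-scores are `residual / s(age)`.

## Normality gate and transform ladder

Three rounds of sigma clipping run on the z-scores: each round recomputes
the mean and sample SD over currently retained points and flags points
more than 3 SDs out; flags accumulate and exactly three rounds always run,
so isolated extremes cannot dominate the subsequent normality test. (Note
a hard bound: a single outlier among n points can lie at most (n−1)/√n SDs
from the mean, so the 3-SD rule cannot flag anything for n ≤ 10.) The
clipped points are excluded from the normality assessment and reported,
but the mean curve is *not* refit without them.

Retained z-scores are tested with Shapiro–Wilk at α = 0.05 (above
n = 5000 a seeded subsample of 5000 is tested; the moments use all
points). A failing sample is still accepted as "normal enough" when
|skew| < 0.6 and the Pearson kurtosis (normal = 3) lies in (2.4, 3.6) —
at these sample sizes Shapiro–Wilk detects deviations too small to
distort a 95% band.

If the gate fails, the original values are shifted by `−min + 1` (making
the minimum exactly 1, so all transforms are real and finite) and the
log, square-root and reciprocal transforms are each applied; every
variant reruns the *entire* pipeline — family selection, curve fit,
residual line, z-scores, clipping, gate — in its own transformed space. A
variant passing the gate wins; among several, the one with the highest
held-out R² (each in its own response space, as no common scale exists);
if none pass, the untransformed models are kept for simplicity. The
recorded shift makes every transform invertible; normative-band bounds
are built in working space as center ± z₀.₉₇₅·s(age) and back-transformed
(bounds swap under the order-reversing reciprocal; bounds outside a
transform's domain are clipped to the domain edge with a warning).

## Deficit scoring

A new observation is transformed with the stored shift, standardised by
the model's curve and spread at its age/sex/hand, and |z| > 2 (≈ the
2.3rd/97.7th normal percentiles) flags a deficit. Ages outside the fitted
range are scored with an extrapolation warning — the curves change
fastest, and are least constrained, at the young end.

## Synthetic cohorts

The generator emulates the cross-sectional structure the analysis
assumes, with known ground truth for recovery testing:

* **Ages** — truncated skew-normal on [5, 18] with fixed shape −3
  (right-heavy: mode in the teens, long tail toward age 5), location and
  scale iteratively moment-matched so the truncated distribution hits the
  target mean 13 y and SD 3.2 y (to within ≈0.1 y at large n). Ages are
  continuous years. The real recruitment histogram is not claimed, only
  its first two moments and direction of skew.
* **Sex** — Bernoulli with male fraction 0.66 (≈2:1), coded female=0,
  male=1.
* **Hands** — for unimanual parameters, both hand codes are emitted per
  participant (288 → 576 rows) with independent noise; real within-child
  hand correlation is not simulated, which makes the effective sample
  size optimistic.
* **Noise** — `normal`: ε ~ N(0, m(age)·√(π/2)) so E|ε| = m(age) exactly.
  `skewed`: a centred gamma with requested skewness g (shape k = (2/g)²,
  using E|X−k| = 2·k^k·e^(−k)/Γ(k)), rescaled to the same E|ε|; a gamma is
  used because a skew-normal's skewness cannot exceed ≈0.995, and
  exercising the transform ladder needs skewness ≈ 2.

The reference scenarios in `devnorm.scenarios` fix the generator's
defaults to study-like conditions: the reaction-time truth decays 54%
from ≈0.52 s at age 5 to ≈0.24 s at 18 with a 95% band shrinking 0.268 →
0.0685 s (74%); total hits grow with a +8-ball male offset and a nearly
constant band (82 → 87); path-length ratio's band shrinks 0.687 → 0.187.
Coefficients were derived by inverting the curve and band-width formulas
at ages 5 and 18 from those targets.

What passing tests on these cohorts do **not** show: robustness to
within-participant correlation, measurement-device drift, non-linear
variance profiles, or misspecified curve families — the generator
satisfies the model's assumptions by construction, so the tests validate
the estimation machinery, not the model's adequacy for any real dataset.

## Numerical and design choices

* Held-out R² with zero held-out variance: 1 if SSE ≈ 0, else −∞
  (excluded from the contest).
* Dummy covariates with no variation in (a fold of) the data are dropped
  from the design and their coefficients pinned to 0, rather than erroring
  or returning an arbitrary least-norm solution.
* Report percentages round half-away-from-zero to integers (58.5 → 59);
  full precision is kept internally.
* Band quantile: z₀.₉₇₅ = 1.959964 (normal, justified by the gate).
* The bootstrap band CI resamples participants (both hand rows together)
  and refits the curve and residual line per replicate with percentile
  CIs; the gate/transform ladder is not re-run per replicate, trading a
  small underestimate of model-selection variability for speed.
* Validation problem sizes: 50-seed recovery runs at n = 576, calibration
  and coverage at n = 5000, spread recovery at n = 10⁵, ladder-benefit
  comparison over 100 seeds at n = 288.

## Known limitations

* The exponential rate a1 is weakly identified under study-like
  conditions: with ages skewed toward the old, nearly flat end of the
  curve and the noise level implied by the reference band widths,
  single-cohort rate estimates at n = 576 land within 15% of truth in
  only ≈80% of simulated cohorts (the residual-slope sign, by contrast,
  recovers essentially always). A uniform age distribution or half the
  noise brings rate recovery to ≈95–100%, so this is an information limit
  of the cohort design, not of the estimator — and is the quantitative
  face of the usual caution against interpreting these curves below
  age ~9.
* Returning the best cross-validation fold's model (rather than refitting
  on all data) leaves ~10% of the data unused by the final coefficients;
  it is kept because it is the described procedure.
* Back-transformed bands from the reciprocal transform can be asymmetric
  and, for working-space bounds near 0, require domain clipping.
* The ±2 cutoff treats each parameter separately; no multiplicity
  correction across a task's many parameters is attempted.
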