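# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Experimental design

The seven crossing factors are held in a fixed order (Side, Orientation,
vSpeed, pSpeed, Angle, Order, Margin) with the first-listed level of each
factor coded −1 and the second +1.  The 2^(7−2) fraction uses the
minimum-aberration resolution-IV generator pair F = ABCD, G = ABDE over
the first five base factors; its defining words (ABCDF, ABDEG, CEFG) all
have length ≥ 4, so every main-effect and interaction column up to third
order sums to zero, and any three factors project onto a four-fold
replicated 2³ — both properties are verified by test rather than assumed.
The exact fraction used in the original experiment is not recorded;
results depend on it only through the alias structure, which no analysis
here touches.  Trial plans shuffle the 32 runs with a seeded uniform
permutation and insert the four scripted collision trials at ranks 7, 14,
21, 28 (vehicle 30 kph, pedestrian 7.5 kph).  Collision trials are
carried through every table but excluded from all fitting and from all
normalising statistics.

## Indicators and transforms

Trial windows are closed intervals from crossing onset to pass time + 3 s
(the 3 s absorbs SCR latency); boundary events count.  iSA is the
trapezoidal integral of the 20 Hz rating trace over the window (window
edges interpolated, so piecewise-linear traces integrate exactly), mSA its
in-window maximum on the raw trace.  EDA conditioning is resampling to
50 Hz, a centred 1-s moving median and a 1-Hz zero-phase low-pass
(4th-order Butterworth); SCRs are trough-to-peak excursions above a
threshold.  The threshold defaults to 0.05 μS: the 5 μS value sometimes
quoted for this protocol is far outside the physiological range of
phasic responses (conventional thresholds are 0.01–0.05 μS) and would
discard essentially every response, so it is treated as a transcription
error and kept configurable.  Continuous decomposition analysis (Ledalab) is *not*
reimplemented: the pipeline accepts phasic traces or SCR event lists
directly, which is where that tool's output enters the analysis anyway.

Skewness correction raises iSA to the 1/2 and mSA to the 1/3 power; the
subjective indicators are then centred and scaled to unit variance within
participant.  "Standardising" the SCR indicators cannot mean centring —
subtracting a mean would destroy the exact zeros and the nonnegativity
that the compound Poisson–gamma law requires — so they are divided by the
participant's mean over nonzero values and not centred.  A participant
with zero variance in a subjective indicator keeps unit scale and
triggers a warning rather than an error.

## Tweedie node

For 1 < p < 2 the Tweedie law is compound Poisson–gamma with
λ = μ^(2−p)/(φ(2−p)), gamma shape α = (2−p)/(p−1) and scale
φ(p−1)μ^(p−1).  The density is evaluated through the Poisson–gamma
mixture series in log space; truncation starts past the index of the
largest term (≈ y^(2−p)/(φ(2−p))) and doubles until the last term is
below 1e−10 of the running sum.  The log-link GLM exploits the fact that
the score equations for the coefficients do not involve φ: coefficients
are exact MLEs by IRLS (working weight μ^(2−p)), φ is then maximised
against the exact series likelihood by a bracketed 1-D search in log φ
(Pearson estimate as start), and p by profile likelihood over the grid
1.1, 1.2, …, 1.9 with bounded local refinement (tolerance 0.01) between
the best grid point's neighbours.  Standard errors come from the expected
information φ(XᵀWX)⁻¹.  Degenerate inputs — all-zero responses, negative
values, rank-deficient designs, or responses that fit the mean exactly
(φ unidentifiable) — are rejected.  The saddle-point approximation and
the p ≤ 1 / p ≥ 2 regimes are out of scope.  The implementation is
cross-checked in the tests against statsmodels' independent series
likelihood (agreement to ~1e−9 relative) and sklearn's deviance-based
`TweedieRegressor` coefficients.

## Network scoring

Factor roots are Bernoulli(1/2) by design balance: they contribute the
structure-independent constant n·7·ln 2 to −2 log L with k = 0, retained
so each total is a genuine joint-likelihood BIC (it cancels in every
ΔBIC).  The Gaussian node uses one mean per parent-level cell plus a
single shared variance (k = 2^|parents| + 1), matching how condition
means are reported and feeding the cluster stage directly; a per-cell
variance variant was considered and rejected as inconsistent with the
pooled-variance cluster model.  When the SCR indicator is a parent of the
subjective node it enters as one additive linear covariate (k + 1).  The
SCR node is the log-link Tweedie GLM on 0/1-dummy-coded parents, plus the
subjective indicator as-is when the edge points that way; its k counts
the coefficients plus φ and p.  n in the penalty is the number of
modelling records (participants × 32).

Families are fitted once per distinct (child, parent set, covariate arm) —
at most 128 Gaussian and 128 Tweedie fits — and the 12,288 totals are
assembled by summation; a monolithic record-by-record joint-likelihood
scorer exists purely as an oracle and must agree to 1e−8.  During the
search one Tweedie power is profiled per indicator (on the family with
the subjective covariate as sole predictor) and held fixed across
families, with φ still refit per family: p characterises the response law
rather than any particular mean structure, estimating it per family adds
a constant 2 to every structure's k anyway, and a single profile keeps
the exhaustive search at paper scale to a couple of seconds
(`p_mode="per-family"` restores the slower variant).  Ties in BIC are
ordered by the canonical enumeration order (parent sets by size then
position, edge none < sa_to_scr < scr_to_sa) and graded "Weak".

## Cluster stage

Partitions of the winning Gaussian node's cells are enumerated as
restricted-growth strings (exact, Bell(#cells) partitions, guarded to
≤ 10 cells — at most 8 arise from ≤ 3 binary parents).  Each partition is
scored on the underlying observations, not on the mean summaries: pooled
mean per block, shared variance, k = #blocks + 1, same n as the network
stage.  This makes the finest partition reproduce the network's Gaussian
node fit exactly and keeps all partitions on a common likelihood scale.

## Synthetic ground truth

The generator encodes the reported effect structure as an overridable
configuration.  Dynamics pair: cell means over Margin × Order of
(0.70, −0.28, 0.15, −0.57) — Order contrasts 0.98 at 1.5 m and 0.72 at
2.5 m — with SCR log-link slope 0.14.  Maxima pair: Margin main effect
±0.4 plus an Orientation-modulated Order effect giving contrasts 1.0
(pedestrian walking away) and 0.23 (facing) at either margin, slope 0.2.
Cell means live on the per-participant standardised scale; for that scale
to be self-consistent the residual SD defaults to
sqrt(1 − Var(cell means)) (≈ 0.88 dynamics, ≈ 0.84 maxima) so that the
within-participant variance is 1 and standardisation preserves the
planted contrasts — a fixed residual SD of 1 would shrink every contrast
by ~10% after standardisation.  Tweedie dispersion and power are not
reported; defaults are φ = 1 and p = 1.5, the midpoint of the admissible
interval.  SCR intercept 0.3 puts the zero-response probability near 0.1
at an average trial, a realistic non-response rate.  Participant
heterogeneity is an additive Gaussian offset (SD 0.5) on the transformed
subjective scale and a multiplicative lognormal factor (log-SD 0.3) on
SCR values — exactly the two nuisances the standardisation stage removes,
so that stage is exercised nontrivially.  Raw-scale tables invert the
skewness correction around a shift of 5 (so iSA_raw = (5 + offset + z)²),
keeping raw values positive and right-skewed.  Random streams split per
participant and per trial from one master `SeedSequence`.

What the generator does *not* emulate: tonic skin-conductance drift,
habituation across trials, heart-rate or pupil channels, any realistic
collision-trial response (collisions carry a saturated placeholder and
are excluded), and integer SCR counts in the table-level simulator — the
nSCR column is drawn from the continuous compound Poisson–gamma law the
model assumes, while the event-level simulator produces true integer
counts.  Passing tests therefore demonstrate that the pipeline recovers
structure and parameters when its distributional assumptions hold at the
reported effect sizes and sample size; they cannot certify behaviour
under the un-modelled features of real electrodermal data.

## Problem sizes and numerical conventions

Structure- and parameter-recovery checks run at the experiment's own
scale: 27 participants × 32 modelling trials (n = 864), 50 replicates for
recovery rates, 10,000 records for slope fits, 100,000 draws for sampler
law checks.  Stochastic assertions use 3 Monte-Carlo standard errors (or
the stated replicate-rate bounds); BIC decomposability is exact to 1e−8;
series truncation to 1e−10 relative.  The window boundary convention is
closed on both ends; mSA is taken on the raw 20 Hz trace (resampling
happens only on the EDA channel).  The four collision trials are flagged,
never modelled.
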