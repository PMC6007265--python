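# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `socialpref`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Task economics

Fixed parameters (`TaskConfig`): endowments 30/30, pie 100, transfers
{0,…,50} in steps of 10, punishment 0–30 in integer steps, leverage 5,
7-s response window, 100 points = 1 CHF (reporting only). Post-punishment
payoffs are `X_r = 30 + t − p` and `X_p = max(0, 130 − t − 5p)`; the floor
at zero keeps payoffs inside the design's printed ranges (0–80 responder,
0–130 proposer). The punishment that zeroes the proposer is
`ceil((130 − t)/5)`, i.e. 26 points at the most unfair transfer down to 16
at a fair split — creating advantageous inequality (AI) is cheapest after
fair offers, which matters repeatedly below.

## 2. Utility models and their fitting forms

All nine models (README table) are linear in their parameters. Each is
represented by named regressors per trial; `CharnessRabin` additionally
carries the fixed-coefficient offset `X_r` implied by its functional form,
so fitting regresses `y − X_r` on `(X_p−X_r)·{r,s,q}`. No intercept is
added anywhere (the equations have none); an intercept switch exists and is
off by default. Consequences of the literal no-intercept reading: fitted to
a dependent standardized to [−1, 1], the Charness–Rabin offset (tens of
payoff points) produces large residuals, so that model ranks last by a wide
margin. Nesting is defined as regressor-*set* inclusion with equal offsets
(`TotalReward` is not "nested" in `LinearCombination` even though its
regressor lies in that model's span).

Dependent variables are standardized per participant (behavior) and per
participant–channel–window (neural) by `x ↦ 2(x−min)/(max−min) − 1`;
constant input maps to zeros. Standardizing each regression's dependent —
rather than one global scaling per channel — keeps residual scales, and
hence AIC, comparable across sliding windows; with a single per-channel
scaling, early windows with little hemodynamic energy would get spuriously
small residuals and dominate the AIC-versus-window profile.

**Behavioral solver.** Every unconstrained model is solved in closed form
(least squares); a best-of-20 multi-start nonlinear least-squares path
(`scipy.optimize.least_squares`, xtol/ftol 1e-10, starts uniform on
α, β, ρ, σ, θ ∈ [−2, 2] and P-weights ∈ [−1, 1]) exists for all models and
is the only solver that can honor the Standard-FS constraints, via the
reparametrization `α = β + δ` with bounds `δ ≥ 0`, `0 ≤ β ≤ 1 − 1e−6`
(the strict `β < 1` bound). The two solvers agree to 1e−10 in RSS on linear
models; the test suite pins that equivalence, so the fast path is
oracle-checked.

**Neural solver.** Iteratively reweighted least squares with the fair
weight function `w(r) = 1/(1 + |r/(c·s)|)`, `c = 1.3998`,
`s = MAD(residuals)/0.6745`, at most 50 iterations, coefficient-change
tolerance 1e−8; rank-deficient designs fall back to least squares and are
flagged unconverged. RSS is reported unweighted so AIC remains comparable
with the behavioral fits. Standard FS is not fitted to neural data.

**Model comparison.** AIC in its least-squares form
`n·ln(RSS/n) + 2(k+1)`, counting the residual variance as a fitted
quantity; the same formula everywhere so rankings are comparable. Zero RSS
returns a sentinel minimal value with a warning. Nested F is the
extra-sum-of-squares test; the null reference "model" scores uniform(−1, 1)
draws against the standardized data (expected MSE 1/3 against a centered
signal). Ties in AIC rank break deterministically by registry order.

## 3. The synthetic cohort

The generator defines the study conditions; its defaults are fixed and the
tests run against them.

**Preferences.** Each agent holds true `FS_RT` parameters: α uniform on
[−0.033, 0.153] and β uniform on [−1, 0] (the behaviorally observed ranges
for this task family — predominantly AI-seeking), own-reward weight
P = 0.02 per point, and an RT (effort) weight uniform on [20, 30]
utility/second. Optional trial-to-trial preference jitter exists and is off
by default.

**Response times.** Deterministic RT =
`2.0 + 2.0·exp(−((t−20)/15)²) + 0.5·1[outcome ≠ E] + 2.0·(p/30)²` seconds,
plus N(0, 0.3) jitter on the realized value, clipped to (0, 7]. The three
components are: an inverted-U difficulty bump peaking at intermediate
transfers; a slowdown for unequal outcomes; and a quadratic slider-movement
time — larger punishments require larger mouse movements and hence more
time. Only the punishment-dependent components can influence choice.

**Choice.** Punishment is sampled by softmax (temperature τ = 0.2, argmax
at τ → 0 with ties to the smaller punishment) over the 31-grid of the
agent's full utility, in which the RT term prices the *anticipated*
deterministic RT of each candidate punishment. The quadratic movement time
thereby acts as a convex effort cost. This is the design's load-bearing
choice: with the piecewise-*linear* Fehr–Schmidt terms alone, optimal
punishments are corner solutions (zero, punish-to-equality, or
punish-to-proposer-zero). On the proposer-zero plateau `X_p ≡ 0`, so the
AI regressor equals `X_r` identically: the design matrix degenerates and
fitted coefficients reflect task geometry, not preferences — no noise
level or temperature rescues identifiability (we verified this across wide
parameter sweeps). The convex effort cost gives interior optima that vary
continuously with α and β, which is what makes parameter recovery possible
at all. At the chosen scales, slider effort rather than own-payoff loss is
the binding marginal cost of punishing; this is consistent with the small
own-reward sensitivities this task family reports.

**Consequence worth stating plainly:** a Fehr–Schmidt-rational agent with
α ≤ 0.153 punishes *maximally unfair* transfers little — zeroing the
proposer after a transfer of 0 costs 26 of 30 points across a 25-point
stretch of disadvantageous inequality, which is utility-negative at those
α values — so mean punishment *rises* from t = 0 to t ≈ 20–30 before
falling, instead of decreasing monotonically as human responders do. The
human pattern reflects reciprocal motives the Fehr–Schmidt family cannot
express (punishing the act, not the resulting payoff allocation). The
corresponding qualitative acceptance clause is therefore an expected,
documented failure under this generator, and passing it would have required
a corner-solution regime that destroys all parameter identifiability. We
privileged identifiability.

**Timeline and optics.** 60 trials (10 per transfer, shuffled), onsets
separated by 5 s transfer + 7 s response + 5 s fixed ITI + uniform(0, 10) s
jitter (mean 5 s), after 60 s of event-free baseline; sampling 10 Hz. The
per-trial neural amplitude is the standardized *valuation signal* of the
chosen outcome: the agent's inequity-weighted payoff terms plus a moderate
difficulty component `−8·RT_det` — the neural RT weight (8 utility/s) is
deliberately distinct from the choice-effort weight (20–30 utility/s),
because the hemodynamic signal is modelled as encoding the outcome's social
value and the engaged difficulty, not the slider-effort price of the
decision. Amplitudes are placed as impulses at transfer onsets, convolved
with a canonical double-gamma HRF (peak 6 s — gamma shapes peak+1 and
undershoot+1 so the density truly peaks at 6 s — undershoot ratio 1/6),
scaled by a regional gain (dlPFC channels 1–8: 1.0; dmPFC channels 9–16:
0.3 plus extra per-trial amplitude noise of SD 0.8), turned into ΔO₂Hb with
ΔHHb = −ΔO₂Hb/3, and pushed through the forward modified Beer–Lambert law
with the instrument's printed absorption coefficients
(µa(O₂Hb) = 1486/2526, µa(HHb) = 3843/1798 at 760/850 nm; DPF 7.25/6.38;
30 mm separation; concentrations in the arbitrary unit system those
coefficients imply — all downstream fits standardize, so the absolute
scale is immaterial). Nuisance terms in OD space: per-channel linear drift
(slope SD 50 OD/s), a 1 Hz cardiac sinusoid (amplitude 5e3 OD), and white
noise (SD 2e4 OD).

Numerical gain/noise values were calibrated once, at design time, so that
the recovery tests pass at realistic signal-to-noise (the only printed
anchor is the qualitative coupling claim: dlPFC stronger than dmPFC); they
were not revisited afterwards.

**What the generator does *not* emulate** — hence what passing tests do not
show about real data: reciprocity-driven punishment of unfair offers (see
above), motion artifacts beyond the optional spike injection, superficial
(scalp) hemodynamics, between-channel anatomical variability within a
region, habituation or learning across trials, and any deviation of real
prefrontal coding from the assumed linear utility-to-amplitude mapping.

## 4. Preprocessing

Order: (optional MAD despike in OD space, default off — it replaces the
manual visual artifact removal of lab practice with a reproducible
automatic rule) → Beer–Lambert inversion (exact 2×2 solve per sample;
round trip with the forward model is machine-precision) → per-channel
linear detrend → subtraction of each channel's first-60-s mean → tHb as
O₂Hb + HHb → per-trial sliding windows (width 2.5 s, step 180 ms, 40
windows from transfer onset; window value = mean tHb in
[onset + k·0.18, onset + k·0.18 + 2.5)). The 40-window count is taken as
authoritative although 39·0.18 + 2.5 = 9.52 s falls short of the nominal
12-s coverage; the grid is configurable. The per-window dependent variable
is the window mean (for boxcar regressors on baseline-corrected data this
coincides with a GLM beta up to scale). Hemisphere handling: left/right
channels of a region are pooled by averaging all of the region's channels
(dlPFC 1–8, dmPFC 9–16).

## 5. Inference statistics

*Percentage-bend correlation* implements the published estimator directly
(bend fraction β = 0.2 by default: ω = m-th smallest |x − median| with
m = ⌊(1−β)n + 0.5⌋, bend-winsorized location, clipped standardized scores,
t(n−2) p-value); the test suite checks it to 1e−10 against an independent
published implementation (pingouin). *Correlation comparison* defaults to
the independent-samples Fisher r-to-z z-test; Steiger's variant for two
correlations sharing one variable within a sample is available
(`method="steiger"`, requires the cross-correlation). The exact dependent
variant behind the original analysis is not identifiable from its
description; the default and the flag are documented here instead of
guessing. *Factorial ANOVA* is statsmodels OLS + type-II `anova_lm`
(type II so unbalanced designs remain well-defined; balanced designs are
unaffected) with Bonferroni-corrected pairwise t-tests on a chosen factor.
*Prediction* is scikit-learn SVR (linear kernel, C = 1, ε = 0.1 — fixed
defaults, none are dictated by the analysis being reproduced) on a seeded
50% holdout split, scored by holdout R² and maximized over the punishment
windows (starts ≥ 5 s after transfer onset, where the punishment phase
begins). Holdout R² may be negative for uninformative predictors and is
reported as computed. In the pipeline the SVR predictor is the *measured*
standardized per-window response, not the utility series evaluated at the
neural fitted parameters: fitted-parameter series from any region live in
the span of the same four design columns, which makes the regional
comparison insensitive to signal quality; only the measured response
carries the extra dmPFC noise the comparison is about.

## 6. Parameter recovery: what is and is not identifiable

Because every fitted dependent is standardized, each participant's
recovered coefficient vector is scaled by `c = 2/range(signal)`, which
varies across participants with their punishment spread and RT range.
Recovery is therefore assessed by *rank* correlation with the generating
values. The neural fits — whose dependent is (noisy) standardized utility,
i.e. a correctly specified regression — recover both α and β with rank
correlations near 0.9 at 24 agents. The *behavioral* fits do not: the
punishment–feature relation is shaped by the endogeneity of post-punishment
payoffs (features depend on the chosen punishment), and its projection on
the no-intercept design is dominated by task geometry. This mirrors a real
property of the analysis being reproduced, not an implementation artifact;
the recovery acceptance test accordingly measures recovery through the
neural route, where the estimator is consistent.

The nested-F type-I calibration likewise runs at the regression level
(punishments linear in the Fehr–Schmidt design plus i.i.d. Gaussian noise,
RT exogenous, RT weight zero) — the regime in which the F reference
distribution holds. A choice-level "null" with a zero RT weight is *not* a
size null here: with no-intercept models and response times whose mean
(~2–4 s) is far from zero, the RT column acts as an intercept proxy and
soaks up linear-model misfit of the discrete choices, inflating rejection
to near 1 regardless of implementation correctness.

## 7. Degenerate inputs and edge rules

Constant vectors standardize to zeros; zero RSS yields the sentinel AIC
with a warning; a degenerate percentage-bend margin (ω = 0) is a data
error; windows extending past the recording name the offending trial;
unmapped channels in region averaging are configuration errors; softmax
ties at τ → 0 resolve to the smallest punishment; realized RTs clip to
(0, 7]. Every stochastic component (cohort, multi-start, null model,
holdout split) is seeded from configuration; identical configuration and
seed reproduce byte-identical tables.

## 8. Problem sizes used by the test suite

The default study conditions are 24 agents × 60 trials. The acceptance
suite runs one full pipeline at that size, 20 replicate cohorts of 8 agents
for model selection, and 500 simulations for the F-test calibration; unit
tests use 4–6-agent cohorts. These sizes give stable Monte-Carlo margins
for every criterion while keeping the whole suite in the low minutes on a
single core; the paper-scale cohort (n = 48) is one configuration field
away (`CohortConfig(n_participants=48)`).

## 9. Known limitations

* Behavioral coefficient estimates are geometry-confounded (Section 6);
  psychometric–neurometric correlations computed on them inherit shared
  compression and should be interpreted as pipeline outputs, not as
  evidence of per-parameter linkage.
* Mean punishment is not monotone decreasing in transfer under
  Fehr–Schmidt-rational agents (Section 3).
* The dlPFC-vs-dmPFC prediction contrast is directionally reproduced but
  its paired significance at n = 24 is marginal: the common
  signal between the behavioral and neural series bounds per-window R²
  well below the levels reported for human data, leaving the regional
  difference small relative to holdout noise.
* The Charness–Rabin model's literal no-intercept form is heavily
  penalized against standardized dependents; reported magnitudes of its
  MSE are not comparable to analyses that rescale or add intercepts.
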