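# Methods notes

## Task generative model

Each of the (by default) 320 trials has a patch stage and a value stage.
Two patches carry latent means that evolve as independent AR(1) processes,
`μ[t+1] = λ μ[t] + (1−λ) κ + ε`, with decay rate λ = 0.96, decay centre
κ = 1 point for the occupied patch and κ = 100 for the alternative, and
per-patch noise ε ~ N(0, 1.2²). Displayed patch values are drawn
N(μ, 3.5), clamped to [10, 90] points, and rounded to integers.

Two details are not fixed by the task description and were resolved as
package design choices:

* **Clamping site.** The clamp is applied to the *sampled values* only;
  the latent mean recursion is never clamped. This keeps the recursion an
  exact AR(1) process — its fixed point (κ) and stationary SD
  (`1.2/√(1−0.96²) ≈ 4.29`) are closed-form and are verified by tests.
* **Integer points.** Values, magnitudes, and costs are integers, matching
  the point semantics of the display; `integer_values=False` switches this
  off.

Travel costs persist across stay trials and are redrawn uniformly from
{5, 10, 15, 20} only after a leave. On a leave, the two patches swap
roles before the means advance, so the newly occupied patch starts
depleting from the former alternative's state.

The chosen patch's value V is split into two option magnitudes by drawing
the left share uniformly from the integers in [⌈0.1 V⌉, ⌊0.9 V⌋]
excluding V/2 — satisfying the ≥10% floor, the no-50/50 rule, and a
uniform ratio simultaneously. Probabilities come independently from
{0.1, …, 0.9}, and both options resolve by independent Bernoulli draws.

**Dominance trials and the flip rule.** A pair where one side is strictly
higher on both magnitude and probability (probability ties do not count —
strict dominance is required) is flagged; with the default
`replicate_side_bias_bug=True`, only *left*-dominant pairs are eligible
for the 50% magnitude flip, reproducing the original experiment's
right-side over-representation of dominance trials. The simulator reports
its empirical dominance share rather than asserting any particular value;
under these rules it comes out near one third of trials.

## Value models

Probability weighting `w(p) = p^γ/(p^γ + (1−p)^γ)^{1/γ}` and power
utility `u(m) = m^α` feed three combination families (additive,
multiplicative, hybrid) crossed with four distortion variants (EV: α=γ=1;
EU: γ=1; EVPW: α=1; SU: both free). The hybrid value is the
ω-normalized mixture of the additive and multiplicative forms scaled by
ω_sum = ω_m + ω_p + ω_mult; it degenerates when ω_m + ω_p = 0 and raises
an error there.

Choice probabilities are a unit-temperature softmax on V_right − V_left:
the ω weights absorb the inverse-temperature scale, and for the standard
fit the multiplicative weight is fixed at 6.62 (it trades off against α
and γ and does not recover well when free). Magnitudes are rescaled to
[1, 10] before fitting, by default with the participant's own min/max
(`rescale='global'` uses the task's theoretical range [1, 81] instead).

Fitting: uniform starting points within box bounds — α, γ ∈ [0.05, 5],
ω's ∈ [0, 50], wide enough to cover published estimates with margin —
refined by L-BFGS-B; the lowest NLL over starts wins; per-trial likelihoods
are floored at 1e−12. BIC = k·ln(n) + 2·NLL with ties broken toward fewer
parameters. All of this is deterministic given a seed.

## Synthetic agents and cohort

No generative model of patch choices or response times is part of the
original analysis approach; the agents here are minimal stand-ins and
should not be read as cognitive-process claims:

* P(leave) = logistic((PLA − θ_leave)/σ_leave). A monotone stochastic
  threshold is the weakest structure that makes the mean PLA a meaningful
  recovered quantity (verified: rank correlation of θ_leave with mean PLA
  > 0.9 across agents).
* Value choices use the multiplicative SU model with the agent's α, γ and
  fixed ω_mult. The agent maps raw magnitudes onto the fitting scale with
  the fixed global affine map; the fitter's default per-participant
  rescaling differs slightly, and recovery is robust to the mismatch.
* log RT = intercept + Σ β_k z_k + N(0, σ²), where z_k are the same
  session-z-scored design variables the analysis regressions use. RTs are
  generated in a second pass after the session because z-scores need the
  whole session. Default βs are small (|β| ≤ 0.3 log-units) with σ = 0.35,
  intercepts ≈ log 0.7 s (patch) and log 1.2 s (value). There is no
  drift-diffusion structure; RT realism is out of scope.

The cohort generator draws one multivariate-normal latent vector per
participant over [five regional E/I values; behavioural traits], with
planted (region, trait, r) correlations; the correlation matrix is checked
for positive semi-definiteness. Traits map to agent parameters through
monotone transforms (θ_leave = 15 + 6z; σ_leave, α, γ log-normal with
medians 5, 0.8, 0.8), which preserve the sign and approximate size of
planted correlations. Default planted effects are dACC↔θ_leave r = 0.5
and vmPFC↔α r = −0.46, mirroring the magnitudes the analysis is expected
to detect at N = 29; both are configuration, not constants.

E/I latents (means ≈ 4.0–4.4, SD 0.6 per region — plausible
creatine-referenced glutamate/GABA ratios) are converted to metabolite
rows by *inverting* the normalization chain: creatine ≈ 8 a.u., fixed
per-region GM/WM fractions (0.42–0.55 / 0.30–0.45), glutamate jittered
near 1.1 (normalized units), GABA solved so that the full
GM-and-creatine-normalized ratio reproduces the latent E/I exactly. This
guarantees the analysis-side normalization arithmetic is exercised, not
bypassed. Quality metrics are drawn inside the acceptance ranges by
default so QC behaviour is tested by perturbing them explicitly.

What passing tests on this cohort do *not* show: robustness to real MRS
noise structure (shared segmentation error, inter-regional metabolite
correlations), non-logistic leave policies, sequential dependencies in
choices, or RT distributions beyond the log-normal.

## Behavioural statistics

* PLA at leave trial t uses the *previous* trial's value difference
  (the values known at decision time) minus the current cost.
* The RM-ANOVA on per-cost-level median leave thresholds uses the plain
  one-way repeated-measures decomposition, F with df (3, 3(n−1)) after
  listwise deletion. Effect size is η² = SS_condition/SS_total *including*
  between-subject variance — the partial variant is about three times
  larger on typical data and inconsistent with the convention adopted
  here. The linear trend regresses each participant's four medians on the
  cost levels and t-tests the slopes.
* Regressions are per participant on z-scored predictors plus a constant;
  log RTs are natural logs z-scored within participant. The value-stage RT
  model replaces the signed EV difference by its absolute value. Logistic
  fits carry a tiny ridge (1e−6 on slopes, escalated tenfold to at most
  1e−2) so complete separation cannot abort a participant.
* Cohen's U3₁ is the fraction of per-participant coefficients strictly
  below zero (so strongly positive group effects give U3₁ ≈ 0).
* The `mean_logrt_value` decision variable is the participant's mean
  natural-log value-stage RT *without* z-scoring (a within-participant
  z-scored mean would be identically zero).
* No RT trimming is applied; non-positive RTs are rejected at ingest.

## Neurochemistry link

Quality control excludes a measurement if CRLB ≥ 20% for either
metabolite, FWHM ≥ 25 Hz, or SNR ≤ 8, and drops a participant from all
link analyses if any of their five regions fails. Normalization divides
GABA and glutamate by relative GM, creatine by relative GM+WM, and
expresses the metabolites relative to creatine; E/I = glutamate/GABA after
normalization (invariant to any common creatine or calibration scale).

The testing hierarchy per decision variable: (1) optionally gate on a
significant behavioural group effect; (2) one OLS GLM of the z-scored
decision variable on all five z-scored regional E/I values plus constant
(value-phase variables additionally carry the participant's no-brainer
share as a covariate of no interest); (3) if and only if a region is
significant (two-tailed p < 0.05; no multiple-comparison correction
across regions), compute the partial correlation by residualizing both
the decision variable and that region's E/I on the other four regions
(always with a constant); (4) transmitter-level partials residualize on
nine nuisance columns (the other transmitter in the target region, both
transmitters elsewhere), and the residual relationship is refit robustly
(bisquare, c = 4.685). Region contrasts test β_a − β_b with the GLM's
coefficient covariance. Pearson CIs use the Fisher z transform.

## Problem sizes and numerical choices

Simulation scales used by the shipped tests were chosen to give stable
statistics while keeping the default suite quick: the AR(1) check uses a
10⁶-step chain (2% tolerance); parameter recovery 100 agents × 320 trials
× 50 starts (threshold r ≥ 0.8 on α and γ; observed ≈ 0.95); model
recovery 50 participants; GLM calibration 1000 null cohorts and 500
planted-effect cohorts at N = 29. Optimizer tolerance in nesting checks is
1e−6 NLL units. All randomness flows from explicit seeds; per-participant
streams derive from the master seed via `SeedSequence`.

## Known limitations

* The agents' RT and leave models are conveniences for validating the
  analysis layer, not models of the underlying cognition.
* The hybrid family is fit only through the generic machinery; no claim
  is made about its identifiability on 320-trial sessions.
* The metabolite generator plants no correlations *between* regions or
  between GABA and glutamate within a region beyond those implied by the
  E/I construction.
* Deposited human data can be ingested through the column-mapping reader,
  but no human data ships with the package.
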