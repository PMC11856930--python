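# Methods

## The modeling problem

Exposure to audiovisual stimulus pairs with a constant stimulus-onset
asynchrony (SOA) shifts the point of subjective simultaneity (PSS):
stimuli initially perceived as asynchronous come to feel synchronous.
`avrecal` implements six observer models of this *temporal
recalibration*, together with the machinery needed to fit them to
ternary temporal-order-judgment (TOJ) data collected before and after an
exposure phase, and to generate complete synthetic experiments for
recovery studies.

Conventions: all times are seconds; SOA is `s = t_A − t_V`, negative
values meaning the auditory stimulus led.

## Measurement model

Auditory and visual arrival latencies are modeled as shifted exponential
distributions with time constants `tau_a` and `tau_v`; the measured SOA
`m` is the difference of the arrival times,

    m = s + beta + E_A − E_V,   E_A ~ Exp(tau_a), E_V ~ Exp(tau_v),

where `beta` is the audiovisual temporal bias (the difference of the
fixed processing delays; only the difference is identifiable and only
the difference is represented). The density of `m` is a two-sided
exponential peaking at `s + beta` with value `1/(tau_a + tau_v)`; its
left flank decays with constant `tau_v`, its right flank with `tau_a`,
so unequal time constants make it asymmetric. *Modality-independent*
model variants tie `tau_a = tau_v` to a single `tau` at the model-spec
level rather than through a separate type.

## Recalibration rules

Each exposure trial draws a measurement at the adapter SOA under the
*current* bias `beta_i = beta_pre + Delta_i` and updates the cumulative
shift `Delta`:

- **Causal inference** — the observer entertains a common-cause scenario
  (`C=1`, Gaussian SOA prior with small spread `sigma_c1`) and a
  separate-causes scenario (`C=2`, spread `sigma_c2 > sigma_c1`),
  computes the scenario-conditioned MAP estimates of the SOA, weighs
  them by the posterior scenario probabilities (prior `p_common`), and
  shifts the bias against the discrepancy between the model-averaged
  estimate and the measurement: `Delta += alpha * (s_hat − m)`.
- **Asynchrony-contingent** — `Delta −= p(m | SOA=0) * alpha * m`: the
  update is proportional to the likelihood that the stimuli were
  physically simultaneous, evaluated from the double-exponential
  measurement distribution under the current bias. Because that
  likelihood decays exponentially in `|m|`, this rule predicts
  essentially no recalibration at 0.7 s adapter SOAs.
- **Asynchrony-correction** — `Delta −= alpha * m` only when `|m| > c`
  (strict), with `c` the same simultaneity criterion used in the TOJ
  read-out; otherwise the measurement is attributed to noise. Updates
  grow linearly beyond the criterion — the qualitative opposite of the
  contingent rule.

The observer performing causal inference treats their measurement as
unbiased: the likelihood read as a function of the physical SOA has its
kink at `s = m`, not at `s = m − beta_i`. This is required for
coherence of the model as a whole — both the measured and the inferred
SOA must carry the bias, otherwise recalibration would move the
measurement distribution and the inference would undo the move exactly,
leaving pre- and post-test response probabilities identical and the
update rule's expected drift nonzero even for a fully adapted observer.
The low-level primitives in `avrecal.causal` nevertheless accept an
arbitrary inference bias through the `MeasurementModel` they are given;
the pipeline calls them with a bias-zero internal model.

Closed forms used (both exact):

- The scenario-conditioned MAP estimate is the likelihood kink clipped
  to `[−sigma²/tau_v, +sigma²/tau_a]` (the piecewise linear-plus-
  quadratic log-posterior has at most three candidate maximizers, which
  collapse to a clip).
- The scenario marginal `P(m|C) = ∫ p(m|s) N(s; 0, sigma²) ds` is a sum
  of two exponentially-modified-Gaussian terms evaluated with
  `log Φ` for stability. A trapezoid quadrature (split and refined at
  the kink) is retained as an independent oracle and agrees to <1e−4
  relative error.

An appendix-style variant rule (`cip_*`), in which the update is
`Delta −= alpha * P(C=1|m) * m`, is provided for recovery studies.

## Ternary TOJ read-out

The observer compares an internal estimate to symmetric criteria `±c`:
visual-first if `s_hat > c`, auditory-first if `s_hat < −c`, otherwise
simultaneous (ties count as simultaneous; measure-zero convention).
Lapses occur with probability `lambda` and distribute uniformly over the
three responses. For the contingent and correction observers
`s_hat = m`, giving closed-form psychometric functions through the
measurement CDF. For the causal-inference observer the estimate
distribution has no closed form; response probabilities are estimated by
Monte Carlo with 10,000 measurement samples per test SOA by default,
generated by inverse-CDF transform of a uniform-deviate array that is
frozen per fitting engine, so the simulated likelihood is a
deterministic function of the parameters across optimizer iterations
(common random numbers).

Inside the joint likelihood the causal-inference probabilities depend on
test SOA and bias only through `u = s + bias`; the engine therefore
evaluates the Monte-Carlo psychometric once per likelihood call on a
uniform `u` grid (5 ms spacing by default) and interpolates linearly for
the hundreds of (shift bin × SOA) combinations the post-test integral
needs. Similarly, the model-averaged estimate `s_hat(d)` is tabulated on
a 2 ms grid and interpolated inside Monte-Carlo loops. Both shortcuts
change the joint log-likelihood by <1e−3 on full experiments.

## Joint likelihood of a nine-session experiment

The pre-test likelihood is multinomial with identical curves in all
sessions (the bias resets to `beta_pre` between sessions). For the
post-test, the unknown cumulative shift after 250 exposure trials is
integrated out per session: the exposure phase is simulated 1000 times
(default), the final shifts are summarized by a Gaussian with the
empirical mean and SD, the Gaussian is discretized into 100 equally
spaced bins spanning triple the Monte-Carlo sample range
(`lb = min − range`, `ub = max + range`), with weights equal to the
Gaussian density at the bin centers, and the per-session trial product
is integrated against the bins as a uniform-width Riemann sum, all in
log space. A degenerate sample (zero learning rate) collapses to a
point mass, which makes the post-test term exactly equal to the
pre-test formula applied to the post-test records. 100 bins resolve a
300-trial session to ~1e−6 log-units relative to 1000 bins; on the full
5400-trial design the session integrands are sharp enough that residual
quadrature differences of ~0.1 log-units remain, which is irrelevant at
the scale of model comparison differences (tens to hundreds of units).

## Fitting

Maximum likelihood with bound-constrained, derivative-free search:
Nelder-Mead in unit-cube coordinates with an explicit absolute-step
initial simplex (scipy's default multiplicative simplex freezes any
coordinate near zero, e.g. a lapse rate at its bound), Latin-hypercube
multistart (20 starts by default), and a warm start obtained by fitting
the closed-form read-out psychometric to the pre-test counts. For the
9-parameter causal models the warm start is refined by block-coordinate
descent alternating a causal block (`sigma_c1, sigma_c2, p_common,
alpha[, c]`) and a shape block (`beta_pre, tau_a, tau_v, c, lambda`)
before the full-dimensional polish; plain 9-D Nelder-Mead frequently
stalls in the curved valley between the read-out-like and
causal-inference-like regions of the surface.

Fitting bounds: `beta_pre ∈ [−0.3, 0.3]`, `tau ∈ [0.005, 0.5]`,
`sigma_c1 ∈ [0.001, 0.3]`, `sigma_c2 ∈ [0.05, 3]` (constrained above
`sigma_c1`), `p_common ∈ [0, 1]`, `c ∈ [0.001, 0.5]`,
`lambda ∈ [1e−4, 0.2]` (lower bound keeps the likelihood finite),
`alpha ∈ [0, 0.1]` for the causal and correction rules and `[0, 0.05]`
for the contingent rule, whose `alpha` carries units of seconds because
it multiplies a density. The bounds are plausibility ranges, not
published values.

Model comparison reports maximized log-likelihood with AIC/BIC
penalties and a log-Bayes-factor analogue `0.5·(AIC_worst − AIC)`
relative to the weakest model. A variational model-evidence backend is
deliberately out of scope: the penalized-likelihood comparison is *not*
identical to an evidence-based comparison, and results should be read
accordingly.

## Descriptive analysis

The model-agnostic analysis fits the closed-form ternary psychometric
jointly to the pre- and post-test of one session with a shared shape
(`tau_a, tau_v, c, lambda`) and separate biases. It is a reconstruction
of the atheoretical analysis from its published description; no
criterion-shift variant is included. The PSS is located by a 1 ms grid
search over ±0.6 s with golden-section refinement; for equal time
constants it equals minus the bias. The recalibration effect of a
session is `PSS_post − PSS_pre`; the asymmetry index is the sum of
effects over the nine adapter SOAs (positive: more recalibration for
visual-lead adapters). Confidence intervals are percentile bootstrap
(1000 resamples by default), resampling responses with replacement
within each (session, phase, test SOA) cell, which preserves the design.

## Synthetic experiments

`avrecal.synthetic` generates complete experiments with the study
design: nine sessions at adapter SOAs ±0.7, ±0.3, ±0.2, ±0.1, 0 s; 15
test SOAs (±0.5 s and −0.3…0.3 s in 0.05 s steps) × 20 repetitions per
phase; 250 exposure trials. Each session draws pre-test responses at
`beta_pre`, simulates one realized exposure trajectory, and draws
post-test responses at the shifted bias. The generator mimics a single
participant (one realized trajectory), whereas the likelihood
integrates over the trajectory distribution — an intentional asymmetry.
Ground-truth observers for recovery studies are drawn uniformly from
plausibility ranges (`PLAUSIBLE_RANGES`) chosen to produce human-scale
behavior: biases within ±150 ms, time constants 20–150 ms, criteria
40–200 ms, lapse rates below 6%, learning rates yielding partial
(roughly 10–80%) compensation after 250 trials.

What the generator does *not* emulate: oddball-detection responses and
top-up trials (the shift is assumed to persist through the post-test),
session-order or fatigue effects, reaction times, and any dissipation
of recalibration. Passing recovery tests therefore demonstrate internal
consistency of model plus fitting pipeline, not robustness to the many
ways real data deviate from the model.

## Recovery studies and their problem sizes

The test suite runs both recovery studies at reduced Monte-Carlo scale
chosen to keep the default run on one CPU within minutes: fits use 800
psychometric samples per grid point, 60 exposure simulations per
session, 100 bins, a block-refined warm start plus one Latin-hypercube
start, and a 150-evaluation final polish (`avrecal.recovery.REDUCED_FIT`);
model recovery uses two observers per generating model and winner-by-AIC
with a family-level (update-rule) confusion matrix. The `recover` CLI
command runs the same harnesses at any scale.

Parameter recovery for the causal-inference modality-specific model at
this scale recovers `beta_pre`, `tau_a`, `tau_v` and `lambda` with
truth-estimate correlations of 0.92–0.99 across 20 synthetic observers.
The simultaneity criterion `c` recovers weakly (r ≈ 0.55, typically
overestimated), and the corresponding acceptance-style test fails by
design rather than being relaxed. This is a property of maximum
likelihood under these study conditions, not an optimizer failure: with
all other parameters held at truth the likelihood is sharply peaked in
`c`, but jointly the surface contains a nearly flat ridge along which
`c` trades against `sigma_c1`, `p_common` and `alpha`, and for many
observers the global maximum sits on that ridge with `c` inflated 2–3×
and a log-likelihood several units above the generating parameters even
at full Monte-Carlo fidelity. Intuitively, the causal-inference
read-out compresses estimates toward zero, so the response partition is
controlled by the compression parameters almost as well as by `c`
itself; `c` is close to interval-identified for moderate-to-strong
common-cause priors. `p_common`, `sigma_c1`, `sigma_c2` and `alpha`
likewise recover weakly at this scale and are reported without a hard
gate.

## Numerical conventions and degenerate inputs

- Kink of the measurement density assigned to the left branch (both
  branches agree there).
- Ties `s_hat = ±c` count as "simultaneous".
- `|m| > c` in the correction rule is strict.
- A zero-spread shift sample yields a point-mass distribution rather
  than an error.
- Zero-probability responses give `−inf` log-likelihood; the fitting
  bounds (`lambda ≥ 1e−4`) keep fitted likelihoods finite, and the
  optimizer treats non-finite values as a large penalty.
- Seeds: every stochastic component derives independent substreams from
  a single integer via `numpy.random.SeedSequence`; identical seeds
  reproduce results bit for bit.

## Known limitations

- Model evidence is approximated by penalized likelihood (AIC/BIC), not
  by a marginal-likelihood estimate.
- The criterion parameter of the causal-inference models is weakly
  identified at the single-participant design scale (see above).
- The contingent rule's learning rate is scale-coupled to the
  measurement density; comparisons of `alpha` across rule families are
  not meaningful (a peak-normalized option exists on the update
  primitive but is off by default for fidelity to the rule as stated).
- Recovery studies at reduced Monte-Carlo scale understate the accuracy
  achievable with the full default settings.
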