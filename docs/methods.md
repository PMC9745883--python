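# Methods

## The two observer models

`depthcue` implements two rival accounts of how the visual system combines
depth cues (texture, shading, binocular disparity, motion parallax) into a
single perceived depth.

**Vector Sum (Intrinsic Constraint).** Each cue module maps distal depth
*z* (cm) linearly and *deterministically* to an internal estimate
ẑᵢ = kᵢ·z, where the slope kᵢ is the *cue strength* (dimensionless,
perceived-depth units per cm; a weak texture gives a shallow slope, not a
noisy output). The combined percept is the Euclidean norm of the single-cue
estimates,

    ẑ_C = sqrt(Σᵢ (kᵢ z)²) = z · sqrt(Σᵢ kᵢ²) = K·z,

so the combined strength K is itself the norm of the single strengths and the
combined percept always exceeds every single-cue percept (combined-cue
overestimation). Trial-to-trial variability in a two-interval forced-choice
(2AFC) task comes only from task noise: holding the first percept in memory
smears it by Gaussian noise of s.d. σ_M (perceived-depth units). The just
noticeable difference (JND) is the distal increment whose perceived change
overcomes that noise, JND = σ_M / K — it depends on the *comparison*
stimulus only. Two consequences drive the package's signature analyses:

* in a crossed standard/comparison design the psychometric spread depends only
  on the comparison class while the PSE sits at (K_s/K_c)·z_s;
* in cross-cue matching, the match point is z₂ = (k₁/k₂)z₁, and since
  kᵢ ∝ 1/JNDᵢ, it is predictable from discrimination data alone:
  z₂ = (JND₂/JND₁)z₁.

**MLE (inverse-variance weighting).** Each cue yields an unbiased noisy
estimate ẑᵢ ~ N(z, σᵢ²) (σᵢ in cm); cues are combined as the weighted
average with wᵢ ∝ 1/σᵢ², giving an unbiased combined estimate with
1/σ_C² = Σ 1/σᵢ². All PSEs are veridical (PSE = z_s), the 2AFC spread pools
standard and comparison noise (sqrt(σ_Cs² + σ_Cc²)), and the matching point
is z₂ = z₁.

The two models share one prediction — the combined JND obeys
1/JND_C² = Σ 1/JNDᵢ² — which under the Vector Sum account is an identity of
strength summation (K_C = sqrt(Σkᵢ²), JND = σ_M/K), not of noise pooling.
The package asserts this identity exactly.

Prior knowledge over depth is deliberately ignored in both models (the
likelihood-only simplification), and the package does not model how strengths
arise from images.

## Identifiability and gauge

2AFC choice probabilities under the Vector Sum observer depend only on
(K_c z_c − K_s z_s)/σ_M, so only strength-to-noise ratios are identifiable.
All inference fixes the gauge **σ_M = 1**; fitted strengths are reported in
that gauge and only their ratios are meaningful. The MLE observer's σ values
carry physical units (cm) and a crossed design identifies each class σ
outright, so none is held fixed.

## Generative trial model

Interval order is randomized 50/50 per trial. For the Vector Sum observer the
memory noise perturbs the first-interval percept only; because the decision
is a difference, this is equivalent to a single N(0, σ_M²) draw on the
difference, which the vectorized simulator exploits. The Vector Sum percept
itself carries exactly zero stimulus-independent noise (repeated
presentations are bit-identical); any "negligible" percept noise is absorbed
into σ_M. All noise is Gaussian throughout. Generative observers have no
lapses; a lapse rate exists only as an optional fitting parameter.

Randomness: every simulator derives its stream from a root seed plus a
stable (CRC-32) hash of condition labels, so adding or reordering conditions
never changes the draws of existing ones.

## Task simulators

* **Constant stimuli**: 7 comparison levels at predicted PSE ± {0, 0.5, 1,
  1.5}×JND, 40 trials/level by default — placed so psychometric fits are
  well conditioned for either observer; fully configurable. Levels are
  clipped away from zero depth.
* **Staircase**: transformed 1-up-2-down (converges on the 70.7% point,
  PSE + 0.545·JND), step halved after each of the first 3 reversals, stop at
  12 reversals or 400 trials; hitting the cap flags the run incomplete
  rather than raising.
* **Matching**: simulated as direct percept equating plus Gaussian
  adjustment noise (default s.d. 0.05·z₁ in distal cm) rather than a nested
  staircase; for the MLE observer each settlement equates two fresh noisy
  estimates, giving unbiased matches with spread sqrt(σ_C1² + σ_C2²).
* **Magnitude estimation**: judged depth is the percept plus additive
  Gaussian response noise in perceived units.

## Psychometric fitting

The 2AFC curve is a cumulative Gaussian P = λ/2 + (1−λ)Φ((z−pse)/σ), fit by
maximum Bernoulli likelihood with bounded L-BFGS-B and five jittered starts
around a probit-regression (GLM) initializer; the best log-likelihood wins,
ties broken by smaller σ. The JND is reported as σ — the depth increment
from the PSE to the 84.1% point (Φ(1)); the 84% criterion is adopted for all
analyses. The lapse λ is fixed at 0 by default and optionally fit in
[0, 0.06] (a conventional bound; the generative models never lapse).

Degenerate data are flagged, not silently fit: perfectly separated responses
(zero-deviance fits, σ at its lower bound) and depth-flat response rates
(σ at its upper bound, PSE unidentifiable) return `converged=False` with
named flags. Bootstrap CIs are percentile intervals over within-level
resampling; replicates refit from the full-data estimate, and a refit failure
rate above 20% raises rather than returning unreliable intervals.

## Predictions and model comparison

Closed-form PSE/JND tables for crossed designs follow the table above. The
combined-slope prediction for magnitude estimation is the norm of the
single-cue slopes; its confidence band is a parametric bootstrap over the
single-cue slope sampling distributions (draws below zero are clipped at 0
and counted; >5% clipping sets a warning flag). The band quantifies
uncertainty in the *predicted* combined strength; when compared against a
measured combined slope, that measurement brings its own sampling error on
top of the band.

`fit_observer_model` maximizes the joint Bernoulli likelihood of all
conditions at once using each model's closed-form choice probabilities
(Nelder-Mead on log-parameters from three scaled starts, on per-cell
aggregated counts). `compare_models` adjudicates by AIC with one parameter
per stimulus class for either model; ties are reported explicitly and tables
under 100 trials are flagged low-power. This likelihood-based adjudication
operationalizes what is otherwise a qualitative slope/PSE pattern contrast;
it is a design choice of this package, not a replication of any particular
study's statistics.

## Synthetic scenarios: what they do and do not emulate

The four scenario generators reproduce the *designs* of the motivating
experiments — crossed single-cue discrimination, single-vs-combined
crossing, matching plus discrimination, and two-distance magnitude
estimation — with invented default parameters (e.g. k_strong = 1.0,
k_weak = 0.5, σ_M = 1, z_s = 10 cm; "40 cm"/"80 cm" are labels on strength
sets, not geometry) chosen once so each qualitative signature is detectable
at the default trial counts. They emulate ideal observers exactly obeying
one model: no lapses, no learning or adaptation, no inter-observer
variability, no session effects, no real image rendering. Passing tests
therefore demonstrate internal consistency and statistical power of the
analysis chain under each model's assumptions — not that human data obey
either model.

## Problem sizes and numerical tolerances

Monte-Carlo checks use 20k–50k trials per point (choice-rate laws to within
3–4 binomial standard errors). Signature and recovery analyses use ~5,000
trials per condition with 200-replicate bootstrap CIs; selection-power and
coverage simulations use 100–200 replicate experiments at the default design
sizes. The combined-JND identity is asserted to 1e-10 relative; closed-form
examples to standard floating-point tolerance. These sizes are the package's
own verification conditions and are all configurable at call sites.

## Known limitations

* Axis rescaling of the cue-estimate space by nuisance variability (the
  mechanism that would make the norm maximally nuisance-invariant) is not
  modelled; the robustness property (a relative perturbation of one
  component moves the norm by strictly less) is asserted as stated, and an
  optional strength-jitter hook is the only nuisance machinery.
* σ_M and σ_N are treated as a single task-noise symbol.
* Cumulative Gaussian is the only psychometric link; no Bayesian fitting,
  no deviance-based goodness-of-fit beyond the log-likelihood.
* The staircase rule is fixed to 1-up-2-down; other transformed rules are
  out of scope.
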