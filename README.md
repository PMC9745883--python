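# depthcue

Observer models, task simulators and inference tools for **depth-cue
integration psychophysics**: the deterministic **Vector Sum** model of
Intrinsic Constraint theory versus the classical **MLE**
(inverse-variance-weighted) model, as executable trial-level observers.

It is written for vision scientists who want to simulate, fit and compare
these two accounts on 2AFC discrimination, cross-cue matching and magnitude
estimation designs — and for anyone who needs a clean cumulative-Gaussian
psychometric fitter with bootstrap CIs along the way.

## The models in brief

A cue *i* (texture, disparity, motion, shading…) maps distal depth *z* (cm)
to an internal estimate:

* **Vector Sum**: ẑᵢ = kᵢ·z deterministically, where kᵢ is the *cue
  strength* (slope). The combined percept is the norm
  ẑ_C = z·√(Σkᵢ²) ≡ K·z, so combined stimuli always look deeper than
  single-cue ones. 2AFC variability comes only from task (memory) noise σ_M,
  hence **JND = σ_M/K**: the spread of a psychometric function depends only
  on the comparison stimulus, PSEs sit at (K_s/K_c)·z_s, and a cross-cue
  match obeys **z₂ = (JND₂/JND₁)·z₁**.
* **MLE**: ẑᵢ ~ N(z, σᵢ²), combined by weights wᵢ ∝ 1/σᵢ² with
  1/σ_C² = Σ1/σᵢ². PSEs are veridical everywhere and the 2AFC spread pools
  both stimuli's noise, √(σ_Cs² + σ_Cc²).

Both predict the same combined-JND law 1/JND_C² = Σ1/JNDᵢ² — for entirely
different reasons — and the package exploits the designs where they diverge.
See `docs/methods.md` for the full account.

## Worked example

Simulate the crossed strong/weak-texture discrimination design (strengths
1.0 and 0.5, σ_M = 1, standard at 10 cm, 280 trials/condition) under each
observer and fit psychometric functions per condition:

```python
from depthcue import (ObserverKind, ScenarioSpec, default_parameters,
                      generate_scenario, fit_psychometric)

for observer in (ObserverKind.VECSUM, ObserverKind.MLE):
    spec = ScenarioSpec("crossed-single-cue",
                        default_parameters("crossed-single-cue"), seed=7)
    bundle = generate_scenario(spec, observer)
    print(observer.value.upper())
    for cid, trials in sorted(bundle.tables.items()):
        fit = fit_psychometric(trials)
        print(f"  {cid}: PSE = {fit.pse:5.2f} cm   JND = {fit.sigma:4.2f} cm")
```

prints

```
VECSUM
  ST1_CT1: PSE = 10.05 cm   JND = 0.79 cm
  ST1_CT2: PSE = 20.13 cm   JND = 1.69 cm
  ST2_CT1: PSE =  5.13 cm   JND = 0.99 cm
  ST2_CT2: PSE = 10.48 cm   JND = 2.28 cm
MLE
  ST1_CT1: PSE = 10.06 cm   JND = 1.40 cm
  ST1_CT2: PSE = 10.54 cm   JND = 2.43 cm
  ST2_CT1: PSE = 10.28 cm   JND = 2.08 cm
  ST2_CT2: PSE =  9.94 cm   JND = 3.08 cm
```

Read `SxCy` as "standard class x, comparison class y". The Vector Sum rows
sharing a comparison share their JND (≈1 cm for the strong comparison, ≈2 cm
for the weak one) and the cross-class PSEs shift by the strength ratio
(10→20 or 10→5 cm); the MLE rows keep every PSE at the 10 cm standard while
the JND grows whenever either stimulus is weak. These are the two models'
distinguishing fingerprints.

The `examples/` directory walks through each capability the same way:
combination rules, the crossed signature, the matching law
(`z₂ = (JND₂/JND₁)z₁`, predicting a 20 cm match for a 10 cm standard from
discrimination data alone), combined-cue overestimation with its bootstrap
band, and AIC model comparison (`compare_models` recovers the generating
observer decisively at default sizes).

## Command line

A thin CLI wraps the library:

```bash
depthcue simulate --scenario crossed-single-cue --observer vecsum --seed 7 -o out/
depthcue fit out/trials_ST1_CT1.csv --boot 500 --seed 3 -o fits/
depthcue predict --bundle out/ -o pred/
depthcue compare out/trials_*.csv
depthcue recover --observer vecsum --seed 11 --n-reps 20 -o recover.json
```

All commands are reproducible from (config, seed); bundles carry a manifest
with parameters and SHA-256 checksums.

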