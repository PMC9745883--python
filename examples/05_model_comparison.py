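"""Which observer generated this crossed-design dataset?

Both observer models are fit to the full multi-condition trial table by
maximum likelihood over their closed-form choice probabilities, and AIC
adjudicates. On data from either generator at the default design size the
generating model wins decisively.
"""

import pandas as pd

from depthcue import (
    ObserverKind,
    ScenarioSpec,
    compare_models,
    default_parameters,
    generate_scenario,
)

for generator in ObserverKind:
    spec = ScenarioSpec("crossed-single-cue", default_parameters("crossed-single-cue"), seed=21)
    bundle = generate_scenario(spec, generator)
    trials = pd.concat(bundle.tables.values(), ignore_index=True)
    result = compare_models(trials)
    delta = abs(result.aic["vecsum"] - result.aic["mle"])
    print(f"generated by {generator.value:6s} -> selected {result.selected:6s} "
          f"(dAIC = {delta:7.1f}; fitted params "
          f"{ {k: round(v, 3) for k, v in result.fits[result.selected].params.items()} })")
# the recovered Vector Sum strengths sit near the generating k = 1.0 / 0.5
# (in the sigma_M = 1 gauge), and the MLE fit recovers the noise ratio.
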