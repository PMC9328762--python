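"""Condition performance on target-location history and measure the
rise-point vs. chance-level relationship.

Guesses tend to go toward the previous trial's target.  Splitting anti
trials into target repeats (AA) and switches (AB) shifts the chance
plateau above/below 0.5; the rise point moves with it.
"""

from urgentsaccade.history import conditioned_analysis, rise_vs_chance_slope
from urgentsaccade.synth import GeneratorSpec, anti_truth, generate

spec = GeneratorSpec(true_curve=anti_truth(), task="anti", n_trials=40_000,
                     seed=13, history_bias_per_repeat=0.14,
                     history_bias_cap=0.14)
trials = generate(spec)
rep, sw = conditioned_analysis(trials, "anti", depth=1)

print(f"{rep.pattern}: chance {rep.chance_level:.2f}, "
      f"rise point {rep.rise_point_ms:.0f} ms ({len(rep.trials)} trials)")
print(f"{sw.pattern}: chance {sw.chance_level:.2f}, "
      f"rise point {sw.rise_point_ms:.0f} ms ({len(sw.trials)} trials)")

# the worked example with published one-back values:
slope = rise_vs_chance_slope({0.36: 154.0, 0.64: 143.0})
print(f"rise-point drop per full chance unit: {slope:.1f} ms "
      f"({0.1 * slope:.1f} ms per 0.1 of chance)")
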