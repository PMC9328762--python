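"""Build a tachometric curve from trials and fit the psychometric sigmoid.

Generates ground-truth prosaccade trials whose accuracy rises from chance
(0.5) to 1.0 with rise point C = 100 ms, then recovers C from the binned
curve (21 ms bins stepped every 1 ms, exact binomial CIs).
"""

from urgentsaccade import fit_pro
from urgentsaccade.synth import GeneratorSpec, generate, pro_truth
from urgentsaccade.tachometric import compute
from urgentsaccade.trials import filter_urgent

spec = GeneratorSpec(true_curve=pro_truth(A=1.0, B=0.5, C=100.0, D=10.0),
                     n_trials=20_000, seed=2)
trials = filter_urgent(generate(spec))
curve = compute(trials)
fit = fit_pro(curve)

print(f"{len(trials)} urgent trials, "
      f"{int(curve.defined().sum())} defined grid points")
print(f"fitted rise point C = {fit.C:.1f} ms (truth 100), "
      f"asymptote A = {fit.A:.3f}, MAE = {fit.mae:.4f}")
# The rise point is the rPT at which accuracy is halfway between chance
# and asymptote: how much cue-viewing time the choice needs to become
# informed rather than guessed.
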