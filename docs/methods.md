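# Methods

## Task geometry and trial records

A trial is described by its task rule (pro: look toward the cue; anti:
look away), block type (single-task or interleaved), cue luminance, gap
(go signal to cue onset, ms; the design set is −200, −100, 0, 75, 100,
125, 150, 175, 200, 250, 350), cue side (±8°, encoded L/R), the response
side, and the reaction time from the go signal to saccade onset.  Derived
per trial: the target side implied by the task rule, the raw processing
time rPT = RT − gap (negative when the saccade precedes cue onset — a pure
guess), and correctness of the first saccade.  Completed trials are scored
even when RT exceeds the 425 ms deadline; trials with no recorded choice
carry an `aborted` flag instead of being dropped, so abort rates remain
computable.  All curve analyses use urgent trials only (gap ≥ 0, not
aborted).

Raw gaze traces and saccade detection (velocity thresholding), and any
exclusion of primarily vertical saccades, are upstream of this package:
its inputs are trial-level tables, and the synthetic generator never
produces such trials.

## The race model

Each trial runs two accumulators, one per saccade direction, integrated
with explicit 1 ms Euler steps; rates are piecewise constant between
modulation events, so activity traces are piecewise linear.  Buildup
rates are drawn from a bivariate normal (mean `build_mean`, sd
`build_sd`, correlation `build_corr`; negative draws floored at 0).
Ramping begins `go_latency_ms` after the go signal (normal jitter,
`go_jitter_sd_ms`).  The first plan whose activity reaches `threshold`
wins; the saccade lands `efferent_delay_ms` later.  If both plans cross in
the same 1 ms step the larger overshoot wins; an exact tie is resolved
uniformly at random (a measure-zero event that must still be defined).

Cue onset triggers the exogenous response interval (ERI) after
`exo_latency_ms` (default 80 ms), lasting `eri_duration_ms` (default
25 ms).  Within the ERI the cue-directed plan is halted for `halt_ms`,
then its rate grows by `exo_accel` per ms; the opposite plan is halted
throughout.  The rate boost acquired during the ERI persists afterwards.
From the end of the ERI the target plan's rate grows by `endo_accel` per
ms and the distracter plan's rate shrinks by `endo_decel` per ms; a rate
may go negative (the plan decays) but activity is floored at 0.  The CAS
(anti) and CPS (pro) variants differ *only* in which plan the endogenous
terms treat as the target, so with a common seed the two models produce
bitwise-identical traces through the end of the ERI.

The lateral bias `b ∈ [−0.5, 0.5]` assigns the larger of the two drawn
rates to the cue-directed plan with probability 0.5 + b (b = 0.1 → 60%).
The bias is defined relative to the cue, matching the biased-assignment
rule of the original simulations; consequently left/right labels are
exchangeable (left-cue and right-cue trials are statistically identical)
while negating b genuinely changes performance.

Trials that never cross within `timeout_cap_ms` (2000 ms) are flagged as
timeouts, excluded from curves.

### Default parameters

`data/default_params.toml` (activity units are arbitrary; only ratios to
`threshold` = 1000 matter): build rates 4.5 ± 2.8 units/ms (ρ = 0.1),
go latency 60 ± 15 ms, efferent delay 10 ms, ERI at 80 ms for 25 ms with a
10 ms halt, exo_accel 1.2, endo_accel 0.15, endo_decel 0.4 units/ms².
These were calibrated once, as a package design choice, to the published
qualitative shape of pooled high-luminance performance: the CAS curve
drops below 0.2 inside rPT 90–140 ms and recovers above 0.9 past 220 ms,
while the CPS curve stays at or above chance everywhere and rises early.
The within-ERI time course (halt length, acceleration shape) is not
uniquely constrained by the behavioral shape; the halt duration and the
linear-in-time acceleration are free modeling choices, as is flooring
negative rate draws at zero rather than resampling.  The low-luminance
preset delays the ERI by 32 ms and scales exo_accel by 0.6, reproducing
the rightward shift of capture produced by dim cues.

## Tachometric curves

Trials are grouped into bins of width 21 ms whose integer-ms centers step
every 1 ms; the bin interval is half-open [c − w/2, c + w/2) so that
stepping by the bin width partitions the data with no double counting.
Each bin with at least `min_bin_n` (default 10) trials contributes a
fraction correct and an exact Clopper–Pearson 95% CI (the conservative
choice among binomial CI flavors, well defined at 0 and 1); sparser bins
are left undefined rather than extrapolated.  Curve inversion for
pro-vs-anti comparison is exact: f → 1 − f with CI bounds swapped.

## Psychometric fits

Prosaccade curves: increasing sigmoid s(x) = B + (A − B)/(1 + e^{−(x−C)/D});
C is the rise point (halfway between chance B and asymptote A).
Antisaccade curves: v(x) = max(sL, sR, 0) with a decreasing limb sL
(plateau AL, shared minimum BLR, drop point CL, scale DL) and an
increasing limb sR (asymptote AR, rise point CR, scale DR).  Parameters
minimize the mean absolute error over the curve's defined grid points,
equally weighted, with no interpolation through gaps.  Because MAE is
non-smooth, the optimizer is a derivative-free simplex (Nelder–Mead,
xatol 1e-4, fatol 1e-7) restarted 10 times from jittered moment-based
guesses; D, DL, DR are log-parameterized to stay positive, and ordering/
range constraints enter as penalties.  Chance parameters (B, AL) are
frozen at 0.5 except in history-conditioned analyses, where the guessing
plateau is the quantity of interest and they are freed.  A fitted dynamic
range below 0.05 flags the fit degenerate: its characteristic points are
NaN rather than meaningless numbers.

## Time-shift comparison

Given a reference curve f₁ and test curve f₂, the alignment minimizes
E = ⟨|g(Δb + f₂(x + Δx)) − f₁(x)|⟩ over a stated rPT window ([55, 105] ms
for the pro-vs-anti comparison, after inverting the pro curve).  Δx is
searched exhaustively on a 1 ms grid over ±60 ms (the bounds are a package
choice) with an inner simplex over (Δb, g) per shift, then refined to
sub-ms by a parabola through the three grid errors around the minimum.
Window points where either curve is undefined are dropped, never imputed;
at least 30 valid points are required.  Because a near-zero or extreme
gain can spuriously align nearly flat segments, the inner objective
penalizes g outside [0.2, 5] and |Δb| > 0.6 — Δb and g are meant to absorb
small vertical offsets, not to re-scale the curve wholesale.  CIs for Δx
come from the bootstrap, not from propagating binomial CIs through the
alignment.

## Resampling

Bootstrap: trials are resampled with replacement at the trial level
(participant-stratified resampling is available but off by default,
matching pooled-trial analyses), the statistic recomputed per iterate,
and the 2.5/97.5 percentiles reported.  One master seed spawns one
independent substream per iteration, so the first k iterates are
identical whatever the total iteration count.  Iterates that raise or
return NaN are counted and excluded; above 20% failures the result is
flagged unreliable.  Permutation test for correlations: Pearson ρ with a
two-sided p equal to the add-one-smoothed fraction of random pairings
with |ρ_perm| ≥ |ρ_obs| (one- vs two-sidedness is not forced by the
method; two-sided is the conservative default).

## History conditioning and motor biases

History is defined on prior **target** locations (not cue locations nor
choices), within participant and block type in session order; patterns at
depth d require the previous d targets to agree (AA/AB at depth 1, AAA/AAB
at depth 2, …).  Trials with insufficient, mixed, or abort-interrupted
history stay unlabeled, so labeling exactly partitions the table per
depth.  Each condition gets its own curve and a free-chance fit; the
rise-point-vs-chance relationship is summarized as the drop in rise point
per full 0→1 chance increase — exact two-point arithmetic, or a
least-absolute-deviation line for more points.

The model-side counterpart sweeps the race bias over both signs,
simulating sessions per bias and fitting with free chance.  The free
double-sigmoid's minimum trades off against its rise point, which makes a
single fit noisy by a few ms; the sweep therefore averages a configurable
number of replicate sessions per bias (the structural tests use 5 biases
spanning ±0.3, 3 × 30 000 trials each).

## Synthetic ground-truth generator

Independent of the race model, the generator draws each trial's
correctness directly from a configurable true accuracy function of rPT
(sigmoid or drop-recover form), so recovery of C, CL, CR, injected time
shifts, and chance offsets can be verified against known truth.  RTs come
from a truncated normal (mean 230 ms, sd 60, support [80, 600] ms — chosen
so rPT mass spans guessing through asymptotic regimes over the task's gap
set); gaps and cue sides are sampled per trial; an optional flat abort
rate emulates fixation breaks.  Guess-regime bias (toward the previous
target, cumulative in run length with a cap, and/or a fixed side
preference) applies only where the true curve sits at its own baseline,
emulating biased guessing without distorting the informed regime.  What
the generator does **not** emulate: RT dependence on gap or urgency,
sequential RT effects, vertical saccades, and any coupling between
correctness and RT beyond the true curve — so passing recovery tests
demonstrates correctness of the analysis machinery, not realism of every
feature of human data.

## Numerical and testing notes

Structural model tests use 30 000–50 000 simulated trials per curve and
the bias sweep sizes above; bootstrap calibration uses 500 replicate
experiments at 250 iterations.  These sizes keep Monte-Carlo noise well
below the asserted margins while the full suite runs in minutes.
Determinism is explicit everywhere: every simulation, generator, and
resampling call takes a seed or Generator, and the CLI writes a manifest
(arguments, seed, version) next to each output.

Known limitations: model parameters are a shape calibration, not a fit to
any participant; fitting race parameters to empirical data is out of
scope.  The free-chance anti fit is weakly identified when the capture
dip is shallow (extreme biases) — flagged via the degenerate mechanism
rather than silently reported.  The shift analysis assumes the two curves
have similar shapes within the window; it is not a warping method.
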