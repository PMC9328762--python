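"""Synthetic trial tables with known ground truth.

This generator is independent of the race model: it draws each trial's
correctness directly from a configurable true accuracy-vs-rPT function, so
every downstream stage (binning, fitting, shift analysis, resampling,
history conditioning) can be validated against known parameters without
any recorded data.

It emulates the urgent-task design: gaps from {−200 … 350} ms sampled per
trial, cue at ±8° (left/right, 50/50), a 425 ms response deadline (trials
beyond it are still scored), reaction times from a truncated normal, and a
guessing regime at short rPT where choices may be biased toward the
previous trial's target location (cumulative with consecutive repeats).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import trials as trials_mod
from .fitting import anti_double_sigmoid, pro_sigmoid
from .race import DEFAULT_GAP_SET_MS

__all__ = ["GeneratorSpec", "generate", "pro_truth", "anti_truth"]


def pro_truth(A=1.0, B=0.5, C=100.0, D=10.0) -> Callable:
    """True accuracy function with the increasing-sigmoid (prosaccade) shape."""
    return lambda x: pro_sigmoid(x, A, B, C, D)


def anti_truth(AL=0.5, AR=1.0, BLR=0.05, CL=95.0, CR=150.0, DL=5.0, DR=10.0) -> Callable:
    """True accuracy function with the drop-recover (antisaccade) shape."""
    return lambda x: anti_double_sigmoid(x, AL, AR, BLR, CL, CR, DL, DR)


@dataclass
class GeneratorSpec:
    """Configuration of the ground-truth trial generator.

    The default RT model (truncated normal, mean 230 ms, sd 60 ms, support
    [80, 600] ms) spreads rPT mass from the guessing regime through the
    asymptotic regime given the task's gap set.
    """

    true_curve: Callable = field(default_factory=pro_truth)
    task: str = "pro"                      # "pro" | "anti" | "interleaved"
    n_trials: int = 10_000
    seed: int = 0
    gap_set: tuple = DEFAULT_GAP_SET_MS
    gap_probs: tuple | None = None         # uniform when None
    rt_mean_ms: float = 230.0
    rt_sd_ms: float = 60.0
    rt_range_ms: tuple = (80.0, 600.0)
    # guessing-regime biases -------------------------------------------------
    history_bias_per_repeat: float = 0.0   # added per consecutive target repeat
    history_bias_cap: float = 0.3
    lateral_bias: float = 0.0              # fixed bias toward preferred_side
    preferred_side: str = "L"
    guess_tol: float = 0.01                # |p - baseline| below which a trial
                                           # counts as a pure guess
    abort_rate: float = 0.0
    participant_id: str = "synth"
    block: str = "single_task"
    luminance: str = "high"

    def validate(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if len(self.gap_set) == 0:
            raise ValueError("gap_set must be nonempty")
        if self.gap_probs is not None:
            p = np.asarray(self.gap_probs, float)
            if len(p) != len(self.gap_set) or not np.isclose(p.sum(), 1.0):
                raise ValueError("gap_probs must match gap_set and sum to 1")
        probe = np.asarray(self.true_curve(np.linspace(-300, 600, 181)), float)
        if np.any(probe < -1e-9) or np.any(probe > 1 + 1e-9):
            raise ValueError("true_curve must map rPT into [0, 1]")
        if not 0 <= self.abort_rate < 1:
            raise ValueError("abort_rate must be in [0, 1)")


def generate(spec: GeneratorSpec) -> pd.DataFrame:
    """Generate a scored trial table according to ``spec``.

    Per trial: sample gap and cue side, derive the target side from the
    task rule, sample RT, set rPT = RT − gap, then draw correctness as a
    Bernoulli with p = true_curve(rPT).  In the guessing regime (where the
    true curve sits at its own baseline) p is offset toward the previous
    target location and/or a fixed preferred side; the choice side follows
    from correctness and the target side.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_trials

    gaps = rng.choice(np.asarray(spec.gap_set, float), size=n, p=spec.gap_probs)
    cue_left = rng.random(n) < 0.5
    cue_side = np.where(cue_left, "L", "R")
    if spec.task == "interleaved":
        tasks = np.where(rng.random(n) < 0.5, "pro", "anti")
    else:
        tasks = np.full(n, spec.task)
    target = np.where(
        tasks == "pro", cue_side, np.where(cue_side == "L", "R", "L")
    )

    a, b = spec.rt_range_ms
    az = (a - spec.rt_mean_ms) / spec.rt_sd_ms
    bz = (b - spec.rt_mean_ms) / spec.rt_sd_ms
    rt = truncnorm.rvs(az, bz, loc=spec.rt_mean_ms, scale=spec.rt_sd_ms,
                       size=n, random_state=rng)
    rpt = rt - gaps

    p = np.asarray(spec.true_curve(rpt), float)
    baseline = float(np.asarray(spec.true_curve(-1000.0), float))
    guessing = np.abs(p - baseline) <= spec.guess_tol

    # history bias: accuracy offset toward the previous target location,
    # growing with the length of the preceding repeat run
    bias = np.zeros(n)
    if spec.history_bias_per_repeat != 0.0:
        run = 1  # length of the same-target run ending at the previous trial
        for i in range(1, n):
            if i >= 2:
                run = run + 1 if target[i - 1] == target[i - 2] else 1
            b_i = min(spec.history_bias_per_repeat * run, spec.history_bias_cap)
            bias[i] = b_i if target[i] == target[i - 1] else -b_i
    if spec.lateral_bias != 0.0:
        bias = bias + np.where(
            target == spec.preferred_side, spec.lateral_bias, -spec.lateral_bias
        )

    p_eff = np.where(guessing, np.clip(p + bias, 0.0, 1.0), p)
    correct = rng.random(n) < p_eff
    choice = np.where(correct, target, np.where(target == "L", "R", "L"))

    if spec.abort_rate > 0:
        aborted = rng.random(n) < spec.abort_rate
        choice = np.where(aborted, None, choice)
        rt = np.where(aborted, np.nan, rt)

    df = pd.DataFrame(
        {
            "participant_id": spec.participant_id,
            "task": tasks,
            "block": spec.block,
            "luminance": spec.luminance,
            "trial_index": np.arange(n),
            "gap_ms": gaps.astype(int),
            "cue_side": cue_side,
            "choice_side": choice,
            "rt_ms": rt,
        }
    )
    return trials_mod.derive_fields(df)
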