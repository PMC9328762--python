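"""Accelerated race-to-threshold models of urgent saccadic choices.

Two motor plans — one aimed at the cue location, one at the diametrically
opposite ("anti") location — ramp toward a fixed threshold at 1 ms Euler
resolution.  The first plan to cross triggers a saccade a short efferent
delay later.  Buildup rates are drawn per trial from a bivariate normal
distribution; a lateral bias ``b`` assigns the larger rate to the cue side
with probability 0.5 + b.

Cue information perturbs the ongoing race twice:

* **Exogenous response interval (ERI)** — starting ``exo_latency_ms``
  (~80 ms) after cue onset and lasting ``eri_duration_ms`` (~25 ms): the
  cue-directed plan is briefly halted (``halt_ms``) and then accelerated
  by ``exo_accel`` per ms, while the anti plan is halted throughout.  This
  involuntary response is identical regardless of task rules.
* **Endogenous steering** — after the ERI, the plan toward the *target* is
  accelerated by ``endo_accel`` per ms and the other decelerated by
  ``endo_decel`` per ms.

The antisaccade model (CAS) and the prosaccade model (CPS) differ by a
single sign: which plan counts as the target for the endogenous terms.
Deceleration may drive a rate negative (the plan decays) but activity is
floored at zero.

Quantitative parameter values are a package calibration stored in
``data/default_params.toml``; they are chosen so the simulated antisaccade
tachometric curve shows the characteristic capture dip at ~90–140 ms of
cue viewing time with recovery to near-perfect accuracy past ~200 ms.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import tachometric, trials as trials_mod

__all__ = [
    "RaceParams",
    "MotorPlanTrace",
    "DEFAULT_GAP_SET_MS",
    "URGENT_GAP_SET_MS",
    "draw_buildup_rates",
    "simulate_trial",
    "simulate_session",
    "predicted_tachometric",
]

#: Gap values of the task design, ms (negative = nonurgent delayed trials).
DEFAULT_GAP_SET_MS = (-200, -100, 0, 75, 100, 125, 150, 175, 200, 250, 350)
#: Urgent subset (gap >= 0), used for simulated tachometric curves.
URGENT_GAP_SET_MS = tuple(g for g in DEFAULT_GAP_SET_MS if g >= 0)


@dataclass(frozen=True)
class RaceParams:
    """All constants of the CAS/CPS race model.

    Units: activity in arbitrary units, rates in units/ms, accelerations
    in units/ms², times in ms.
    """

    build_mean: float          # mean of the buildup-rate distribution
    build_sd: float            # sd of the buildup-rate distribution
    build_corr: float          # correlation of the two rates, |rho| <= 1
    threshold: float           # activity level that triggers a saccade
    efferent_delay_ms: float   # threshold crossing -> saccade onset
    go_latency_ms: float       # mean latency from go signal to ramping
    go_jitter_sd_ms: float     # trial-to-trial sd of that latency
    exo_latency_ms: float      # cue onset -> ERI start (~80)
    eri_duration_ms: float     # ERI length (~25)
    halt_ms: float             # initial halt of the cue plan inside the ERI
    exo_accel: float           # cue-plan rate gain per ms after the halt
    endo_accel: float          # target-plan rate gain per ms after the ERI
    endo_decel: float          # distracter-plan rate loss per ms after the ERI
    bias: float = 0.0          # lateral guessing bias in [-0.5, 0.5]
    timeout_cap_ms: int = 2000

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if abs(self.build_corr) > 1:
            raise ValueError("|build_corr| must be <= 1")
        if abs(self.bias) > 0.5:
            raise ValueError("|bias| must be <= 0.5")
        for name in ("efferent_delay_ms", "go_latency_ms", "go_jitter_sd_ms",
                     "exo_latency_ms", "eri_duration_ms", "halt_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.halt_ms > self.eri_duration_ms:
            raise ValueError("halt_ms cannot exceed eri_duration_ms")

    def replace(self, **kwargs) -> "RaceParams":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def default(cls) -> "RaceParams":
        """Calibrated high-luminance parameter set shipped with the package."""
        text = resources.files("urgentsaccade.data").joinpath(
            "default_params.toml").read_text()
        return cls(**tomllib.loads(text)["race"])

    @classmethod
    def from_file(cls, path) -> "RaceParams":
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        return cls(**cfg.get("race", cfg))

    def low_luminance(self) -> "RaceParams":
        """Preset emulating a dim cue: the exogenous response starts later
        and is weaker, shifting the capture dip to longer processing times."""
        return self.replace(
            exo_latency_ms=self.exo_latency_ms + 32.0,
            exo_accel=self.exo_accel * 0.6,
        )


@dataclass
class MotorPlanTrace:
    """Activity of both motor plans over time for a single simulated trial."""

    t: np.ndarray              # ms from the go signal
    r_left: np.ndarray         # leftward plan activity
    r_right: np.ndarray        # rightward plan activity
    eri_window: tuple[float, float] | None
    crossing_time_ms: float    # NaN on timeout
    winner: str | None         # "L" / "R" / None


def draw_buildup_rates(params: RaceParams, rng: np.random.Generator, n: int = 1):
    """Draw (cue-plan, anti-plan) buildup rates for ``n`` trials.

    Rates come from the bivariate normal (negative draws floored at 0);
    with bias b the larger of the two is assigned to the cue-directed plan
    with probability 0.5 + b.
    """
    cov = params.build_sd ** 2 * np.array(
        [[1.0, params.build_corr], [params.build_corr, 1.0]]
    )
    raw = rng.multivariate_normal([params.build_mean] * 2, cov, size=n)
    raw = np.maximum(raw, 0.0)
    hi = raw.max(axis=1)
    lo = raw.min(axis=1)
    to_cue = rng.random(n) < (0.5 + params.bias)
    rate_cue = np.where(to_cue, hi, lo)
    rate_anti = np.where(to_cue, lo, hi)
    return rate_cue, rate_anti


def _effective_rates(t, base_cue, base_anti, ramp_start, eri_start, halt_end,
                     eri_end, params, task_sign):
    """Effective ramp rates of both plans at integer time t (vectorized).

    ``task_sign`` = +1 when the cue plan is the endogenous target (pro),
    −1 when the anti plan is (anti).
    """
    started_cue = t >= ramp_start
    started_anti = t >= ramp_start

    r_cue = np.where(started_cue, base_cue, 0.0)
    r_anti = np.where(started_anti, base_anti, 0.0)

    in_halt = (t >= eri_start) & (t < halt_end)
    in_accel = (t >= halt_end) & (t < eri_end)
    in_eri = (t >= eri_start) & (t < eri_end)
    post = t >= eri_end

    # exogenous: cue plan halted then accelerated; anti plan halted throughout
    r_cue = np.where(in_halt, 0.0, r_cue)
    r_cue = np.where(in_accel, r_cue + params.exo_accel * (t - halt_end + 1), r_cue)
    r_anti = np.where(in_eri, 0.0, r_anti)

    # after the ERI the exogenous boost persists in the cue plan's rate
    n_accel = np.maximum(eri_end - halt_end, 0.0)
    dt_post = t - eri_end + 1
    boost = params.exo_accel * n_accel
    endo_cue = np.where(task_sign > 0, params.endo_accel, -params.endo_decel)
    endo_anti = np.where(task_sign > 0, -params.endo_decel, params.endo_accel)
    r_cue = np.where(post, r_cue + boost + endo_cue * dt_post, r_cue)
    r_anti = np.where(post, r_anti + endo_anti * dt_post, r_anti)
    return r_cue, r_anti


def _simulate_batch(params, task, gaps, rng, record_trace=False):
    """Integrate the race for a batch of trials with a common task.

    Returns per-trial arrays: crossing time (NaN on timeout), winner plan
    (+1 cue side, −1 anti side), and optionally full activity traces.
    """
    gaps = np.asarray(gaps, float)
    n = gaps.size
    if np.any(gaps < 0):
        raise ValueError("race simulation requires urgent trials (gap >= 0)")
    task_sign = 1.0 if task == "pro" else -1.0

    rate_cue, rate_anti = draw_buildup_rates(params, rng, n)
    ramp_start = np.maximum(
        np.rint(rng.normal(params.go_latency_ms, params.go_jitter_sd_ms, n)), 0.0
    )
    eri_start = gaps + params.exo_latency_ms
    halt_end = eri_start + params.halt_ms
    eri_end = eri_start + params.eri_duration_ms

    act_cue = np.zeros(n)
    act_anti = np.zeros(n)
    cross_t = np.full(n, np.nan)
    winner = np.zeros(n)  # +1 cue plan, -1 anti plan, 0 pending
    cap = int(params.timeout_cap_ms)
    traces = ([], []) if record_trace else None

    for t in range(cap):
        pending = winner == 0
        if not pending.any():
            break
        r_cue, r_anti = _effective_rates(
            float(t), rate_cue, rate_anti, ramp_start, eri_start, halt_end,
            eri_end, params, task_sign
        )
        act_cue = np.where(pending, np.maximum(act_cue + r_cue, 0.0), act_cue)
        act_anti = np.where(pending, np.maximum(act_anti + r_anti, 0.0), act_anti)
        if record_trace:
            traces[0].append(act_cue.copy())
            traces[1].append(act_anti.copy())
        hit_cue = pending & (act_cue >= params.threshold)
        hit_anti = pending & (act_anti >= params.threshold)
        both = hit_cue & hit_anti
        if both.any():
            over_cue = act_cue - params.threshold
            over_anti = act_anti - params.threshold
            cue_wins = np.where(
                over_cue == over_anti, rng.random(n) < 0.5, over_cue > over_anti
            )
            winner = np.where(both, np.where(cue_wins, 1.0, -1.0), winner)
            cross_t = np.where(both, float(t + 1), cross_t)
            hit_cue &= ~both
            hit_anti &= ~both
        winner = np.where(hit_cue, 1.0, winner)
        winner = np.where(hit_anti, -1.0, winner)
        cross_t = np.where(hit_cue | hit_anti, float(t + 1), cross_t)

    out = {"cross_t": cross_t, "winner": winner,
           "timeout": winner == 0, "eri": (eri_start, eri_end)}
    if record_trace:
        out["trace_cue"] = np.array(traces[0])
        out["trace_anti"] = np.array(traces[1])
    return out


def simulate_trial(params: RaceParams, task: str, cue_side: str, gap_ms: float,
                   rng: np.random.Generator):
    """Simulate one trial, returning the scored record and the full trace."""
    res = _simulate_batch(params, task, [gap_ms], rng, record_trace=True)
    cross = float(res["cross_t"][0])
    timeout = bool(res["timeout"][0])
    win = res["winner"][0]
    if timeout:
        choice = None
        rt = np.nan
    else:
        choice = cue_side if win > 0 else trials_mod.opposite_side(cue_side)
        rt = cross + params.efferent_delay_ms
    target = trials_mod.target_side_for(task, cue_side)
    record = {
        "task": task,
        "gap_ms": gap_ms,
        "cue_side": cue_side,
        "target_side": target,
        "choice_side": choice,
        "rt_ms": rt,
        "rpt_ms": rt - gap_ms if not timeout else np.nan,
        "correct": (choice == target) if not timeout else None,
        "aborted": timeout,
    }
    n_steps = res["trace_cue"].shape[0]
    act_cue = res["trace_cue"][:, 0]
    act_anti = res["trace_anti"][:, 0]
    left_is_cue = cue_side == "L"
    trace = MotorPlanTrace(
        t=np.arange(1, n_steps + 1, dtype=float),
        r_left=act_cue if left_is_cue else act_anti,
        r_right=act_anti if left_is_cue else act_cue,
        eri_window=(float(res["eri"][0][0]), float(res["eri"][1][0])),
        crossing_time_ms=cross,
        winner=None if timeout else (cue_side if win > 0 else
                                     trials_mod.opposite_side(cue_side)),
    )
    return record, trace


def simulate_session(
    params: RaceParams,
    task: str,
    gap_set=URGENT_GAP_SET_MS,
    n_trials: int = 1000,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
    luminance: str = "high",
) -> pd.DataFrame:
    """Simulate a session of urgent trials as a standard trial table.

    ``task`` is ``"pro"``, ``"anti"``, or ``"interleaved"`` (both tasks
    randomly mixed 50/50).  Gap and cue side are sampled uniformly per
    trial.  Timeout trials (no crossing within the cap) are flagged
    aborted.
    """
    gap_set = tuple(gap_set)
    if len(gap_set) == 0:
        raise ValueError("gap_set must be nonempty")
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    gaps = rng.choice(np.asarray(gap_set, float), size=n_trials)
    cue_left = rng.random(n_trials) < 0.5
    cue_side = np.where(cue_left, "L", "R")
    if task == "interleaved":
        tasks = np.where(rng.random(n_trials) < 0.5, "pro", "anti")
        block = "interleaved"
    else:
        tasks = np.full(n_trials, task)
        block = "single_task"

    rt = np.full(n_trials, np.nan)
    winner = np.zeros(n_trials)
    timeout = np.zeros(n_trials, bool)
    for tk in ("pro", "anti"):
        m = tasks == tk
        if not m.any():
            continue
        # single rng stream: draws happen in task-sorted order, reproducibly
        res = _simulate_batch(params, tk, gaps[m], rng)
        rt[m] = res["cross_t"] + params.efferent_delay_ms
        winner[m] = res["winner"]
        timeout[m] = res["timeout"]

    choice = np.where(winner > 0, cue_side, np.where(cue_side == "L", "R", "L"))
    choice = np.where(timeout, None, choice)
    rt[timeout] = np.nan

    df = pd.DataFrame(
        {
            "participant_id": participant_id,
            "task": tasks,
            "block": block,
            "luminance": luminance,
            "trial_index": np.arange(n_trials),
            "gap_ms": gaps.astype(int),
            "cue_side": cue_side,
            "choice_side": choice,
            "rt_ms": rt,
        }
    )
    return trials_mod.derive_fields(df)


def predicted_tachometric(
    params: RaceParams,
    task: str,
    n_trials: int = 50_000,
    seed: int | np.random.Generator = 0,
    bin_width_ms: int = 21,
    min_bin_n: int = 10,
    rpt_range: tuple[float, float] | None = (-100, 300),
) -> tachometric.TachometricCurve:
    """Model-predicted tachometric curve for the CAS (anti) or CPS (pro) task."""
    table = simulate_session(params, task, URGENT_GAP_SET_MS, n_trials, seed)
    urgent = trials_mod.filter_urgent(table)
    return tachometric.compute(
        urgent, bin_width_ms=bin_width_ms, min_bin_n=min_bin_n,
        rpt_range=rpt_range, task=task,
    )
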