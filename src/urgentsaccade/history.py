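"""Target-location history conditioning and motor-bias analyses.

Guesses in urgent tasks tend to go toward the previous trial's *target*
location.  Splitting trials by whether the current target repeats or
switches relative to the preceding 1–3 targets shifts the chance plateau
of the tachometric curve above or below 0.5, and — in the antisaccade
task — moves the rise point: the larger the chance level, the earlier the
rise.  This module labels trials by history pattern (AA/AB, AAA/AAB,
AAAA/AAAB), fits each conditioned curve with the chance parameter freed,
and quantifies the rise-point-vs-chance-level relationship for data and
for race-model simulations with injected bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tachometric
from .fitting import AntiFit, ProFit, fit_anti, fit_pro
from .race import RaceParams, URGENT_GAP_SET_MS, simulate_session
from .trials import filter_urgent

__all__ = [
    "HistoryCondition",
    "BiasSweepResult",
    "label_history",
    "conditioned_analysis",
    "rise_vs_chance_slope",
    "model_bias_sweep",
    "participant_timing_table",
]

MIN_CONDITION_TRIALS = 500


@dataclass
class HistoryCondition:
    """One history condition (repeat or switch) at a given depth."""

    depth: int
    pattern: str               # e.g. "AA" (repeat) or "AB" (switch)
    trials: pd.DataFrame
    curve: tachometric.TachometricCurve
    fit: ProFit | AntiFit
    chance_level: float        # fitted baseline (B or AL, freed)
    rise_point_ms: float
    low_n: bool = False        # fewer than MIN_CONDITION_TRIALS trials


@dataclass
class BiasSweepResult:
    """Race-model sweep over lateral bias values."""

    biases: np.ndarray
    chance_levels: np.ndarray
    rise_points: np.ndarray
    slope_ms_per_chance: float     # drop in rise point per full 0->1 chance increase
    failed: np.ndarray             # boolean per bias: degenerate/failed fit


def _pattern(depth: int, repeat: bool) -> str:
    return "A" * (depth + 1) if repeat else "A" * depth + "B"


def label_history(trials: pd.DataFrame, depth: int) -> pd.DataFrame:
    """Label each trial repeat/switch relative to its previous targets.

    A trial is *repeat* when the ``depth`` preceding targets (within the
    same participant and block, in session order) are all on one side and
    the current target is on that same side; *switch* when they are all on
    one side and the current target is opposite.  Trials with insufficient
    history, mixed-side history, or any aborted trial among the
    predecessors stay unlabeled (empty string).

    Adds a ``history`` column; every trial is repeat, switch, or unlabeled,
    exactly once per depth.
    """
    if depth not in (1, 2, 3):
        raise ValueError("depth must be 1, 2, or 3")
    if "trial_index" not in trials.columns:
        raise ValueError("trials need a trial_index column (session order)")
    out = trials.copy()
    out["history"] = ""
    labels = np.full(len(out), "", dtype=object)
    pos = {idx: i for i, idx in enumerate(out.index)}
    for _, grp in out.groupby(["participant_id", "block"], observed=True, sort=False):
        grp = grp.sort_values("trial_index")
        tgt = grp["target_side"].to_numpy()
        ab = grp["aborted"].to_numpy()
        for j in range(depth, len(grp)):
            prev = tgt[j - depth: j]
            if ab[j - depth: j].any():
                continue
            if not (prev == prev[0]).all():
                continue
            labels[pos[grp.index[j]]] = (
                "repeat" if tgt[j] == prev[0] else "switch"
            )
    out["history"] = labels
    return out


def conditioned_analysis(
    trials: pd.DataFrame,
    task: str,
    depth: int = 1,
    bin_width_ms: int = 21,
    min_bin_n: int = 10,
    rpt_range=None,
) -> tuple[HistoryCondition, HistoryCondition]:
    """Tachometric curve + free-chance fit per history condition.

    Returns (repeat, switch).  Fits free the chance parameter (B for pro,
    AL — and the implied baseline — for anti) because conditioning on
    history is precisely the case where the guessing plateau departs from
    0.5.
    """
    labeled = label_history(trials, depth)
    labeled = filter_urgent(labeled[labeled["task"] == task])
    conditions = []
    for name in ("repeat", "switch"):
        sub = labeled[labeled["history"] == name].reset_index(drop=True)
        if len(sub) == 0:
            raise ValueError(f"no {name} trials at depth {depth}")
        curve = tachometric.compute(
            sub, bin_width_ms=bin_width_ms, min_bin_n=min_bin_n,
            rpt_range=rpt_range, task=task,
        )
        if task == "anti":
            fit = fit_anti(curve, fix_chance=False)
        else:
            fit = fit_pro(curve, fix_chance=False)
        conditions.append(
            HistoryCondition(
                depth=depth,
                pattern=_pattern(depth, name == "repeat"),
                trials=sub,
                curve=curve,
                fit=fit,
                chance_level=fit.chance_level,
                rise_point_ms=fit.rise_point_ms,
                low_n=len(sub) < MIN_CONDITION_TRIALS,
            )
        )
    return conditions[0], conditions[1]


def rise_vs_chance_slope(points: dict[float, float]) -> float:
    """Drop in rise point (ms) per full 0→1 increase in chance level.

    For two points the slope is exact arithmetic:
    (rise_a − rise_b) / (chance_b − chance_a).  With the one-back
    conditioned values (chance 0.36 → rise 154 ms, chance 0.64 → 143 ms)
    this gives ≈39 ms per full chance unit, i.e. ≈3.9 ms per 0.1.
    For more points a least-absolute-deviation line is fitted and the
    negated slope returned.
    """
    if len(points) < 2:
        raise ValueError("need at least two (chance, rise) points")
    chance = np.asarray(list(points.keys()), float)
    rise = np.asarray(list(points.values()), float)
    if np.unique(chance).size < 2:
        raise ValueError("chance levels must not all be equal")
    if chance.size == 2:
        (c1, c2), (r1, r2) = chance, rise
        return float((r1 - r2) / (c2 - c1))
    from scipy.optimize import minimize

    def lad(p):
        return float(np.sum(np.abs(rise - (p[0] + p[1] * chance))))

    slope0 = np.polyfit(chance, rise, 1)[0]
    res = minimize(lad, [rise.mean() - slope0 * chance.mean(), slope0],
                   method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
    return float(-res.x[1])


def model_bias_sweep(
    params: RaceParams,
    biases=(-0.2, -0.1, 0.0, 0.1, 0.2),
    task: str = "anti",
    n_trials: int = 50_000,
    seed: int = 0,
    rpt_range=(-100, 300),
    n_reps: int = 1,
) -> BiasSweepResult:
    """Run the race model over a set of lateral biases.

    Per bias: simulate ``n_reps`` independent sessions, build each
    tachometric curve, fit with the chance parameter free, and record the
    replicate-averaged (chance level, rise point).  Averaging over
    replicates tames the fit-to-fit variability of the free-baseline
    double-sigmoid, whose minimum trades off against the rise point.
    The returned slope is the drop in rise point per full chance unit —
    the model's prediction to compare against history-conditioned data.
    """
    biases = np.asarray(biases, float)
    if not (biases.min() < 0 < biases.max()):
        raise ValueError("biases should span both signs")
    chance = np.full(biases.size, np.nan)
    rise = np.full(biases.size, np.nan)
    failed = np.zeros(biases.size, bool)
    for i, b in enumerate(biases):
        p = params.replace(bias=float(b))
        ch_reps, rise_reps = [], []
        for r in range(n_reps):
            table = simulate_session(p, task, URGENT_GAP_SET_MS, n_trials,
                                     seed=seed + 10 * i + r)
            urgent = filter_urgent(table)
            curve = tachometric.compute(urgent, rpt_range=rpt_range, task=task)
            try:
                if task == "anti":
                    fit = fit_anti(curve, fix_chance=False)
                else:
                    fit = fit_pro(curve, fix_chance=False)
            except ValueError:
                continue
            if not fit.degenerate:
                ch_reps.append(fit.chance_level)
                rise_reps.append(fit.rise_point_ms)
        if not ch_reps:
            failed[i] = True
            continue
        chance[i] = float(np.mean(ch_reps))
        rise[i] = float(np.mean(rise_reps))
    ok = ~failed
    slope = (rise_vs_chance_slope(dict(zip(chance[ok], rise[ok])))
             if ok.sum() >= 2 else np.nan)
    return BiasSweepResult(biases=biases, chance_levels=chance,
                           rise_points=rise, slope_ms_per_chance=slope,
                           failed=failed)


def participant_timing_table(fits: dict[str, dict]) -> pd.DataFrame:
    """Per-participant timing metrics for cross-participant correlations.

    ``fits`` maps participant id → {"anti": AntiFit, "pro": ProFit}.
    Participants with a missing or degenerate fit are excluded.  Columns:
    anti_drop_ms, anti_rise_ms, pro_rise_ms — feed pairs of them to
    :func:`urgentsaccade.resampling.permutation_correlation`.
    """
    rows = []
    for pid, d in fits.items():
        anti, pro = d.get("anti"), d.get("pro")
        if anti is None or pro is None or anti.degenerate or pro.degenerate:
            continue
        rows.append(
            {
                "participant_id": pid,
                "anti_drop_ms": anti.drop_point_ms,
                "anti_rise_ms": anti.rise_point_ms,
                "pro_rise_ms": pro.rise_point_ms,
            }
        )
    table = pd.DataFrame(rows, columns=["participant_id", "anti_drop_ms",
                                        "anti_rise_ms", "pro_rise_ms"])
    table.attrs["underpowered"] = len(table) < 3
    return table
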