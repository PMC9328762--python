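"""Trial-level behavioral records for urgent pro-/antisaccade tasks.

A trial table is a :class:`pandas.DataFrame` with one row per trial and the
columns listed in :data:`COLUMNS`.  Sides are encoded ``"L"``/``"R"``,
booleans as 0/1, and missing choices (aborted trials) as empty fields.  The
derived quantities are

* ``target_side`` — equals ``cue_side`` for prosaccades and the opposite
  side for antisaccades,
* ``rpt_ms`` — the raw processing time, RT − gap (cue viewing time before
  the saccade; negative when the saccade precedes cue onset),
* ``correct`` — whether the first saccade went to the target side.

Completed trials are kept even when the reaction time exceeds the task's
425 ms deadline; only aborted trials (no recorded choice) are unscored.
"""

from __future__ import annotations

import io
from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "TrialValidationError",
    "opposite_side",
    "target_side_for",
    "compute_rpt",
    "score_trial",
    "derive_fields",
    "filter_urgent",
    "read_trials",
    "write_trials",
    "summarize_trials",
]

#: Canonical column order of a trial table.
COLUMNS = [
    "participant_id",
    "task",
    "block",
    "luminance",
    "trial_index",
    "gap_ms",
    "cue_side",
    "target_side",
    "choice_side",
    "rt_ms",
    "rpt_ms",
    "correct",
    "aborted",
]

_SIDES = ("L", "R")
_TASKS = ("pro", "anti")
_BLOCKS = ("single_task", "interleaved")
_LUMINANCES = ("high", "low")


class TrialValidationError(ValueError):
    """Raised when a trial table violates the schema or task rules."""

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


def opposite_side(side: str) -> str:
    return "R" if side == "L" else "L"


def target_side_for(task: str, cue_side: str) -> str:
    """Side of the correct response: toward the cue (pro) or away (anti)."""
    if task == "pro":
        return cue_side
    if task == "anti":
        return opposite_side(cue_side)
    raise TrialValidationError(f"unknown task {task!r}")


def compute_rpt(rt_ms, gap_ms):
    """Raw processing time rPT = RT − gap.

    Accepts scalars or array-likes; NaN reaction times (aborted trials)
    propagate.  Negative values are legitimate: the saccade was committed
    before the cue appeared (a guess).
    """
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt[~np.isnan(rt)] < 0):
        raise ValueError("rt_ms must be nonnegative")
    out = rt - np.asarray(gap_ms, dtype=float)
    if np.isscalar(rt_ms) or np.ndim(rt_ms) == 0:
        return float(out)
    return out


def score_trial(task: str, cue_side: str, choice_side: str | None) -> bool | None:
    """Correctness of the first saccade under the task rule.

    Returns ``None`` when the choice is missing (aborted trial): such trials
    are flagged, not scored.
    """
    if choice_side is None or (isinstance(choice_side, float) and np.isnan(choice_side)):
        return None
    return choice_side == target_side_for(task, cue_side)


def derive_fields(df: pd.DataFrame) -> pd.DataFrame:
    """Fill target_side, rpt_ms, correct, and aborted from the raw columns."""
    df = df.copy()
    df["choice_side"] = df["choice_side"].where(df["choice_side"].notna(), np.nan)
    pro = df["task"] == "pro"
    df["target_side"] = np.where(
        pro, df["cue_side"], df["cue_side"].map(opposite_side)
    )
    df["aborted"] = df["choice_side"].isna().astype(int)
    df["rpt_ms"] = df["rt_ms"].astype(float) - df["gap_ms"].astype(float)
    correct = (df["choice_side"] == df["target_side"]).astype(float)
    correct[df["aborted"] == 1] = np.nan
    df["correct"] = correct
    return df[[c for c in COLUMNS if c in df.columns]]


def filter_urgent(df: pd.DataFrame) -> pd.DataFrame:
    """Keep urgent trials only: gap ≥ 0 ms and not aborted.

    Nonurgent trials (negative gap: the cue precedes the go signal) are easy
    and excluded from all tachometric analyses.  Idempotent.
    """
    mask = (df["gap_ms"] >= 0) & (df["aborted"] == 0)
    return df.loc[mask].reset_index(drop=True)


def _check_values(df: pd.DataFrame) -> None:
    def bad_rows(mask: pd.Series) -> int:
        return int(np.flatnonzero(mask.to_numpy())[0])

    for col, allowed in [
        ("task", _TASKS),
        ("block", _BLOCKS),
        ("luminance", _LUMINANCES),
        ("cue_side", _SIDES),
    ]:
        bad = ~df[col].isin(allowed)
        if bad.any():
            raise TrialValidationError(
                f"invalid {col} value {df[col][bad].iloc[0]!r}", bad_rows(bad)
            )
    bad = ~(df["choice_side"].isin(_SIDES) | df["choice_side"].isna())
    if bad.any():
        raise TrialValidationError(
            f"invalid choice_side value {df['choice_side'][bad].iloc[0]!r}",
            bad_rows(bad),
        )
    rt = df["rt_ms"].astype(float)
    bad = rt.notna() & (rt < 0)
    if bad.any():
        raise TrialValidationError("negative rt_ms", bad_rows(bad))
    if "target_side" in df.columns:
        expect = np.where(
            df["task"] == "pro", df["cue_side"], df["cue_side"].map(opposite_side)
        )
        bad = df["target_side"] != expect
        if bad.any():
            raise TrialValidationError(
                "target_side inconsistent with task rule", bad_rows(bad)
            )


def read_trials(path) -> pd.DataFrame:
    """Read and validate a CSV trial table, deriving any missing fields.

    Required columns: participant_id, task, block, luminance, trial_index,
    gap_ms, cue_side, rt_ms, choice_side.  Derived columns present in the
    file are checked for consistency.
    """
    df = pd.read_csv(path, dtype={"choice_side": "string", "cue_side": "string"})
    required = [
        "participant_id", "task", "block", "luminance",
        "trial_index", "gap_ms", "cue_side", "choice_side", "rt_ms",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown:
        raise TrialValidationError(f"unknown column(s): {', '.join(unknown)}")
    try:
        df["gap_ms"] = df["gap_ms"].astype(int)
        df["trial_index"] = df["trial_index"].astype(int)
        df["rt_ms"] = df["rt_ms"].astype(float)
    except (TypeError, ValueError) as exc:
        raise TrialValidationError(f"unparseable numeric value ({exc})") from exc
    df["cue_side"] = df["cue_side"].astype(object)
    df["choice_side"] = df["choice_side"].astype(object).where(df["choice_side"].notna())
    _check_values(df)
    return derive_fields(df)


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table to CSV (UTF-8, one header row, booleans as 0/1)."""
    out = derive_fields(df)
    out.to_csv(path, index=False, float_format="%.6g")


def summarize_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Trial counts per participant × task × gap, with abort tallies."""
    g = df.groupby(["participant_id", "task", "gap_ms"], observed=True)
    out = g.agg(
        n_trials=("gap_ms", "size"),
        n_aborted=("aborted", "sum"),
        frac_correct=("correct", "mean"),
    ).reset_index()
    return out
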