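"""Tachometric curves: choice accuracy as a function of raw processing time.

The tachometric curve is the central psychometric object in urgent tasks.
Scored urgent trials are grouped into overlapping rPT bins (default width
21 ms) whose centers step along a 1 ms grid; each bin yields a fraction
correct with an exact (Clopper–Pearson) 95% binomial confidence interval.
Bins with too few trials are left undefined rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = ["TachometricCurve", "compute", "invert"]


@dataclass
class TachometricCurve:
    """Accuracy vs. rPT on a 1 ms grid with per-bin counts and binomial CIs.

    ``frac_correct`` (and the CI bounds) are NaN where a bin holds fewer
    than ``min_bin_n`` trials.
    """

    rpt_grid: np.ndarray          # bin centers, ms
    frac_correct: np.ndarray      # fraction correct per bin, NaN if undefined
    n_trials: np.ndarray          # trials per bin
    ci_low: np.ndarray
    ci_high: np.ndarray
    bin_width_ms: int = 21
    task: str = ""
    metadata: dict = field(default_factory=dict)

    def defined(self) -> np.ndarray:
        """Boolean mask of grid points with a defined fraction correct."""
        return ~np.isnan(self.frac_correct)

    def __call__(self, x) -> np.ndarray:
        """Linear interpolation of the curve over its defined points."""
        m = self.defined()
        return np.interp(x, self.rpt_grid[m], self.frac_correct[m],
                         left=np.nan, right=np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rpt": self.rpt_grid,
                "frac": self.frac_correct,
                "n": self.n_trials,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path, bin_width_ms: int = 21, task: str = "") -> "TachometricCurve":
        df = pd.read_csv(path)
        return cls(
            rpt_grid=df["rpt"].to_numpy(float),
            frac_correct=df["frac"].to_numpy(float),
            n_trials=df["n"].to_numpy(int),
            ci_low=df["ci_low"].to_numpy(float),
            ci_high=df["ci_high"].to_numpy(float),
            bin_width_ms=bin_width_ms,
            task=task,
        )


def compute(
    trials: pd.DataFrame,
    bin_width_ms: int = 21,
    step_ms: int = 1,
    min_bin_n: int = 10,
    rpt_range: tuple[float, float] | None = None,
    alpha: float = 0.05,
    task: str = "",
) -> TachometricCurve:
    """Build a tachometric curve from scored, urgent-filtered trials.

    Each grid center ``c`` collects trials with rPT in the half-open
    interval ``[c − w/2, c + w/2)``; the fraction correct and its exact
    binomial CI come from the bin's correct/incorrect tallies.

    Parameters
    ----------
    trials
        Trial table with ``rpt_ms`` and ``correct`` columns (no NaNs in
        either; run :func:`urgentsaccade.trials.filter_urgent` first).
    rpt_range
        Grid span (inclusive of endpoints, integer centers).  Default:
        floor/ceil of the observed rPT range.
    """
    rpt = trials["rpt_ms"].to_numpy(float)
    correct = trials["correct"].to_numpy(float)
    if rpt.size == 0:
        empty = np.empty(0)
        return TachometricCurve(empty, empty, empty.astype(int), empty, empty,
                                bin_width_ms, task)
    if np.isnan(rpt).any() or np.isnan(correct).any():
        raise ValueError("trials must be scored and urgent-filtered (no NaNs)")

    if rpt_range is None:
        lo, hi = int(np.floor(rpt.min())), int(np.ceil(rpt.max()))
    else:
        lo, hi = int(rpt_range[0]), int(rpt_range[1])
    grid = np.arange(lo, hi + 1, step_ms, dtype=float)

    order = np.argsort(rpt, kind="stable")
    rpt_s = rpt[order]
    csum = np.concatenate([[0.0], np.cumsum(correct[order])])
    half = bin_width_ms / 2.0
    i0 = np.searchsorted(rpt_s, grid - half, side="left")
    i1 = np.searchsorted(rpt_s, grid + half, side="left")
    n = (i1 - i0).astype(int)
    k = (csum[i1] - csum[i0])

    frac = np.full(grid.shape, np.nan)
    ci_low = np.full(grid.shape, np.nan)
    ci_high = np.full(grid.shape, np.nan)
    ok = n >= max(min_bin_n, 1)
    frac[ok] = k[ok] / n[ok]
    if ok.any():
        lo_ci, hi_ci = proportion_confint(k[ok], n[ok], alpha=alpha, method="beta")
        ci_low[ok] = np.nan_to_num(lo_ci, nan=0.0)   # beta CI is NaN at k=0 / k=n ends
        ci_high[ok] = np.nan_to_num(hi_ci, nan=1.0)
    return TachometricCurve(grid, frac, n, ci_low, ci_high, bin_width_ms, task)


def invert(curve: TachometricCurve) -> TachometricCurve:
    """Reflect a curve about 1: f(x) → 1 − f(x), swapping the CI bounds.

    Used to compare the early *rise* of a prosaccade curve with the early
    *drop* of an antisaccade curve; chance (0.5) is the fixed point.
    """
    return replace(
        curve,
        frac_correct=1.0 - curve.frac_correct,
        ci_low=1.0 - curve.ci_high,
        ci_high=1.0 - curve.ci_low,
        metadata={**curve.metadata, "inverted": not curve.metadata.get("inverted", False)},
    )
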