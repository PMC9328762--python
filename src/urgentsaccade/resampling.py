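"""Bootstrap confidence intervals and permutation tests.

Uncertainty on any curve-derived statistic (rise point, drop point,
optimal shift, …) comes from resampling trials with replacement at the
trial level, recomputing the statistic on each resample, and taking the
2.5/97.5 percentiles of the resulting distribution.  Cross-participant
correlations are tested with a two-sided permutation test on the Pearson
coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = ["BootstrapResult", "bootstrap", "permutation_correlation"]


@dataclass
class BootstrapResult:
    point_estimate: float
    samples: np.ndarray        # statistic values from successful iterates
    ci_low: float              # 2.5 percentile
    ci_high: float             # 97.5 percentile
    n_iter: int
    n_failed: int
    seed: int
    unreliable: bool = False   # > 20% of iterates failed
    meta: dict = field(default_factory=dict)

    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def bootstrap(
    trials: pd.DataFrame,
    statistic,
    n_iter: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    stratify_by: str | None = None,
) -> BootstrapResult:
    """Percentile bootstrap of a trial-table statistic.

    ``statistic`` maps a trial table to a scalar.  The resampling unit is
    the trial; pass ``stratify_by="participant_id"`` to resample within
    participants instead (off by default, matching trial-wise pooling).
    Iterates that raise or return NaN are counted as failures and excluded;
    more than 20% failures flags the result unreliable.

    Seeding uses one master :class:`numpy.random.SeedSequence` that spawns
    an independent substream per iteration, so results for the first k
    iterations do not depend on ``n_iter``.
    """
    point = float(statistic(trials))
    idx_all = np.arange(len(trials))
    if stratify_by is not None:
        groups = [np.flatnonzero(trials[stratify_by].to_numpy() == g)
                  for g in pd.unique(trials[stratify_by])]
    streams = np.random.SeedSequence(seed).spawn(n_iter)

    samples = []
    n_failed = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        if stratify_by is None:
            take = rng.choice(idx_all, size=idx_all.size, replace=True)
        else:
            take = np.concatenate(
                [rng.choice(g, size=g.size, replace=True) for g in groups]
            )
        resampled = trials.iloc[take].reset_index(drop=True)
        try:
            val = float(statistic(resampled))
        except Exception:
            n_failed += 1
            continue
        if np.isnan(val):
            n_failed += 1
            continue
        samples.append(val)

    samples = np.asarray(samples)
    unreliable = n_failed > 0.2 * n_iter
    if unreliable:
        warnings.warn(
            f"bootstrap: {n_failed}/{n_iter} iterates failed; CI unreliable",
            stacklevel=2,
        )
    if samples.size:
        lo, hi = np.percentile(samples, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        lo = hi = np.nan
    return BootstrapResult(
        point_estimate=point, samples=samples, ci_low=float(lo),
        ci_high=float(hi), n_iter=n_iter, n_failed=n_failed, seed=seed,
        unreliable=unreliable,
    )


def permutation_correlation(x, y, n_perm: int = 10_000, seed: int = 0):
    """Pearson correlation with a two-sided permutation p value.

    The p value is the smoothed fraction of random pairings whose |ρ|
    meets or exceeds the observed |ρ|: p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) /
    (1 + n_perm), so p is never exactly zero.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    rho = float(pearsonr(x, y).statistic)

    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y.size)
        r = float((xc * yc[perm]).sum() / denom)
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return rho, p
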