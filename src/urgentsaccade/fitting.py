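"""Analytic fits to tachometric curves and their characteristic points.

Prosaccade curves are increasing sigmoids

    s(x) = B + (A − B) / (1 + exp(−(x − C)/D))

where ``C`` is the rise point: the rPT at which the fraction correct is
halfway between chance (``B``) and asymptote (``A``).

Antisaccade curves drop below chance (oculomotor capture) and then
recover, and are fitted with the lower envelope of two sigmoids,

    v(x) = max(sL(x), sR(x), 0)
    sL(x) = BLR + (AL − BLR) / (1 + exp(+(x − CL)/DL))   # decreasing limb
    sR(x) = BLR + (AR − BLR) / (1 + exp(−(x − CR)/DR))   # rising limb

``CL`` is the drop point (halfway between chance ``AL`` and the minimum
``BLR``) and ``CR`` the rise point (halfway between the minimum and the
asymptote ``AR``).

All fits minimize the mean absolute error (MAE) over the curve's defined
grid points with a derivative-free simplex (Nelder–Mead) restarted from
jittered moment-based guesses; slope scales are log-parameterized to stay
positive.  Chance parameters (B, AL) are frozen at 0.5 unless the analysis
conditions on motor bias, in which case they are freed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .tachometric import TachometricCurve

__all__ = [
    "ProFit", "AntiFit",
    "pro_sigmoid", "anti_double_sigmoid",
    "fit_pro", "fit_anti",
    "rise_point", "drop_point",
]

#: Fitted dynamic range below which characteristic points are meaningless.
DEGENERATE_RANGE = 0.05
_N_RESTARTS = 10


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


def pro_sigmoid(x, A, B, C, D):
    """Increasing sigmoid between chance B and asymptote A, rise point C."""
    return B + (A - B) * _logistic((np.asarray(x, float) - C) / D)


def anti_double_sigmoid(x, AL, AR, BLR, CL, CR, DL, DR):
    """Drop-recover curve: max of a falling and a rising sigmoid, floored at 0."""
    x = np.asarray(x, float)
    sL = BLR + (AL - BLR) * _logistic(-(x - CL) / DL)
    sR = BLR + (AR - BLR) * _logistic((x - CR) / DR)
    return np.maximum(np.maximum(sL, sR), 0.0)


@dataclass
class ProFit:
    A: float
    B: float
    C: float
    D: float
    mae: float
    degenerate: bool = False

    def __call__(self, x):
        return pro_sigmoid(x, self.A, self.B, self.C, self.D)

    @property
    def rise_point_ms(self) -> float:
        return np.nan if self.degenerate else self.C

    @property
    def chance_level(self) -> float:
        return self.B


@dataclass
class AntiFit:
    AL: float
    AR: float
    BLR: float
    CL: float
    CR: float
    DL: float
    DR: float
    mae: float
    degenerate: bool = False

    def __call__(self, x):
        return anti_double_sigmoid(
            x, self.AL, self.AR, self.BLR, self.CL, self.CR, self.DL, self.DR
        )

    @property
    def drop_point_ms(self) -> float:
        return np.nan if self.degenerate else self.CL

    @property
    def rise_point_ms(self) -> float:
        return np.nan if self.degenerate else self.CR

    @property
    def chance_level(self) -> float:
        return self.AL


def _defined_xy(curve: TachometricCurve):
    m = curve.defined()
    return curve.rpt_grid[m], curve.frac_correct[m]


def _simplex(objective, x0, maxiter=4000):
    return minimize(objective, x0, method="Nelder-Mead",
                    options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-7})


def fit_pro(curve: TachometricCurve, fix_chance: bool = True,
            n_restarts: int = _N_RESTARTS) -> ProFit:
    """Fit the increasing sigmoid to a (prosaccade-shaped) curve by MAE.

    With ``fix_chance`` the baseline B is frozen at 0.5; freeing it is
    appropriate when the guessing regime is biased away from 0.5 (history
    conditioning).  A fit whose dynamic range A − B is below
    ``DEGENERATE_RANGE`` is flagged degenerate and its rise point is NaN.
    """
    x, y = _defined_xy(curve)
    if x.size < 4:
        raise ValueError("curve has too few defined points to fit")
    rng = np.random.default_rng(12345)

    B0 = 0.5 if fix_chance else float(np.clip(np.median(y[: max(5, x.size // 10)]), 0, 1))
    A0 = float(np.clip(np.percentile(y, 95), B0 + 0.05, 1.0))
    half = (A0 + B0) / 2.0
    above = x[y >= half]
    C0 = float(above[0]) if above.size else float(np.median(x))
    D0 = 10.0

    def unpack(p):
        if fix_chance:
            A, C, logD = p
            B = 0.5
        else:
            A, B, C, logD = p
        return A, B, C, np.exp(logD)

    def objective(p):
        A, B, C, D = unpack(p)
        pen = 0.0
        if not (0.0 <= B <= A <= 1.0):
            pen = 10.0 + abs(B) + abs(A)
        return float(np.mean(np.abs(pro_sigmoid(x, A, B, C, D) - y))) + pen

    p0 = [A0, C0, np.log(D0)] if fix_chance else [A0, B0, C0, np.log(D0)]
    best = None
    for i in range(n_restarts):
        start = np.asarray(p0, float)
        if i > 0:
            jitter = rng.normal(0, [0.05, 15.0, 0.4][: 3] if fix_chance
                                else [0.05, 0.05, 15.0, 0.4], size=start.shape)
            start = start + jitter
        res = _simplex(objective, start)
        if best is None or res.fun < best.fun:
            best = res
    A, B, C, D = unpack(best.x)
    degenerate = bool((A - B) < DEGENERATE_RANGE)
    return ProFit(A=float(A), B=float(B), C=float(C), D=float(D),
                  mae=float(best.fun), degenerate=degenerate)


def fit_anti(curve: TachometricCurve, fix_chance: bool = True,
             n_restarts: int = _N_RESTARTS) -> AntiFit:
    """Fit the drop-recover double sigmoid to an (antisaccade-shaped) curve.

    With ``fix_chance`` the left plateau AL is frozen at 0.5.  A monotone
    curve (no capture dip) yields a degenerate fit: the drop and rise
    points are NaN.
    """
    x, y = _defined_xy(curve)
    if x.size < 6:
        raise ValueError("curve has too few defined points to fit")
    rng = np.random.default_rng(54321)

    AL0 = 0.5 if fix_chance else float(np.clip(np.median(y[: max(5, x.size // 10)]), 0, 1))
    i_min = int(np.argmin(y))
    BLR0 = float(max(y[i_min], 0.0))
    AR0 = float(np.clip(np.percentile(y[i_min:], 95), BLR0 + 0.05, 1.0))
    left = x[: i_min + 1][y[: i_min + 1] <= (AL0 + BLR0) / 2]
    CL0 = float(left[0]) if left.size else float(x[max(i_min - 10, 0)])
    right = x[i_min:][y[i_min:] >= (AR0 + BLR0) / 2]
    CR0 = float(right[0]) if right.size else float(x[min(i_min + 10, x.size - 1)])
    DL0, DR0 = 5.0, 10.0

    def unpack(p):
        if fix_chance:
            AR, BLR, CL, CR, logDL, logDR = p
            AL = 0.5
        else:
            AL, AR, BLR, CL, CR, logDL, logDR = p
        return AL, AR, BLR, CL, CR, np.exp(logDL), np.exp(logDR)

    def objective(p):
        AL, AR, BLR, CL, CR, DL, DR = unpack(p)
        pen = 0.0
        if not (0.0 <= BLR <= min(AL, AR) and AR <= 1.0 and AL <= 1.0):
            pen += 10.0 + abs(BLR) + abs(AR)
        if CL >= CR:
            pen += 1.0 + 0.01 * (CL - CR)
        v = anti_double_sigmoid(x, AL, AR, BLR, CL, CR, DL, DR)
        return float(np.mean(np.abs(v - y))) + pen

    p0 = ([AR0, BLR0, CL0, CR0, np.log(DL0), np.log(DR0)] if fix_chance
          else [AL0, AR0, BLR0, CL0, CR0, np.log(DL0), np.log(DR0)])
    scale = ([0.05, 0.03, 8.0, 12.0, 0.3, 0.3] if fix_chance
             else [0.05, 0.05, 0.03, 8.0, 12.0, 0.3, 0.3])
    best = None
    for i in range(n_restarts):
        start = np.asarray(p0, float)
        if i > 0:
            start = start + rng.normal(0, scale)
        res = _simplex(objective, start)
        if best is None or res.fun < best.fun:
            best = res
    AL, AR, BLR, CL, CR, DL, DR = unpack(best.x)
    degenerate = bool(min(AL, AR) - BLR < DEGENERATE_RANGE or CL >= CR)
    return AntiFit(AL=float(AL), AR=float(AR), BLR=float(BLR), CL=float(CL),
                   CR=float(CR), DL=float(DL), DR=float(DR),
                   mae=float(best.fun), degenerate=degenerate)


def rise_point(fit: ProFit | AntiFit) -> float:
    """rPT where accuracy is halfway between its baseline and asymptote."""
    return fit.rise_point_ms


def drop_point(fit: AntiFit) -> float:
    """rPT where anti accuracy is halfway between chance and its minimum."""
    return fit.drop_point_ms
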