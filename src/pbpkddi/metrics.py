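"""Non-compartmental PK endpoints and DDI exposure ratios.

AUC uses the linear-up/log-down trapezoid (log interpolation on descending
positive segments, linear otherwise). Optional extrapolation to infinity
adds C_last/λz, with λz from a log-linear fit of the final descending
points. DDI effect sizes are the standard AUC and Cmax ratios of the victim
with vs without the perpetrator, and model qualification compares predicted
against observed ratios with the conventional 2-fold acceptance band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["PKMetrics", "DDIRatios", "PredObsComparison", "compute_metrics",
           "ddi_ratios", "pred_obs_ratio", "TWO_FOLD"]

TWO_FOLD = (0.5, 2.0)


@dataclass(frozen=True)
class PKMetrics:
    auc: float            # µM·min over the stated interval
    cmax: float           # µM
    tmax: float           # min (first occurrence on ties)
    interval: tuple[float, Optional[float]]  # (t0, t1); t1=None means 0→∞
    lambda_z: Optional[float] = None         # 1/min, if extrapolated

    def __post_init__(self):
        if self.auc < 0:
            raise ValueError("auc must be >= 0")
        t0, t1 = self.interval
        if self.tmax < t0 or (t1 is not None and self.tmax > t1):
            raise ValueError("tmax outside interval")


@dataclass(frozen=True)
class DDIRatios:
    auc_ratio: float
    cmax_ratio: float

    def __post_init__(self):
        if self.auc_ratio <= 0 or self.cmax_ratio <= 0:
            raise ValueError("ratios must be > 0")


@dataclass(frozen=True)
class PredObsComparison:
    auc_ratio: float   # predicted/observed AUC_R
    cmax_ratio: float  # predicted/observed Cmax_R
    auc_within_twofold: bool
    cmax_within_twofold: bool

    @property
    def within_twofold(self) -> bool:
        return self.auc_within_twofold and self.cmax_within_twofold


def _lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    log_ok = (c2 < c1) & (c2 > 0) & (c1 > 0)
    log_ratio = np.ones_like(c1)
    np.log(c1, where=log_ok, out=log_ratio)
    log_ratio[log_ok] -= np.log(c2[log_ok])
    seg = np.where(log_ok, (c1 - c2) * dt / log_ratio,
                   0.5 * (c1 + c2) * dt)
    return float(seg.sum())


def _terminal_slope(t: np.ndarray, c: np.ndarray,
                    min_points: int = 3) -> float:
    """λz from a log-linear fit of the trailing descending positive points."""
    pos = c > 0
    if not pos.any():
        raise ValueError("cannot extrapolate an all-zero profile")
    i_max = int(np.argmax(c))
    # longest strictly-descending positive run at the tail, after the peak
    if c[-1] <= 0:
        raise ValueError("profile ends at zero; cannot extrapolate")
    start = len(c) - 1
    while start > i_max and c[start - 1] > c[start] and c[start - 1] > 0:
        start -= 1
    tail = list(range(start, len(c)))
    if len(tail) < min_points:
        raise ValueError(
            f"need >= {min_points} descending terminal points for λz, "
            f"found {len(tail)}")
    tt, cc = t[tail], np.log(c[tail])
    slope = np.polyfit(tt, cc, 1)[0]
    if slope >= 0:
        raise ValueError("terminal phase is not declining; cannot extrapolate")
    return float(-slope)


def compute_metrics(times: Sequence[float], concentrations: Sequence[float],
                    interval: Optional[tuple[float, float]] = None,
                    extrapolate: bool = False) -> PKMetrics:
    """AUC, Cmax and Tmax of a concentration–time profile.

    ``interval`` restricts the endpoints to (t0, t1) with linear
    interpolation at the cut points; ``extrapolate`` adds the C_last/λz tail
    to the AUC (0→∞), incompatible with a finite interval.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise ValueError("profile needs at least 3 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if len(c) != len(t):
        raise ValueError("times and concentrations differ in length")
    if np.any(c < 0):
        raise ValueError("negative concentrations")
    if interval is not None and extrapolate:
        raise ValueError("extrapolation applies to the 0→∞ endpoint only")

    if interval is not None:
        t0, t1 = interval
        if t0 < t[0] or t1 > t[-1] or t0 >= t1:
            raise ValueError(f"interval {interval} outside profile span")
        inner = (t > t0) & (t < t1)
        tt = np.concatenate([[t0], t[inner], [t1]])
        cc = np.concatenate([[np.interp(t0, t, c)], c[inner],
                             [np.interp(t1, t, c)]])
    else:
        t0, t1 = float(t[0]), float(t[-1])
        tt, cc = t, c

    auc = _lin_up_log_down(tt, cc)
    i_max = int(np.argmax(cc))
    cmax = float(cc[i_max])
    tmax = float(tt[i_max])

    lam = None
    if extrapolate:
        if not np.any(c > 0):
            raise ValueError("cannot extrapolate an all-zero profile")
        lam = _terminal_slope(t, c)
        auc += float(c[-1]) / lam
        return PKMetrics(auc=auc, cmax=cmax, tmax=tmax,
                         interval=(t0, None), lambda_z=lam)
    return PKMetrics(auc=auc, cmax=cmax, tmax=tmax, interval=(t0, t1))


def ddi_ratios(victim_alone: PKMetrics,
               victim_with_perp: PKMetrics) -> DDIRatios:
    """Exposure ratios (with perpetrator / alone) over matching intervals."""
    a, b = victim_alone.interval, victim_with_perp.interval
    same = (abs(a[0] - b[0]) < 1e-9
            and ((a[1] is None) == (b[1] is None))
            and (a[1] is None or abs(a[1] - b[1]) < 1e-9))
    if not same:
        raise ValueError(f"interval mismatch: {a} vs {b}")
    return DDIRatios(auc_ratio=victim_with_perp.auc / victim_alone.auc,
                     cmax_ratio=victim_with_perp.cmax / victim_alone.cmax)


def pred_obs_ratio(predicted: DDIRatios,
                   observed: DDIRatios) -> PredObsComparison:
    """Element-wise predicted/observed ratios with 2-fold pass flags."""
    if observed.auc_ratio == 0 or observed.cmax_ratio == 0:
        raise ValueError("observed ratios must be nonzero")
    ra = predicted.auc_ratio / observed.auc_ratio
    rc = predicted.cmax_ratio / observed.cmax_ratio
    lo, hi = TWO_FOLD
    return PredObsComparison(
        auc_ratio=ra, cmax_ratio=rc,
        auc_within_twofold=lo <= ra <= hi,
        cmax_within_twofold=lo <= rc <= hi)
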