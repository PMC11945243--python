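"""Non-compartmental analysis, geometric summaries, and DDI ratio evaluation.

AUC uses the linear-up/log-down trapezoid; the terminal slope λz comes from a
log-linear regression over the best adjusted-R² terminal window of at least
three post-peak points.  DDI effect sizes are geometric-mean ratios
(treated / control) reported at three significant figures and judged against
the conventional 1.5-fold acceptance band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NCAResult:
    """Summary exposure metrics from one concentration-time profile."""

    auc_last: float  # nmol*h/L
    cmax: float  # nmol/L
    tmax: float  # h
    lambda_z: float | None  # 1/h
    auc_inf: float | None  # nmol*h/L
    extrapolated_fraction: float | None  # %
    n_lambda_points: int = 0


def _trapezoid_linup_logdown(t: np.ndarray, c: np.ndarray) -> float:
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return auc


def _lambda_z(t: np.ndarray, c: np.ndarray) -> tuple[float | None, int]:
    """Terminal slope by best adjusted-R² over windows of >= 3 points after Cmax."""
    pos = c > 0
    i_max = int(np.argmax(c))
    cand_idx = np.flatnonzero(pos & (np.arange(len(c)) > i_max))
    if len(cand_idx) < 3:
        return None, 0
    tt, lc = t[cand_idx], np.log(c[cand_idx])
    best = None
    for start in range(0, len(cand_idx) - 2):
        x, y = tt[start:], lc[start:]
        n = len(x)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot <= 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if slope < 0 and (best is None or adj > best[0] + 1e-12):
            best = (adj, -slope, n)
    if best is None:
        return None, 0
    return best[1], best[2]


def nca(time, conc) -> NCAResult:
    """Non-compartmental analysis of a single profile.

    AUC_last by linear-up/log-down trapezoid over the sampled grid; when a
    terminal slope is estimable, AUC_inf = AUC_last + C_last/λz.
    """
    t = np.asarray(time, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.shape != c.shape or len(t) < 2:
        raise ValueError("time and conc must be equal-length 1-D arrays (n >= 2)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")

    auc_last = _trapezoid_linup_logdown(t, c)
    i_max = int(np.argmax(c))
    lam, n_lam = _lambda_z(t, c)
    auc_inf = ext = None
    if lam is not None:
        c_last = c[np.flatnonzero(c > 0)[-1]]
        auc_inf = auc_last + c_last / lam
        ext = 100.0 * (auc_inf - auc_last) / auc_inf if auc_inf > 0 else None
    return NCAResult(
        auc_last=float(auc_last),
        cmax=float(c[i_max]),
        tmax=float(t[i_max]),
        lambda_z=lam,
        auc_inf=auc_inf,
        extrapolated_fraction=ext,
        n_lambda_points=n_lam,
    )


def geo_summary(values) -> dict:
    """Geometric mean with empirical 5th and 95th percentiles.

    Percentiles use the type-7 (linear-interpolation) convention.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if np.any(v <= 0):
        raise ValueError("geometric summary requires strictly positive values")
    return {
        "geomean": float(np.exp(np.mean(np.log(v)))),
        "p5": float(np.percentile(v, 5, method="linear")),
        "p95": float(np.percentile(v, 95, method="linear")),
        "n": int(len(v)),
    }


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def ddi_ratio(treated_stat: float, control_stat: float) -> float:
    """Treated/control effect ratio, reported at 3 significant figures."""
    if control_stat <= 0:
        raise ValueError("control statistic must be > 0")
    return round_sig(treated_stat / control_stat, 3)


def fold_check(observed: float, simulated: float, fold: float = 1.5) -> bool:
    """Prediction acceptance: observed/simulated within a ``fold``-range.

    Pass iff max(o/s, s/o) <= fold.
    """
    if observed <= 0 or simulated <= 0:
        raise ValueError("observed and simulated must be > 0")
    r = observed / simulated
    return max(r, 1.0 / r) <= fold
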