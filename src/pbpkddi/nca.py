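"""Non-compartmental analysis of concentration–time profiles.

AUC uses the linear-up/log-down trapezoid (pharma convention; pure linear
available).  The terminal slope λz is estimated by log-linear regression
over automatically selected terminal points: every suffix of ≥3 positive
post-Tmax points is scored by adjusted R² and the best wins (ties go to
the longer fit).  ``auc_inf = auc_last + C_last/λz``; ``CL/F = dose/auc_inf``;
``V/F = CL/F / λz``; ``t½ = ln2/λz``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .pk_engine import ConcTimeProfile

__all__ = ["NCAResult", "run_nca", "auc_trapezoid", "auc_interval", "percent_error"]


@dataclass
class NCAResult:
    cmax: float  # µg/mL (== mg/L)
    tmax: float  # h
    auc_last: float  # µg·h/mL
    auc_inf: Optional[float]  # µg·h/mL; None when λz is not estimable
    lambda_z: Optional[float]  # 1/h
    t_half: Optional[float]  # h
    cl_f: Optional[float]  # L/h
    v_f: Optional[float]  # L
    extrap_pct: Optional[float]  # % of auc_inf beyond the last observation
    lambda_z_n_points: int = 0
    lambda_z_estimable: bool = False


def auc_trapezoid(times: np.ndarray, concs: np.ndarray, method: str = "linuplogdown") -> float:
    """AUC over the sampled grid.

    ``linuplogdown``: linear trapezoid on rising or flat segments,
    log-trapezoid on falling segments with both endpoints positive (exact
    for mono-exponential decline).  ``linear``: plain trapezoid.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    lin = 0.5 * (c1 + c2) * dt
    if method == "linear":
        return float(lin.sum())
    if method != "linuplogdown":
        raise ValueError(f"unknown trapezoid method {method!r}")
    down = (c2 < c1) & (c2 > 0) & (c1 > 0)
    seg = lin.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_seg = (c1 - c2) / np.log(c1 / c2) * dt
    seg[down] = log_seg[down]
    return float(seg.sum())


def auc_interval(profile: ConcTimeProfile, t0: float, t1: float, method: str = "linuplogdown") -> float:
    """AUC of a profile over [t0, t1] (grid points assumed to cover the bounds)."""
    sub = profile.slice(t0, t1)
    if sub.times.size < 2:
        raise ValueError("interval contains fewer than two sampled points")
    return auc_trapezoid(sub.times, sub.concentrations, method=method)


def _select_lambda_z(t: np.ndarray, c: np.ndarray):
    """Best-adjusted-R² log-linear terminal fit.

    Candidates are suffixes of the strictly post-Tmax, positive
    concentrations with at least 3 points.  Returns
    ``(lambda_z, n_points, ok)``.
    """
    i_max = int(np.argmax(c))  # earliest maximum (argmax takes first)
    mask = np.arange(t.size) > i_max
    mask &= c > 0
    tt = t[mask]
    yy = np.log(c[mask])
    m = tt.size
    if m < 3:
        return None, 0, False
    # vectorized suffix regressions via reverse cumulative sums
    rt = tt[::-1]
    ry = yy[::-1]
    n = np.arange(1, m + 1, dtype=float)
    sx = np.cumsum(rt)
    sy = np.cumsum(ry)
    sxx = np.cumsum(rt * rt)
    sxy = np.cumsum(rt * ry)
    syy = np.cumsum(ry * ry)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx_c = sxx - sx * sx / n
        syy_c = syy - sy * sy / n
        sxy_c = sxy - sx * sy / n
        slope = sxy_c / sxx_c
        r2 = np.where(syy_c > 0, (sxy_c * sxy_c) / (sxx_c * syy_c), 1.0)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    valid = (n >= 3) & (slope < 0) & np.isfinite(adj)
    if not valid.any():
        return None, 0, False
    adj_v = np.where(valid, adj, -np.inf)
    best = float(np.nanmax(adj_v))
    # ties within 1e-4 of the best go to the longest fit
    candidates = np.flatnonzero(adj_v >= best - 1e-4)
    k = int(candidates.max())
    return float(-slope[k]), int(n[k]), True


def run_nca(
    profile: ConcTimeProfile,
    dose: float,
    route: str = "oral",
    method: str = "linuplogdown",
) -> NCAResult:
    """Non-compartmental parameters of a single-dose profile.

    The profile is expected to start at the dose time (rebase multi-dose
    intervals first).  Requires at least 3 positive concentrations.
    """
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.concentrations, dtype=float)
    if np.count_nonzero(c > 0) < 3:
        raise ValueError("NCA requires at least 3 positive concentrations")
    i_max = int(np.argmax(c))
    cmax = float(c[i_max])
    tmax = float(t[i_max])
    auc_last = auc_trapezoid(t, c, method=method)
    lam, n_pts, ok = _select_lambda_z(t, c)
    if ok:
        c_last = float(c[c > 0][-1])
        auc_inf = auc_last + c_last / lam
        extrap = 100.0 * (auc_inf - auc_last) / auc_inf
        cl_f = dose / auc_inf if dose > 0 else None
        v_f = cl_f / lam if cl_f is not None else None
        t_half = float(np.log(2.0) / lam)
    else:
        auc_inf = extrap = cl_f = v_f = t_half = None
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        auc_last=float(auc_last),
        auc_inf=auc_inf,
        lambda_z=lam,
        t_half=t_half,
        cl_f=cl_f,
        v_f=v_f,
        extrap_pct=extrap,
        lambda_z_n_points=n_pts,
        lambda_z_estimable=ok,
    )


def percent_error(predicted: float, observed: float) -> float:
    """Prediction error 100*(predicted - observed)/observed, 2-decimal rounded."""
    if observed == 0:
        raise ValueError("observed value must be non-zero")
    return round(100.0 * (predicted - observed) / observed, 2)
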