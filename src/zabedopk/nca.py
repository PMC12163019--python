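"""Noncompartmental analysis: λz, AUC/AUMC, single- and multiple-dose parameters.

Conventions follow standard pharmacopeial practice: the default area method is
linear-up/log-down trapezoid, AUC(0-inf) = AUC(0-tlast) + Clast/λz, and the
terminal slope is the best adjusted-R² log-linear regression over contiguous
terminal windows of at least three post-Cmax points (preferring windows
spanning at least two half-lives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LambdaZFit", "NCAResult", "AccumulationResult",
    "fit_lambda_z", "auc_trapezoid", "aumc_trapezoid", "interpolate_conc",
    "nca_single", "nca_multiple", "theoretical_accumulation", "nca_table",
]


@dataclass(frozen=True)
class LambdaZFit:
    lambda_z: float | None   # 1/h
    t_half: float | None     # h
    n_points: int
    r2_adj: float | None
    start_index: int | None  # first point of the regression window
    estimable: bool


@dataclass(frozen=True)
class NCAResult:
    """Per-subject-per-period noncompartmental parameter set (mg, h, L units)."""

    dose: float
    route: str
    cmax: float
    tmax: float
    auc_0_t: float
    auc_inf: float | None = None
    auc_tau: float | None = None
    tau: float | None = None
    lambda_z: float | None = None
    t_half: float | None = None
    cl_f: float | None = None       # CL for IV, CL/F for oral
    vz_f: float | None = None       # Vz for IV, Vz/F for oral
    vss: float | None = None        # IV only
    mrt: float | None = None
    c_av: float | None = None
    c_min: float | None = None
    ptf: float | None = None        # %
    extrapolated_fraction: float | None = None  # %


@dataclass(frozen=True)
class AccumulationResult:
    ra_auc: float
    ra_cmax: float
    r_lin: float

    def __post_init__(self):
        if min(self.ra_auc, self.ra_cmax, self.r_lin) <= 0:
            raise ValueError("accumulation ratios must be positive")


# ---------------------------------------------------------------------------
# terminal slope


def _ols_loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and adjusted R² of ln(c) on t."""
    y = np.log(c)
    n = len(t)
    slope, intercept = np.polyfit(t, y, 1)
    yhat = slope * t + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return float(slope), float(intercept), r2_adj


def fit_lambda_z(times, conc, min_points: int = 3) -> LambdaZFit:
    """Estimate the terminal elimination rate constant λz.

    Considers every contiguous window of >= ``min_points`` positive
    concentrations ending at the last observation and starting after Cmax
    (the Cmax point itself is excluded); picks the best adjusted R², giving
    preference to windows spanning at least two estimated half-lives.
    Returns a non-estimable result when no window yields a negative slope.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    keep = c > 0
    t, c = t[keep], c[keep]
    not_estimable = LambdaZFit(None, None, 0, None, None, False)
    if len(c) < min_points:
        return not_estimable
    imax = int(np.argmax(c))
    # Cmax is excluded from the terminal fit; profiles that start at their
    # maximum (IV bolus without an absorption phase) keep the first point
    start_min = imax + 1 if imax > 0 else 0
    candidates = []
    for start in range(start_min, len(c) - min_points + 1):
        tw, cw = t[start:], c[start:]
        slope, _, r2_adj = _ols_loglinear(tw, cw)
        if slope >= -1e-12:
            continue
        lz = -slope
        span_ok = (tw[-1] - tw[0]) >= 2.0 * math.log(2.0) / lz
        candidates.append((span_ok, r2_adj, len(tw), lz, start))
    if not candidates:
        return not_estimable
    spanning = [cand for cand in candidates if cand[0]]
    pool = spanning if spanning else candidates
    # best adjusted R²; ties broken toward more points
    _, r2_adj, n, lz, start = max(pool, key=lambda cand: (cand[1], cand[2]))
    return LambdaZFit(lz, math.log(2.0) / lz, n, r2_adj, start, True)


# ---------------------------------------------------------------------------
# areas


def _segment_areas(t1, c1, t2, c2, method):
    dt = t2 - t1
    logdown = method == "linuplogdown" and c2 < c1 and c1 > 0 and c2 > 0
    if logdown:
        k = math.log(c1 / c2) / dt
        auc = (c1 - c2) / k
        aumc = (t1 * c1 - t2 * c2) / k + (c1 - c2) / k ** 2
    else:
        auc = 0.5 * (c1 + c2) * dt
        aumc = 0.5 * (t1 * c1 + t2 * c2) * dt
    return auc, aumc


def auc_trapezoid(times, conc, method: str = "linuplogdown") -> float:
    """AUC by trapezoid; ``method`` is 'linuplogdown', 'linear' or 'log'."""
    return _areas(times, conc, method)[0]


def aumc_trapezoid(times, conc, method: str = "linuplogdown") -> float:
    return _areas(times, conc, method)[1]


def _areas(times, conc, method):
    if method not in ("linuplogdown", "linear", "log"):
        raise ValueError(f"unknown AUC method {method!r}")
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    auc = aumc = 0.0
    for i in range(len(t) - 1):
        m = method
        if method == "log":
            # pure-log where possible, linear fallback on zero/equal values
            m = "linuplogdown" if c[i + 1] < c[i] and c[i + 1] > 0 else "linear"
        a, b = _segment_areas(t[i], c[i], t[i + 1], c[i + 1], m)
        auc += a
        aumc += b
    return auc, aumc


def interpolate_conc(times, conc, ti: float, method: str = "linuplogdown") -> float:
    """Concentration at ``ti`` using the interpolation rule matching the AUC method."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if ti <= t[0]:
        return float(c[0])
    if ti >= t[-1]:
        return float(c[-1])
    j = int(np.searchsorted(t, ti, side="right"))
    t1, t2, c1, c2 = t[j - 1], t[j], c[j - 1], c[j]
    if method == "linuplogdown" and c2 < c1 and c1 > 0 and c2 > 0:
        k = math.log(c1 / c2) / (t2 - t1)
        return float(c1 * math.exp(-k * (ti - t1)))
    return float(c1 + (c2 - c1) * (ti - t1) / (t2 - t1))


# ---------------------------------------------------------------------------
# single dose


def nca_single(times, conc, dose: float, route: str = "oral",
               auc_method: str = "linuplogdown") -> NCAResult:
    """Single-dose NCA.

    For IV profiles whose first sample is after t=0, C(0) is back-extrapolated
    log-linearly from the first two positive samples (standard bolus handling)
    before computing areas. When λz is not estimable the extrapolated fields
    (AUC(0-inf), CL/F, Vz/F, MRT, t½) are absent.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    order = np.argsort(t)
    t, c = t[order], c[order]
    if dose <= 0:
        raise ValueError("dose must be positive")
    if route == "iv" and t[0] > 0:
        pos = np.nonzero(c > 0)[0]
        if len(pos) >= 2 and c[pos[0]] > c[pos[1]]:
            k0 = math.log(c[pos[0]] / c[pos[1]]) / (t[pos[1]] - t[pos[0]])
            c0 = c[pos[0]] * math.exp(k0 * t[pos[0]])
        else:
            c0 = c[pos[0]] if len(pos) else 0.0
        t = np.insert(t, 0, 0.0)
        c = np.insert(c, 0, c0)

    icmax = int(np.argmax(c))
    cmax, tmax = float(c[icmax]), float(t[icmax])
    auc_0_t, aumc_0_t = _areas(t, c, auc_method)
    lz = fit_lambda_z(t, c)

    pos = np.nonzero(c > 0)[0]
    tlast, clast = (float(t[pos[-1]]), float(c[pos[-1]])) if len(pos) else (t[-1], 0.0)

    if not lz.estimable or clast <= 0:
        return NCAResult(dose=dose, route=route, cmax=cmax, tmax=tmax,
                         auc_0_t=auc_0_t)
    k = lz.lambda_z
    auc_inf = auc_0_t + clast / k
    aumc_inf = aumc_0_t + clast * tlast / k + clast / k ** 2
    cl_f = dose / auc_inf
    vz_f = cl_f / k
    mrt = aumc_inf / auc_inf
    vss = cl_f * mrt if route == "iv" else None
    return NCAResult(
        dose=dose, route=route, cmax=cmax, tmax=tmax,
        auc_0_t=auc_0_t, auc_inf=auc_inf, lambda_z=k, t_half=lz.t_half,
        cl_f=cl_f, vz_f=vz_f, vss=vss, mrt=mrt,
        extrapolated_fraction=100.0 * (auc_inf - auc_0_t) / auc_inf,
    )


# ---------------------------------------------------------------------------
# multiple dose


def nca_multiple(times_ss, conc_ss, times_sd, conc_sd, dose: float, tau: float,
                 auc_method: str = "linuplogdown") -> tuple[NCAResult, AccumulationResult]:
    """Multiple-dose NCA over one steady-state dosing interval.

    ``times_ss`` are hours after the steady-state dose (must cover [0, tau]);
    the single-dose profile supplies AUCτ after the first dose and AUC(0-inf)
    for the accumulation ratio RA_AUC and linearity factor R_LIN. Cmin for the
    peak-trough fluctuation is the minimum within the interval.
    """
    t_ss = np.asarray(times_ss, dtype=float)
    c_ss = np.asarray(conc_ss, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if t_ss[-1] < tau - 1e-9:
        raise ValueError(f"steady-state interval not fully sampled up to tau={tau}")

    def _interval(t, c):
        inside = t <= tau + 1e-9
        ti, ci = t[inside], c[inside]
        if ti[-1] < tau - 1e-9:
            ti = np.append(ti, tau)
            ci = np.append(ci, interpolate_conc(t, c, tau, auc_method))
        return ti, ci

    ti, ci = _interval(t_ss, c_ss)
    auc_tau = auc_trapezoid(ti, ci, auc_method)
    cmax = float(np.max(ci))
    tmax = float(ti[int(np.argmax(ci))])
    cmin = float(np.min(ci))
    c_av = auc_tau / tau
    ptf = 100.0 * (cmax - cmin) / c_av

    sd = nca_single(times_sd, conc_sd, dose, auc_method=auc_method)
    t_sd = np.asarray(times_sd, dtype=float)
    c_sd = np.asarray(conc_sd, dtype=float)
    if t_sd[-1] < tau - 1e-9:
        raise ValueError("single-dose profile does not cover one dosing interval")
    tj, cj = _interval(t_sd, c_sd)
    auc_tau_sd = auc_trapezoid(tj, cj, auc_method)
    if auc_tau_sd <= 0 or sd.cmax <= 0:
        raise ValueError("degenerate single-dose profile")

    lz = fit_lambda_z(t_ss, c_ss)
    cl_f = dose / auc_tau
    result = NCAResult(
        dose=dose, route="oral", cmax=cmax, tmax=tmax,
        auc_0_t=auc_trapezoid(t_ss, c_ss, auc_method),
        auc_tau=auc_tau, tau=tau,
        lambda_z=lz.lambda_z, t_half=lz.t_half,
        cl_f=cl_f, vz_f=(cl_f / lz.lambda_z if lz.estimable else None),
        c_av=c_av, c_min=cmin, ptf=ptf,
    )
    acc = AccumulationResult(
        ra_auc=auc_tau / auc_tau_sd,
        ra_cmax=cmax / sd.cmax,
        r_lin=(auc_tau / sd.auc_inf) if sd.auc_inf else float("nan"),
    )
    return result, acc


def theoretical_accumulation(t_half: float, tau: float) -> float:
    """Linear-superposition AUC accumulation ratio, 1 / (1 - 2^(-tau/t_half)).

    The value expected for a linear time-invariant model with terminal
    half-life ``t_half`` dosed every ``tau`` hours.
    """
    if t_half <= 0 or tau <= 0:
        raise ValueError("t_half and tau must be positive")
    return 1.0 / (1.0 - 2.0 ** (-tau / t_half))


# ---------------------------------------------------------------------------
# dataset-level driver


def nca_table(dataset, analyte: str = "total", route_by_analyte: dict | None = None):
    """Single-dose NCA for every subject/period of a dataset -> DataFrame."""
    import pandas as pd

    route_by_analyte = route_by_analyte or {"tracer": "iv"}
    rows = []
    for sid in dataset.subject_ids():
        for period in dataset.periods(sid):
            doses = dataset.doses.get((sid, period), ())
            if not doses:
                continue
            route = route_by_analyte.get(analyte, "oral")
            evs = [ev for ev in doses if ev.route == route]
            if not evs:
                continue
            t, c = dataset.profile(sid, period, analyte)
            if len(t) < 3:
                continue
            amount = sum(ev.amount for ev in evs)
            res = nca_single(t, c, amount, route=route)
            row = {"subject": sid, "period": period, "analyte": analyte,
                   "food_state": evs[0].food_state, "regimen": evs[0].regimen_tag}
            row.update({k: getattr(res, k) for k in (
                "dose", "cmax", "tmax", "auc_0_t", "auc_inf", "lambda_z",
                "t_half", "cl_f", "vz_f", "vss", "mrt", "extrapolated_fraction")})
            rows.append(row)
    df = pd.DataFrame(rows)
    numeric = [c for c in df.columns
               if c not in ("subject", "analyte", "food_state", "regimen")]
    return df.astype({c: float for c in numeric})
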