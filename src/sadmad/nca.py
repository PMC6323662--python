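"""Non-compartmental pharmacokinetic analysis.

Model-free PK parameters from a concentration--time series: Cmax/tmax,
trapezoidal AUC to the last quantifiable concentration (linear or
linear-up/log-down), terminal-slope (lambda-z) estimation by best adjusted
R-squared over suffix windows, extrapolation to infinity, apparent clearance
and volume, accumulation ratio, bioavailability, geometric-mean summaries and
a power-model dose-proportionality assessment.

Undefined parameters propagate as NaN with a text reason, never exceptions,
so cohort summaries can drop them with an ``n`` annotation.

A terminal fit is reported but flagged invalid when the time spanned by the
selected window is less than twice the estimated half-life — such profiles
are excluded from half-life-dependent summaries, mirroring standard
regulatory NCA practice for long-half-life biologics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LambdaZFit",
    "NCAResult",
    "SummaryStat",
    "DoseProportionalityResult",
    "compute_cmax_tmax",
    "compute_auc_0_t",
    "fit_lambda_z",
    "extrapolate_auc_inf",
    "compute_cl_v",
    "compute_accumulation",
    "estimate_bioavailability",
    "summarize_parameter",
    "assess_dose_proportionality",
    "run_nca_profile",
    "nca_subject_table",
    "nca_summary_table",
]

NO_QUANTIFIABLE = "no quantifiable concentrations"
TOO_FEW_POINTS = "fewer than min_points quantifiable post-peak points"
NONNEG_SLOPE = "nonnegative terminal slope"
SPAN_RULE = "time spanned less than twice the estimated t_half"


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression diagnostics."""

    kel: float = math.nan  # 1/day
    t_half: float = math.nan  # days
    n_points: int = 0
    r2_adjusted: float = math.nan
    time_span: float = math.nan  # days
    valid: bool = False
    reason: str = ""


@dataclass
class NCAResult:
    """Per-subject, per-profile NCA parameter set (NaN where undefined)."""

    cmax: float = math.nan  # ng/mL
    tmax: float = math.nan  # day
    auc_0_t: float = math.nan  # day*ng/mL
    auc_0_inf: float = math.nan
    pct_extrap: float = math.nan  # %
    kel: float = math.nan
    t_half: float = math.nan
    cl_over_f: float = math.nan  # L/day (CL for IV)
    v_over_f: float = math.nan  # L (V for IV)
    lambda_fit: LambdaZFit = field(default_factory=LambdaZFit)
    route: str = ""
    reason: str = ""


@dataclass(frozen=True)
class SummaryStat:
    n: int
    geometric_mean: float
    cv_pct: float
    arithmetic_mean: float
    sd: float
    median: float
    min: float
    max: float


@dataclass(frozen=True)
class DoseProportionalityResult:
    parameter: str
    slope: float
    ci_low: float
    ci_high: float
    dose_proportional: bool
    per_dose_geometric_means: dict


def _clean(times, conc, blq=None):
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if blq is None:
        blq = conc <= 0
    blq = np.asarray(blq, dtype=bool)
    order = np.argsort(times, kind="stable")
    return times[order], conc[order], blq[order]


def compute_cmax_tmax(times, conc, blq=None) -> tuple[float, float, str]:
    """Maximum observed concentration and its time; ties go to the earliest.

    Returns ``(nan, nan, reason)`` for an all-BLQ series.
    """
    times, conc, blq = _clean(times, conc, blq)
    quant = ~blq & (conc > 0)
    if not quant.any():
        return math.nan, math.nan, NO_QUANTIFIABLE
    i = int(np.argmax(conc))  # argmax returns the first (earliest) maximum
    return float(conc[i]), float(times[i]), ""


def _analysis_points(times, conc, blq):
    """Points entering AUC: leading BLQ kept as zeros, embedded BLQ dropped,
    series truncated at the last quantifiable concentration."""
    quant = ~blq & (conc > 0)
    if not quant.any():
        return times[:0], conc[:0]
    first_q = int(np.argmax(quant))
    last_q = len(quant) - 1 - int(np.argmax(quant[::-1]))
    keep = np.zeros(len(times), dtype=bool)
    keep[: first_q + 1] = True  # leading BLQ as zero-valued points
    keep[first_q : last_q + 1] = quant[first_q : last_q + 1]
    keep[last_q + 1 :] = False
    t = times[keep]
    c = np.where(blq[keep], 0.0, conc[keep])
    return t, c


def compute_auc_0_t(times, conc, blq=None, method: str = "lin_up_log_down") -> tuple[float, str]:
    """Trapezoidal AUC from the first sample to the last quantifiable one.

    ``lin_up_log_down`` uses the logarithmic trapezoid on strictly decreasing
    positive segments and the linear rule elsewhere.
    """
    if method not in ("linear", "lin_up_log_down"):
        raise ValueError(f"unknown AUC method {method!r}")
    times, conc, blq = _clean(times, conc, blq)
    t, c = _analysis_points(times, conc, blq)
    if (c > 0).sum() < 2:
        return math.nan, "fewer than 2 quantifiable points"
    auc = 0.0
    for (t1, c1), (t2, c2) in zip(zip(t, c), zip(t[1:], c[1:])):
        dt = t2 - t1
        dlog = math.log(c1) - math.log(c2) if c1 > 0 and c2 > 0 else 0.0
        if method == "lin_up_log_down" and c1 > c2 > 0 and dlog > 1e-12:
            auc += dt * (c1 - c2) / dlog
        else:
            # linear rule; also the correct limit for an effectively flat segment
            auc += dt * (c1 + c2) / 2.0
    return float(auc), ""


def fit_lambda_z(times, conc, blq=None, min_points: int = 3) -> LambdaZFit:
    """Terminal elimination rate by OLS on ln(C) vs t.

    Candidate windows are all suffixes of quantifiable points strictly after
    tmax (the peak itself excluded) with at least ``min_points`` points; the
    window with the largest adjusted R-squared wins, ties broken toward more
    points.  The fit is flagged invalid when the window's time span is less
    than twice the implied half-life, or when the slope is nonnegative.
    """
    times, conc, blq = _clean(times, conc, blq)
    quant = ~blq & (conc > 0)
    t_all, c_all = times[quant], conc[quant]
    if len(t_all) == 0:
        return LambdaZFit(reason=NO_QUANTIFIABLE)
    i_max = int(np.argmax(c_all))
    t_post, c_post = t_all[i_max + 1 :], c_all[i_max + 1 :]
    if len(t_post) < min_points:
        # a profile still rising at its end has no declining terminal phase
        if i_max == len(c_all) - 1 and len(c_all) >= min_points:
            return LambdaZFit(n_points=len(t_post), reason=NONNEG_SLOPE)
        return LambdaZFit(n_points=len(t_post), reason=TOO_FEW_POINTS)
    best: tuple[float, int, float] | None = None  # (adj_r2, n, slope)
    logc = np.log(c_post)
    for start in range(0, len(t_post) - min_points + 1):
        tt, yy = t_post[start:], logc[start:]
        n = len(tt)
        res = sps.linregress(tt, yy)
        if res.slope >= 0:
            continue
        r2 = res.rvalue**2
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        if best is None or adj > best[0] + 1e-4 or (abs(adj - best[0]) <= 1e-4 and n > best[1]):
            best = (adj, n, res.slope, tt)
    if best is None:
        return LambdaZFit(n_points=len(t_post), reason=NONNEG_SLOPE)
    adj, n, slope, tt = best
    kel = -float(slope)
    t_half = math.log(2) / kel
    span = float(tt[-1] - tt[0])
    valid = span >= 2.0 * t_half
    return LambdaZFit(
        kel=kel,
        t_half=t_half,
        n_points=n,
        r2_adjusted=float(adj),
        time_span=span,
        valid=valid,
        reason="" if valid else SPAN_RULE,
    )


def extrapolate_auc_inf(auc_0_t: float, c_last: float, fit: LambdaZFit) -> tuple[float, float]:
    """AUC to infinity (= AUC0-t + Clast/kel) and the extrapolated percentage."""
    if not fit.valid or not np.isfinite(auc_0_t) or c_last <= 0:
        return math.nan, math.nan
    auc_inf = auc_0_t + c_last / fit.kel
    pct = 100.0 * (auc_inf - auc_0_t) / auc_inf
    return float(auc_inf), float(pct)


def compute_cl_v(dose_mg: float, auc_0_inf: float, fit: LambdaZFit, route: str) -> tuple[float, float]:
    """Apparent clearance (L/day) and volume (L); true CL and V for IV.

    Dose is converted mg -> ng so that dose/AUC comes out in mL/day, then
    reported in L/day.
    """
    if not np.isfinite(auc_0_inf) or auc_0_inf <= 0 or not fit.valid:
        return math.nan, math.nan
    cl_ml_day = dose_mg * 1e6 / auc_0_inf
    cl = cl_ml_day / 1000.0
    return float(cl), float(cl / fit.kel)


def compute_accumulation(series_day1, series_later) -> float:
    """Accumulation ratio Rac(Cmax): Cmax after a later dose / Cmax after dose 1.

    Each series is (times, conc) or (times, conc, blq).
    """
    c1, _, r1 = compute_cmax_tmax(*series_day1)
    c2, _, r2 = compute_cmax_tmax(*series_later)
    if r1 or r2:
        return math.nan
    return float(c2 / c1)


def _gmean(values) -> float:
    values = np.asarray(values, dtype=float)
    return float(np.exp(np.mean(np.log(values))))


def estimate_bioavailability(sc_aucs, iv_aucs, sc_dose_mg: float, iv_dose_mg: float) -> float:
    """Absolute bioavailability F = GM(AUCinf, SC) / GM(AUCinf, IV) at matched dose."""
    if sc_dose_mg != iv_dose_mg:
        raise ValueError(f"dose levels must match (SC {sc_dose_mg} mg vs IV {iv_dose_mg} mg)")
    sc = np.asarray(sc_aucs, dtype=float)
    iv = np.asarray(iv_aucs, dtype=float)
    sc, iv = sc[np.isfinite(sc)], iv[np.isfinite(iv)]
    if len(sc) == 0 or len(iv) == 0:
        return math.nan
    return _gmean(sc) / _gmean(iv)


def summarize_parameter(values, scale: str = "geometric", labels=None) -> SummaryStat:
    """Cohort summary of one parameter.

    Geometric scale: GM mean with CV% = 100*sqrt(exp(s^2)-1) where s is the
    SD of log values.  Arithmetic scale: mean with CV% = 100*sd/mean.
    NaN values (undefined parameters) are dropped; ``n`` reflects the kept
    sample.
    """
    if scale not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown scale {scale!r}")
    raw = np.asarray(values, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(len(raw))]
    keep = np.isfinite(raw)
    vals = raw[keep]
    kept_labels = [l for l, k in zip(labels, keep) if k]
    if len(vals) == 0:
        raise ValueError("no defined values to summarize")
    if scale == "geometric":
        bad = [l for l, v in zip(kept_labels, vals) if v <= 0]
        if bad:
            raise ValueError(f"geometric summary requires positive values; offending subject(s): {bad}")
        logs = np.log(vals)
        gm = float(np.exp(logs.mean()))
        s2 = float(logs.var(ddof=1)) if len(vals) > 1 else 0.0
        cv = 100.0 * math.sqrt(math.expm1(s2))
    else:
        gm = float(np.exp(np.mean(np.log(vals)))) if (vals > 0).all() else math.nan
        mean = float(vals.mean())
        cv = 100.0 * float(vals.std(ddof=1)) / mean if len(vals) > 1 and mean != 0 else 0.0
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    if scale == "geometric":
        pass
    return SummaryStat(
        n=int(len(vals)),
        geometric_mean=gm,
        cv_pct=float(cv),
        arithmetic_mean=mean,
        sd=sd,
        median=float(np.median(vals)),
        min=float(vals.min()),
        max=float(vals.max()),
    )


def assess_dose_proportionality(doses, values, parameter: str = "") -> DoseProportionalityResult:
    """Power-model fit ln(param) = a + b*ln(dose) with a 95% CI on b.

    The parameter is flagged approximately dose-proportional when the CI
    contains 1.  With zero residual degrees of freedom (a saturated fit) the
    CI degenerates to the point estimate.
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values) & (values > 0) & (doses > 0)
    doses, values = doses[keep], values[keep]
    levels = np.unique(doses)
    if len(levels) < 2:
        raise ValueError("dose-proportionality assessment needs >= 2 distinct dose levels")
    x, y = np.log(doses), np.log(values)
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(x)).fit()
    b = float(model.params[1])
    if model.df_resid > 0 and model.ssr > 1e-24:
        lo, hi = (float(v) for v in model.conf_int(alpha=0.05)[1])
    else:
        lo = hi = b
    gms = {float(d): _gmean(values[doses == d]) for d in levels}
    return DoseProportionalityResult(
        parameter=parameter,
        slope=b,
        ci_low=lo,
        ci_high=hi,
        dose_proportional=bool(lo - 1e-9 <= 1.0 <= hi + 1e-9),
        per_dose_geometric_means=gms,
    )


# ---------------------------------------------------------------------------
# Dataset-level orchestration
# ---------------------------------------------------------------------------

def run_nca_profile(
    times,
    conc,
    blq=None,
    dose_mg: float = math.nan,
    route: str = "SC",
    method: str = "lin_up_log_down",
    min_points: int = 3,
) -> NCAResult:
    """Full NCA for one dose profile (times in days post that dose)."""
    res = NCAResult(route=route)
    res.cmax, res.tmax, reason = compute_cmax_tmax(times, conc, blq)
    if reason:
        res.reason = reason
        return res
    res.auc_0_t, auc_reason = compute_auc_0_t(times, conc, blq, method=method)
    fit = fit_lambda_z(times, conc, blq, min_points=min_points)
    res.lambda_fit = fit
    if fit.kel == fit.kel:  # not NaN: report even when flagged invalid
        res.kel, res.t_half = fit.kel, fit.t_half
    t_arr, c_arr, b_arr = _clean(times, conc, blq)
    quant = ~b_arr & (c_arr > 0)
    c_last = float(c_arr[quant][-1]) if quant.any() else math.nan
    if np.isfinite(res.auc_0_t):
        res.auc_0_inf, res.pct_extrap = extrapolate_auc_inf(res.auc_0_t, c_last, fit)
        res.cl_over_f, res.v_over_f = compute_cl_v(dose_mg, res.auc_0_inf, fit, route)
    res.reason = auc_reason or fit.reason
    return res


def _result_row(sid, cohort, profile, dose_mg, r: NCAResult) -> dict:
    return {
        "subject_id": sid,
        "cohort": cohort,
        "profile": profile,
        "dose_mg": dose_mg,
        "route": r.route,
        "cmax_ng_ml": r.cmax,
        "tmax_day": r.tmax,
        "auc_0_t": r.auc_0_t,
        "auc_0_inf": r.auc_0_inf,
        "pct_extrap": r.pct_extrap,
        "kel_per_day": r.kel,
        "t_half_day": r.t_half,
        "cl_over_f_l_day": r.cl_over_f,
        "v_over_f_l": r.v_over_f,
        "lambda_n_points": r.lambda_fit.n_points,
        "lambda_r2_adj": r.lambda_fit.r2_adjusted,
        "lambda_span_day": r.lambda_fit.time_span,
        "lambda_valid": r.lambda_fit.valid,
        "reason": r.reason,
    }


def nca_subject_table(
    pk_conc: pd.DataFrame,
    dosing: pd.DataFrame,
    subjects: pd.DataFrame,
    method: str = "lin_up_log_down",
    min_points: int = 3,
) -> pd.DataFrame:
    """Per-subject NCA over all dosed subjects.

    Single-dose subjects yield one ``day1`` profile.  Multiple-dose subjects
    yield a ``day1`` profile (samples up to the second dose) and a profile
    for the final administered dose (samples from that dose onward,
    re-referenced to the dose time), plus the Cmax accumulation ratio.
    """
    rows = []
    cohort_of = dict(zip(subjects["subject_id"], subjects["cohort"]))
    for sid, doses in dosing.groupby("subject_id"):
        doses = doses.sort_values("day")
        sconc = pk_conc[pk_conc["subject_id"] == sid].sort_values("day_decimal")
        if sconc.empty:
            continue
        t = sconc["day_decimal"].to_numpy(dtype=float) - 1.0
        c = sconc["conc_ng_ml"].to_numpy(dtype=float)
        b = sconc["blq_flag"].to_numpy(dtype=bool)
        route = doses["route"].iloc[0]
        dose_mg = float(doses["dose_mg"].iloc[0])
        dose_times = doses["day"].to_numpy(dtype=float) - 1.0
        cohort = cohort_of.get(sid, "")
        if len(dose_times) == 1:
            r = run_nca_profile(t, c, b, dose_mg, route, method, min_points)
            rows.append(_result_row(sid, cohort, "day1", dose_mg, r) | {"rac_cmax": math.nan})
        else:
            first_mask = t <= dose_times[1]
            r1 = run_nca_profile(t[first_mask], c[first_mask], b[first_mask], dose_mg, route, method, min_points)
            t_last = dose_times[-1]
            last_mask = t >= t_last
            rl = run_nca_profile(
                t[last_mask] - t_last, c[last_mask], b[last_mask], dose_mg, route, method, min_points
            )
            rac = rl.cmax / r1.cmax if np.isfinite(rl.cmax) and np.isfinite(r1.cmax) else math.nan
            last_day = int(t_last + 1)
            rows.append(_result_row(sid, cohort, "day1", dose_mg, r1) | {"rac_cmax": math.nan})
            rows.append(_result_row(sid, cohort, f"day{last_day}", dose_mg, rl) | {"rac_cmax": rac})
    return pd.DataFrame(rows)


_GEOMETRIC_PARAMS = ("cmax_ng_ml", "auc_0_t", "auc_0_inf")
_ARITHMETIC_PARAMS = ("pct_extrap", "kel_per_day", "t_half_day", "cl_over_f_l_day", "v_over_f_l", "rac_cmax")


def nca_summary_table(nca_subject: pd.DataFrame) -> pd.DataFrame:
    """Cohort x profile x parameter summary (GM/CV% for exposure parameters,
    arithmetic mean/CV% for rate-type parameters, median/range for tmax).

    Half-life-dependent parameters are summarized only over subjects whose
    terminal fit passed the span-validity rule.
    """
    rows = []
    for (cohort, profile), grp in nca_subject.groupby(["cohort", "profile"]):
        for param in _GEOMETRIC_PARAMS + _ARITHMETIC_PARAMS:
            if param not in grp:
                continue
            vals = grp[param].to_numpy(dtype=float)
            if param in ("kel_per_day", "t_half_day", "cl_over_f_l_day", "v_over_f_l"):
                vals = np.where(grp["lambda_valid"].to_numpy(dtype=bool), vals, np.nan)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            scale = "geometric" if param in _GEOMETRIC_PARAMS else "arithmetic"
            s = summarize_parameter(vals, scale=scale)
            rows.append(
                {
                    "cohort": cohort,
                    "profile": profile,
                    "parameter": param,
                    "n": s.n,
                    "geometric_mean": s.geometric_mean,
                    "cv_pct": s.cv_pct,
                    "arithmetic_mean": s.arithmetic_mean,
                    "sd": s.sd,
                    "median": s.median,
                    "min": s.min,
                    "max": s.max,
                }
            )
        tm = grp["tmax_day"].to_numpy(dtype=float)
        tm = tm[np.isfinite(tm)]
        if len(tm):
            rows.append(
                {
                    "cohort": cohort,
                    "profile": profile,
                    "parameter": "tmax_day",
                    "n": len(tm),
                    "geometric_mean": math.nan,
                    "cv_pct": math.nan,
                    "arithmetic_mean": float(tm.mean()),
                    "sd": float(tm.std(ddof=1)) if len(tm) > 1 else 0.0,
                    "median": float(np.median(tm)),
                    "min": float(tm.min()),
                    "max": float(tm.max()),
                }
            )
    return pd.DataFrame(rows)
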