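"""Nonlinear least-squares fits for death kinetics and protein decay.

The central model is the lag-exponential death (LED) curve for lethal
fraction kinetics,

    LF(t) = LF0 + (LFP − LF0) · (1 − exp(−DR · (t − DO)))   for t ≥ DO,
    LF(t) = LF0                                              for t < DO,

with baseline lethal fraction LF0, plateau LFP, initial death rate DR
(per hour) and death-onset time DO (hours).  The curve is held constant at
LF0 before onset: the raw exponential would dip below the baseline before
DO, contradicting the lag interpretation.

Also here: the two-term exponential decay fit used for protein half-lives
(hypophosphorylated Pol IIA and hyperphosphorylated Pol IIO immunoblot
courses), the 4-parameter Hill fit for EU-incorporation loss, the standard
4-parameter sigmoid dose-response fit, and the regression coupling protein
decay half-life to death-onset timing (LF50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LEDFit",
    "DecayFit",
    "HillFit",
    "Sigmoid4Fit",
    "OnsetCoupling",
    "led_eval",
    "fit_led",
    "lf50_from_led",
    "led_auc",
    "fit_exp2_decay",
    "fit_hill4_eu",
    "fit_sigmoid4",
    "onset_coupling",
]

# Stopping tolerances shared by every fit in this module.
FIT_XTOL = 1e-8
FIT_MAX_NFEV = 10_000
DEFAULT_HORIZON_H = 72.0


@dataclass
class LEDFit:
    """Fitted lag-exponential death parameters plus derived quantities."""

    lf0: float
    lfp: float
    dr: float
    do: float
    converged: bool = True
    residual_sse: float = np.nan
    max_observed_lf: float = np.nan
    lf50: float = np.nan
    auc: float = np.nan

    def __call__(self, t):
        return led_eval(t, self.lf0, self.lfp, self.dr, self.do)


def led_eval(t, lf0: float, lfp: float, dr: float, do: float):
    """Evaluate the LED curve; constant at ``lf0`` before onset."""
    t = np.asarray(t, dtype=float)
    out = lf0 + (lfp - lf0) * -np.expm1(-dr * np.clip(t - do, 0.0, None))
    return out if out.ndim else float(out)


def _led_residuals(params, t, lf):
    lf0, dlf, dr, do = params
    return led_eval(t, lf0, lf0 + dlf, dr, do) - lf


def fit_led(times, lf) -> LEDFit:
    """Fit the LED curve to a lethal-fraction time series.

    Bounded least squares with 0 ≤ LF0 ≤ LFP ≤ 1 (enforced by fitting the
    rise LFP − LF0 ≥ 0), DR > 0, DO ≥ 0.  Multi-start over onset candidates:
    the observed times of maximal finite-difference LF slope plus the
    quartiles of the time range; DR is seeded from the maximal
    finite-difference slope.  Best SSE wins; ties go to the smallest DO.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(lf, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 6:
        raise ValueError("LED fit requires at least 6 timepoints")

    max_obs = float(np.max(y))
    slopes = np.diff(y) / np.diff(t)
    lf0_init = float(np.clip(np.min(y[: max(2, len(y) // 4)]), 0.0, 1.0))
    rise = max(max_obs - lf0_init, 1e-3)
    dr_init = float(np.clip(np.max(slopes, initial=0.0) / rise, 1e-3, 10.0))

    # Onset candidates: steepest-slope times plus quartiles of the window.
    order = np.argsort(slopes)[::-1]
    steep_times = [float(t[i]) for i in order[:3]]
    quartiles = list(np.quantile(t, [0.0, 0.25, 0.5, 0.75]))
    do_candidates = sorted({round(c, 6) for c in steep_times + quartiles if c >= 0})

    t_max = float(t[-1])
    bounds = ([0.0, 0.0, 1e-6, 0.0], [1.0, 1.0, 50.0, t_max])
    best = None
    for do0 in do_candidates:
        x0 = np.clip(
            [lf0_init, rise, dr_init, do0],
            bounds[0],
            np.nextafter(bounds[1], -np.inf),
        )
        try:
            res = optimize.least_squares(
                _led_residuals,
                x0,
                bounds=bounds,
                args=(t, y),
                xtol=FIT_XTOL,
                ftol=FIT_XTOL,
                gtol=FIT_XTOL,
                max_nfev=FIT_MAX_NFEV,
            )
        except Exception:
            continue
        if not res.success:
            continue
        sse = float(2.0 * res.cost)
        cand = (sse, float(res.x[3]), res.x)
        if best is None or cand[:2] < best[:2]:
            best = cand

    if best is None:
        return LEDFit(np.nan, np.nan, np.nan, np.nan, converged=False, max_observed_lf=max_obs)

    lf0, dlf, dr, do = best[2]
    fit = LEDFit(
        lf0=float(lf0),
        lfp=float(lf0 + dlf),
        dr=float(dr),
        do=float(do),
        converged=True,
        residual_sse=best[0],
        max_observed_lf=max_obs,
    )
    fit.max_observed_lf = max(max_obs, float(fit(max(DEFAULT_HORIZON_H, t_max))))
    fit.lf50 = lf50_from_led(fit, horizon=max(DEFAULT_HORIZON_H, t_max), observed_max=max_obs)
    fit.auc = led_auc(fit, t_max)
    return fit


def lf50_from_led(
    fit: LEDFit,
    horizon: float = DEFAULT_HORIZON_H,
    observed_max: float | None = None,
    tol: float = 1e-6,
) -> float:
    """Time at which half of the maximum observed lethal fraction is reached.

    The maximum is the larger of the measured maximum LF and the fitted
    curve evaluated at the horizon (default 72 h) — "measured or inferred".
    Returns NaN when the curve never rises above its baseline (no death).
    """
    if not fit.converged:
        return np.nan
    max_lf = float(fit(horizon))
    if observed_max is not None and np.isfinite(observed_max):
        max_lf = max(max_lf, float(observed_max))
    target = 0.5 * max_lf
    if max_lf <= fit.lf0 + 1e-12 or target <= fit.lf0:
        # Curve at/below baseline, or the half-max is already exceeded at t=0.
        return np.nan if max_lf <= fit.lf0 + 1e-12 else 0.0
    lo, hi = fit.do, horizon
    if fit(hi) < target:
        return np.nan
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fit(mid) >= target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def led_auc(fit: LEDFit, t_end: float, t_start: float = 0.0) -> float:
    """Analytic area under the LED curve over ``[t_start, t_end]``.

    For T > DO the integral is
    ``LF0·T + (LFP−LF0)·[(T−DO) − (1 − exp(−DR(T−DO)))/DR]``
    (with T measured from 0); before onset the curve is the constant LF0.
    """
    if t_start != 0.0:
        return led_auc(fit, t_end) - led_auc(fit, t_start)
    T = float(t_end)
    if T <= 0:
        raise ValueError("AUC window must have positive length")
    base = fit.lf0 * T
    if T <= fit.do:
        return base
    dt = T - fit.do
    return base + (fit.lfp - fit.lf0) * (dt - (-math.expm1(-fit.dr * dt)) / fit.dr)


# ---------------------------------------------------------------------------
# Two-term exponential protein decay


@dataclass
class DecayFit:
    """Two-term exponential decay fit ``a·exp(b t) + c·exp(d t)`` with b, d ≤ 0."""

    a: float
    b: float
    c: float
    d: float
    t_half: float = np.nan
    converged: bool = True
    residual_sse: float = np.nan

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.a * np.exp(self.b * t) + self.c * np.exp(self.d * t)
        return out if out.ndim else float(out)


def fit_exp2_decay(times, signal, t_half_search_h: float = 1000.0) -> DecayFit:
    """Fit a two-term exponential decay to a normalized intensity course.

    The signal is expected pre-normalized so its maximum is 1 (relative to
    the highest observed signal).  The half-life is the earliest time at
    which the fitted curve first crosses half of its own maximum — the first
    downward crossing, which guards against non-monotonic two-term fits.  If
    the crossing lies beyond the observed window it is extrapolated from the
    fit; if the curve never reaches half-maximum the half-life is infinite.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 5:
        raise ValueError("decay fit requires at least 5 timepoints")

    span = max(t[-1] - t[0], 1e-6)
    rate0 = math.log(2.0) / (0.25 * span)

    def residuals(p):
        a, b, c, d = p
        return a * np.exp(b * t) + c * np.exp(d * t) - y

    best = None
    # Two starts: near-single-exponential and split fast/slow components.
    for x0 in ([0.9, -rate0, 0.1, -0.01 * rate0], [0.5, -4.0 * rate0, 0.5, -0.25 * rate0]):
        try:
            res = optimize.least_squares(
                residuals,
                x0,
                bounds=([0.0, -np.inf, 0.0, -np.inf], [2.0, 0.0, 2.0, 0.0]),
                xtol=FIT_XTOL,
                ftol=FIT_XTOL,
                gtol=FIT_XTOL,
                max_nfev=FIT_MAX_NFEV,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, converged=False)

    a, b, c, d = (float(v) for v in best.x)
    fit = DecayFit(a, b, c, d, converged=True, residual_sse=float(2.0 * best.cost))
    fit.t_half = _decay_half_time(fit, horizon=t_half_search_h)
    return fit


def _decay_half_time(fit: DecayFit, horizon: float, tol: float = 1e-6) -> float:
    """First downward crossing of half the fitted curve's maximum."""
    grid = np.linspace(0.0, horizon, 20_001)
    vals = fit(grid)
    peak = float(np.max(vals))
    if peak <= 0:
        return np.inf
    target = 0.5 * peak
    i_peak = int(np.argmax(vals))
    below = np.nonzero(vals[i_peak:] <= target)[0]
    if len(below) == 0:
        return np.inf
    j = i_peak + below[0]
    if j == 0:
        return 0.0
    lo, hi = grid[j - 1], grid[j]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fit(mid) <= target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# 4-parameter Hill fit for loss of nascent transcription (EU incorporation)


@dataclass
class HillFit:
    """4-parameter Hill curve of fraction-EU-negative cells versus time."""

    floor: float
    ceiling: float
    midpoint: float
    slope: float
    t_half_eu: float = np.nan
    converged: bool = True

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore", over="ignore"):
            frac = np.where(
                t > 0,
                1.0 / (1.0 + (self.midpoint / np.where(t > 0, t, 1.0)) ** self.slope),
                0.0,
            )
        out = self.floor + (self.ceiling - self.floor) * frac
        return out if out.ndim else float(out)


def fit_hill4_eu(times, frac_negative) -> HillFit:
    """Fit fraction-EU-negative kinetics and locate the 50%-negative time.

    ``t_half_eu`` is the time at which the fitted curve crosses the absolute
    fraction 0.5 (not the curve midpoint); NaN if the curve never reaches it.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(frac_negative, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 5:
        raise ValueError("Hill fit requires at least 5 timepoints")

    mid0 = float(np.interp(0.5 * (y.min() + y.max()), y, t)) if y.max() > y.min() else t.mean()
    mid0 = max(mid0, 1e-3)

    def residuals(p):
        return HillFit(p[0], p[1], p[2], p[3])(t) - y

    res = optimize.least_squares(
        residuals,
        [max(y.min(), 0.0), min(y.max(), 1.0), mid0, 2.0],
        bounds=([0.0, 0.0, 1e-6, 0.1], [1.0, 1.0, 10.0 * max(t[-1], 1.0), 50.0]),
        xtol=FIT_XTOL,
        ftol=FIT_XTOL,
        gtol=FIT_XTOL,
        max_nfev=FIT_MAX_NFEV,
    )
    floor, ceiling, midpoint, slope = (float(v) for v in res.x)
    if floor > ceiling:
        floor, ceiling = ceiling, floor
    fit = HillFit(floor, ceiling, midpoint, slope, converged=bool(res.success))
    fit.t_half_eu = _hill_cross_time(fit, 0.5, horizon=10.0 * t[-1])
    return fit


def _hill_cross_time(fit: HillFit, level: float, horizon: float, tol: float = 1e-6) -> float:
    if fit.ceiling < level or fit(horizon) < level:
        return np.nan
    lo, hi = 0.0, horizon
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fit(mid) >= level:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# 4-parameter sigmoid dose-response


@dataclass
class Sigmoid4Fit:
    """4-parameter logistic dose-response curve on log10 concentration."""

    bottom: float
    top: float
    ec50: float
    hill_slope: float
    converged: bool = True

    def __call__(self, dose):
        dose = np.asarray(dose, dtype=float)
        x = np.log10(dose)
        mid = np.log10(self.ec50)
        out = self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** (self.hill_slope * (mid - x))
        )
        return out if out.ndim else float(out)


def fit_sigmoid4(doses, response) -> Sigmoid4Fit:
    """Fit the standard 4-parameter sigmoid to a dose-response series.

    A flat response leaves the Hill slope unidentifiable; the fit is then
    flagged unconverged.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(response, dtype=float)
    ok = np.isfinite(d) & np.isfinite(y) & (d > 0)
    d, y = d[ok], y[ok]
    if len(d) < 5:
        raise ValueError("sigmoid fit requires at least 5 doses")
    if np.ptp(y) < 1e-12:
        return Sigmoid4Fit(float(y[0]), float(y[0]), np.nan, np.nan, converged=False)

    ec50_0 = float(np.exp(np.mean(np.log(d))))

    def residuals(p):
        return Sigmoid4Fit(p[0], p[1], 10.0 ** p[2], p[3])(d) - y

    span = np.ptp(y)
    res = optimize.least_squares(
        residuals,
        [float(y.min()), float(y.max()), math.log10(ec50_0), 1.0],
        bounds=(
            [y.min() - span, y.min() - span, math.log10(d.min()) - 3, -50.0],
            [y.max() + span, y.max() + span, math.log10(d.max()) + 3, 50.0],
        ),
        xtol=FIT_XTOL,
        ftol=FIT_XTOL,
        gtol=FIT_XTOL,
        max_nfev=FIT_MAX_NFEV,
    )
    return Sigmoid4Fit(
        float(res.x[0]), float(res.x[1]), float(10.0 ** res.x[2]), float(res.x[3]),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# Coupling of protein decay half-life to death onset


@dataclass
class OnsetCoupling:
    """Regression of death timing (LF50) on protein decay half-life.

    ``lag_constant`` is the offset of the best-fit shifted-identity line
    LF50 = t_half + c, i.e. the mean lag between protein loss and death.
    """

    slope: float
    intercept: float
    r: float
    lag_constant: float
    n: int


def onset_coupling(t_half, lf50) -> OnsetCoupling:
    """OLS of LF50 on decay half-life plus the shifted-identity lag constant."""
    x = np.asarray(t_half, dtype=float)
    y = np.asarray(lf50, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("onset coupling requires at least 3 (t_half, LF50) pairs")
    if np.ptp(x) == 0:
        # Degenerate abscissa: slope undefined by OLS; report flat line.
        slope, intercept, r = 0.0, float(np.mean(y)), 0.0
    else:
        lin = stats.linregress(x, y)
        slope, intercept, r = float(lin.slope), float(lin.intercept), float(lin.rvalue)
    return OnsetCoupling(
        slope=slope,
        intercept=intercept,
        r=r,
        lag_constant=float(np.mean(y - x)),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Table-level driver


def fit_led_table(metric_df, groupby=("condition_id",), auc_window: float | None = None):
    """Fit the LED model per condition of a long-format LF table.

    Returns one row per condition with parameters, flags, SSE, LF50 and AUC.
    ``auc_window`` defaults to each condition's last timepoint.
    """
    import pandas as pd

    rows = []
    keys = list(groupby)
    for key, sub in metric_df.groupby(keys, sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        sub = sub.sort_values("time_h")
        fit = fit_led(sub["time_h"].to_numpy(), sub["LF"].to_numpy())
        if fit.converged and auc_window is not None:
            fit.auc = led_auc(fit, auc_window)
        row = dict(zip(keys, key))
        for col in ("genotype", "drug", "dose_uM"):
            if col in sub.columns and col not in row:
                row[col] = sub[col].iloc[0]
        row.update(
            lf0=fit.lf0, lfp=fit.lfp, dr=fit.dr, do=fit.do,
            converged=fit.converged, residual_sse=fit.residual_sse,
            max_observed_lf=fit.max_observed_lf, lf50=fit.lf50, auc=fit.auc,
        )
        rows.append(row)
    return pd.DataFrame(rows)
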