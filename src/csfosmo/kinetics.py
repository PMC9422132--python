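"""Tracer-efflux rate constants, imaging slopes, and Hill dose-response fits.

Three small fitting problems recur in the transporter experiments:

* the ⁸⁶Rb⁺ efflux rate constant k (min⁻¹), the negative slope of
  ln(A_T/A_0) against time after ³H-mannitol background correction;
* linear rates of fluorescence change over time (dye-front imaging,
  intracellular Na⁺/pH indicators);
* the four-parameter logistic (Hill) dose-response curve
  Y = Y_min + (Y_max − Y_min) / (1 + (IC50/X)^HillSlope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class KineticsError(ValueError):
    pass


@dataclass(frozen=True)
class EffluxSeries:
    """⁸⁶Rb⁺ / ³H-mannitol count pairs against time (s, starting at 0)."""

    time_s: np.ndarray
    rb_counts: np.ndarray
    mannitol_counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        rb = np.asarray(self.rb_counts, dtype=float)
        bg = np.asarray(self.mannitol_counts, dtype=float)
        if not (len(t) == len(rb) == len(bg)):
            raise KineticsError("time/rb/mannitol must have equal lengths")
        if np.any(np.diff(t) <= 0):
            raise KineticsError("time_s must be strictly increasing")
        if t[0] != 0:
            raise KineticsError("first time point must be 0")
        if np.any(rb < 0) or np.any(bg < 0):
            raise KineticsError("counts must be >= 0")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "rb_counts", rb)
        object.__setattr__(self, "mannitol_counts", bg)


@dataclass(frozen=True)
class EffluxFit:
    rate_constant_per_min: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class RateFit:
    slope_per_min: float
    slope_se: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class DoseResponseFit:
    ic50: float
    hill_slope: float
    y_min: float
    y_max: float
    increasing: bool


def background_correct(s: EffluxSeries) -> np.ndarray:
    """Subtract the mannitol-inferred extracellular background from ⁸⁶Rb⁺.

    Direct count-for-count subtraction; values that would go negative
    are clipped to zero with a warning (counting noise can push the
    background above the signal at late time points).
    """
    corrected = s.rb_counts - s.mannitol_counts
    if np.any(corrected < 0):
        warnings.warn(
            "background exceeds signal at some time points; clipping to zero",
            stacklevel=2,
        )
        corrected = np.clip(corrected, 0.0, None)
    return corrected


def efflux_rate_constant(s: EffluxSeries, correct_background: bool = True) -> EffluxFit:
    """Efflux rate constant k (min⁻¹) from the log-linear decay of activity.

    Fits ln(A_T/A_0) on time by OLS; k is the negated slope, converted
    to min⁻¹.  A perfectly exponential series A_T = A_0·e^(−kt) is
    recovered exactly; a constant series gives k = 0.
    """
    if len(s.time_s) < 3:
        raise KineticsError("need at least 3 time points")
    activity = background_correct(s) if correct_background else s.rb_counts
    if np.any(activity <= 0):
        bad = s.time_s[activity <= 0].tolist()
        raise KineticsError(f"non-positive activity at time points {bad} s")
    log_ratio = np.log(activity / activity[0])
    res = stats.linregress(s.time_s / 60.0, log_ratio)
    r2 = float(res.rvalue**2) if np.ptp(log_ratio) > 0 else 1.0
    return EffluxFit(
        rate_constant_per_min=float(-res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
    )


def rate_from_series(time_min, signal) -> RateFit:
    """OLS slope (signal units min⁻¹) of a signal time series, with SE."""
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(signal, dtype=float)
    if len(t) < 3:
        raise KineticsError("need at least 3 points")
    if np.ptp(t) == 0:
        raise KineticsError("singular design: all time points are equal")
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 1.0
    return RateFit(
        slope_per_min=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=r2,
    )


def hill_equation(x, y_min, y_max, ic50, hill_slope):
    """Four-parameter logistic: Y = Y_min + (Y_max − Y_min)/(1 + (IC50/X)^h)."""
    x = np.asarray(x, dtype=float)
    return y_min + (y_max - y_min) / (1.0 + (ic50 / x) ** hill_slope)


def hill_fit(dose_um, response) -> DoseResponseFit:
    """Nonlinear least-squares fit of the four-parameter Hill equation.

    Initialization: plateaus from the response extremes, IC50 from the
    geometric mean of the doses bracketing half-maximum, Hill slope 1.
    Bounds: IC50 > 0 and Hill slope in [0.1, 10]; the plateaus are free,
    so decreasing curves fit with the plateau estimates swapped.
    """
    x = np.asarray(dose_um, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(x) < 4:
        raise KineticsError("need at least 4 doses")
    if np.any(x <= 0):
        raise KineticsError("doses must be > 0")
    span = np.ptp(y)
    if span == 0 or span < 1e-9 * max(1.0, np.max(np.abs(y))):
        raise KineticsError("flat response: plateaus coincide, no transition to fit")

    order = np.argsort(x)
    xs, ys = x[order], y[order]
    half = 0.5 * (np.min(y) + np.max(y))
    crossings = np.nonzero(np.diff(np.sign(ys - half)))[0]
    if len(crossings) > 0:
        i = crossings[0]
        ic50_0 = float(np.sqrt(xs[i] * xs[i + 1]))
    else:
        ic50_0 = float(np.exp(np.mean(np.log(xs))))
    p0 = [ys[0], ys[-1], ic50_0, 1.0]
    bounds = (
        [-np.inf, -np.inf, 1e-12, 0.1],
        [np.inf, np.inf, np.inf, 10.0],
    )
    try:
        popt, _ = optimize.curve_fit(
            hill_equation, x, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise KineticsError(
            f"Hill fit did not converge (init y_min={p0[0]:.4g}, y_max={p0[1]:.4g}, "
            f"ic50={p0[2]:.4g}, hill=1): {exc}"
        ) from exc
    fit_ymin, fit_ymax, ic50, hill = popt
    if abs(fit_ymax - fit_ymin) < 1e-9 * max(1.0, abs(fit_ymax), abs(fit_ymin)):
        raise KineticsError("degenerate fit: y_max ≈ y_min")
    return DoseResponseFit(
        ic50=float(ic50),
        hill_slope=float(hill),
        y_min=float(min(fit_ymin, fit_ymax)),
        y_max=float(max(fit_ymin, fit_ymax)),
        increasing=bool(fit_ymax >= fit_ymin),
    )
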