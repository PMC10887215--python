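"""Activity and thermal-inactivation kinetics from assay time series.

Covers the quantitative steps of the bench assays: a linear densitometry
calibration, background-subtracted initial rates from progress curves,
nonlinear fits of thermal-inactivation decay under first-order
(dA/dt = -kA) or second-order (dA/dt = -kA^2) kinetics, small-sample AICc
model selection between the two, and half-life extraction either from the
fitted model (closed form) or by log-linear interpolation of the sampled
series.

Half-life conventions: first order t1/2 = ln2 / k; second order
t1/2 = 1 / (k * A0).  The default sampling grid is the 0-128 min doubling
series used in the heat-inactivation assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .variants import ND, Response

#: Incubation times (minutes) of the thermal-inactivation assay.
DEFAULT_DECAY_TIMES = (0.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)

#: Sampling grid (minutes) of the TLC activity assay.
DEFAULT_PROGRESS_TIMES = (0.0, 3.5, 7.0, 10.5, 14.0, 17.5)


class KineticsError(ValueError):
    pass


class FitError(KineticsError):
    """Nonlinear fit failed to converge or hit a parameter boundary."""


# ---------------------------------------------------------------------------
# densitometry calibration


@dataclass
class CalibrationCurve:
    slope: float  # signal per mM
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]

    @property
    def usable(self) -> bool:
        return self.slope > 0

    def concentration(self, signal: float) -> float:
        if not self.usable:
            raise KineticsError("calibration curve has non-positive slope")
        return (signal - self.intercept) / self.slope


def fit_calibration(concentrations, signals) -> CalibrationCurve:
    """Ordinary least-squares line of signal on concentration (>= 3 points)."""
    conc = np.asarray(concentrations, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if conc.size != sig.size or conc.size < 3:
        raise KineticsError("calibration needs >= 3 matched points")
    res = stats.linregress(conc, sig)
    r2 = 0.0 if math.isnan(res.rvalue) else float(res.rvalue**2)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        valid_range=(float(conc.min()), float(conc.max())),
    )


# ---------------------------------------------------------------------------
# progress curves and initial rates


@dataclass
class ProgressCurve:
    times: np.ndarray  # minutes, ascending, first = 0
    signal: np.ndarray  # spot staining, arbitrary units
    background_signal: np.ndarray | None = None  # matched no-enzyme series

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.background_signal is not None:
            self.background_signal = np.asarray(self.background_signal, dtype=float)
            if self.background_signal.shape != self.signal.shape:
                raise KineticsError("background series length mismatch")
        if self.times.shape != self.signal.shape:
            raise KineticsError("times and signal length mismatch")
        if self.times.size < 2 or self.times[0] != 0:
            raise KineticsError("progress curve must start at t=0 with >= 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise KineticsError("times must be strictly increasing")

    @property
    def corrected(self) -> np.ndarray:
        if self.background_signal is None:
            return self.signal
        return self.signal - self.background_signal


@dataclass
class RateEstimate:
    rate: float  # signal units per minute
    n_points: int  # length of the linear prefix used
    r_squared: float
    low_confidence: bool = False


def _line_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r^2; a perfectly flat series counts as a perfect fit."""
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0:
        return 0.0, float(y.mean()), 1.0
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def initial_rate(curve: ProgressCurve, r2_threshold: float = 0.98) -> RateEstimate:
    """Slope of the initial linear part of a background-corrected progress curve.

    Starting from the full series, drop trailing points until the linear fit of
    the remaining prefix (>= 3 points) reaches the r^2 threshold.  If no prefix
    qualifies, the first three points are used and the estimate is flagged
    low-confidence.
    """
    y = curve.corrected
    t = curve.times
    if t.size < 3:
        raise KineticsError("initial rate needs >= 3 time points")
    for n in range(t.size, 2, -1):
        slope, _, r2 = _line_fit(t[:n], y[:n])
        if r2 >= r2_threshold:
            return RateEstimate(rate=slope, n_points=n, r_squared=r2)
    slope, _, r2 = _line_fit(t[:3], y[:3])
    return RateEstimate(rate=slope, n_points=3, r_squared=r2, low_confidence=True)


def relative_activity(
    variant_rate: float, reference_rate: float, detection_floor: float = 0.0
) -> Response:
    """Fold activity relative to a reference; below-floor rates map to ND."""
    if reference_rate <= 0:
        raise KineticsError("reference rate must be positive")
    if variant_rate <= detection_floor:
        return ND
    return variant_rate / reference_rate


# ---------------------------------------------------------------------------
# thermal-inactivation decay


@dataclass
class DecayDataset:
    times: np.ndarray  # minutes, first = 0
    activity: np.ndarray  # remaining activity (absolute or fraction of t=0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.times.shape != self.activity.shape:
            raise KineticsError("times and activity length mismatch")
        if self.times.size < 2 or self.times[0] != 0:
            raise KineticsError("decay series must start at t=0")
        if np.any(self.activity < 0):
            raise KineticsError("activity must be non-negative")


def first_order(t, a0, k):
    return a0 * np.exp(-k * t)


def second_order(t, a0, k):
    return a0 / (1.0 + a0 * k * t)


@dataclass
class DecayFit:
    model_order: str  # "first" | "second"
    rate_constant: float  # min^-1 (first) or (activity*min)^-1 (second)
    initial_activity: float
    half_life: float  # minutes
    rss: float
    aicc: float
    aicc_margin: float | None = None  # winner only: |delta AICc| to the loser
    competitor_failed: bool = False

    def predict(self, t) -> np.ndarray:
        f = first_order if self.model_order == "first" else second_order
        return f(np.asarray(t, dtype=float), self.initial_activity, self.rate_constant)


def _aicc(rss: float, n: int, n_params: int = 2) -> float:
    rss = max(rss, 1e-300)
    k = n_params
    return n * math.log(rss / n) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


def fit_decay(data: DecayDataset, model_order: str) -> DecayFit:
    """Least-squares fit of one decay law, initialized from its linearizing
    transform (log for first order, reciprocal for second order)."""
    if model_order not in ("first", "second"):
        raise KineticsError(f"unknown model order {model_order!r}")
    t, a = data.times, data.activity
    pos = a > 0
    if pos.sum() < 4:
        raise FitError("need >= 4 points with positive activity")
    if a[0] <= 0:
        raise FitError("activity at t=0 must be positive")
    if model_order == "first":
        slope, intercept, _ = _line_fit(t[pos], np.log(a[pos]))
        k0, a00 = max(-slope, 1e-6), math.exp(intercept)
        model = first_order
    else:
        slope, intercept, _ = _line_fit(t[pos], 1.0 / a[pos])
        k0 = max(slope / max(intercept, 1e-12), 1e-6)
        a00 = 1.0 / max(intercept, 1e-12)
        model = second_order
    a00 = max(a00, 1e-9)
    try:
        popt, _ = optimize.curve_fit(
            model, t, a, p0=[a00, k0], bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"{model_order}-order fit did not converge: {exc}") from exc
    a0_fit, k_fit = float(popt[0]), float(popt[1])
    # effective fractional decline over the sampled window; a flat series
    # drives k to the boundary and the fit is meaningless
    k_eff = k_fit if model_order == "first" else k_fit * a0_fit
    if k_eff * max(t.max(), 1.0) < 1e-3:
        raise FitError(
            f"{model_order}-order rate constant at lower boundary "
            f"(k={k_fit:.3g}): no measurable decay over the sampled window"
        )
    rss = float(((model(t, a0_fit, k_fit) - a) ** 2).sum())
    if model_order == "first":
        t_half = math.log(2) / k_fit
    else:
        t_half = 1.0 / (k_fit * a0_fit)
    return DecayFit(
        model_order=model_order,
        rate_constant=k_fit,
        initial_activity=a0_fit,
        half_life=t_half,
        rss=rss,
        aicc=_aicc(rss, t.size),
    )


def select_decay_model(data: DecayDataset) -> DecayFit:
    """Fit both decay orders and return the lower-AICc winner.

    If one fit fails, the other wins with ``competitor_failed`` set.
    """
    fits: dict[str, DecayFit] = {}
    errors: dict[str, FitError] = {}
    for order in ("first", "second"):
        try:
            fits[order] = fit_decay(data, order)
        except FitError as exc:
            errors[order] = exc
    if not fits:
        raise FitError(f"both decay fits failed: {errors}")
    if len(fits) == 1:
        winner = next(iter(fits.values()))
        winner.competitor_failed = True
        return winner
    first, second = fits["first"], fits["second"]
    winner, loser = (first, second) if first.aicc <= second.aicc else (second, first)
    winner.aicc_margin = abs(loser.aicc - winner.aicc)
    return winner


def half_life(obj: DecayFit | DecayDataset, method: str = "model") -> float | None:
    """Half-life in minutes; ``None`` when the series never reaches 50%.

    ``model`` takes the closed form from a fit; ``interpolate`` finds the
    50%-of-initial crossing by log-linear interpolation between the bracketing
    sample times.
    """
    if method == "model":
        if not isinstance(obj, DecayFit):
            raise KineticsError("model method needs a DecayFit")
        return obj.half_life
    if method != "interpolate":
        raise KineticsError(f"unknown method {method!r}")
    if not isinstance(obj, DecayDataset):
        raise KineticsError("interpolate method needs a DecayDataset")
    t, a = obj.times, obj.activity
    if a[0] <= 0:
        raise KineticsError("activity at t=0 must be positive")
    target = a[0] / 2.0
    for i in range(1, t.size):
        if a[i] <= target:
            a_hi, a_lo = a[i - 1], a[i]
            if a_lo <= 0 or a_hi <= 0:
                # linear fallback when the log transform is undefined
                frac = (a_hi - target) / (a_hi - a_lo)
            else:
                frac = (math.log(a_hi) - math.log(target)) / (
                    math.log(a_hi) - math.log(a_lo)
                )
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return None
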