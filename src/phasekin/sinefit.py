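"""Decaying sine wave model for nucleosome phasing profiles.

The average methylation-rate profile downstream of the +1 nucleosome dyad
oscillates with the nucleosome repeat and loses amplitude down the gene.
The model is

    y(x) = A * exp(-lam * x) * sin(omega * x + theta) + slope * x + baseline

where ``x`` is the dyad-relative offset in bp.  The period ``2*pi/omega``
is the average nucleosome spacing; ``exp(-lam * period)`` is the
proportional amplitude loss per nucleosome repeat; ``slope`` is the drift
of the profile baseline (reported per kb); and the mean of the fitted
curve over the first kilobase (integer offsets -50..1000) is the adjusted
mean rate relative to the internal control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SinePhaseParams",
    "FitQuality",
    "SineFitDerived",
    "FitReport",
    "sine_eval",
    "solve_baseline",
    "params_from_descriptors",
    "fit_sine",
    "derive",
    "adjusted_r2",
    "DEFAULT_FIT_RANGE",
]

#: Dyad-relative fitting window in bp (inclusive); 1051 integer offsets.
DEFAULT_FIT_RANGE = (-50, 1000)

#: Number of free parameters of the model (A, lam, omega, theta, slope, baseline).
N_PARAMS = 6

#: Allowed period band during fitting, bp.  Brackets every plausible yeast
#: nucleosome repeat length with margin.
PERIOD_BOUNDS = (120.0, 220.0)

#: Multi-start grid: periods in bp and phases in radians.  Fixed grid, no
#: randomness, so fits are bit-reproducible.
START_PERIODS = tuple(float(p) for p in range(140, 201, 5))
START_THETAS = (-math.pi / 2, 0.0, math.pi / 2, math.pi)


@dataclass(frozen=True)
class SinePhaseParams:
    """Parameters of the decaying sine wave model.

    amplitude
        Initial oscillation amplitude A at x = 0 (rate-ratio units).
    lam
        Exponential amplitude decay constant, per bp (>= 0).
    omega
        Angular frequency, rad per bp; period = 2*pi/omega.
    theta
        Phase in radians, normalized to (-pi, pi].  theta = -pi/2 puts a
        trough at the +1 dyad.
    slope
        Linear baseline drift, rate ratio per bp.
    baseline
        Baseline value at x = 0, rate ratio.
    """

    amplitude: float
    lam: float
    omega: float
    theta: float
    slope: float
    baseline: float

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.amplitude, self.lam, self.omega, self.theta, self.slope, self.baseline]
        )

    @staticmethod
    def from_array(v: np.ndarray) -> "SinePhaseParams":
        return SinePhaseParams(*(float(x) for x in v))


@dataclass(frozen=True)
class FitQuality:
    """Sums of squares of a sine fit: SSR, SST, point count n, parameter count p."""

    ssr: float
    sst: float
    n: int
    p: int = N_PARAMS


@dataclass(frozen=True)
class SineFitDerived:
    """Reported descriptors derived from a fitted model."""

    spacing_bp: float
    amplitude: float
    slope_per_kb: float
    decay_per_period: float
    adj_mean_rate: float
    adj_r2: float
    n_points: int


@dataclass(frozen=True)
class FitReport:
    """Full result of a phasing fit."""

    params: SinePhaseParams
    quality: FitQuality
    derived: SineFitDerived
    fit_range: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "params": vars(self.params) | {},
            "derived": vars(self.derived) | {},
            "quality": {"ssr": self.quality.ssr, "sst": self.quality.sst,
                        "n": self.quality.n, "p": self.quality.p},
            "fit_range": list(self.fit_range),
        }


def sine_eval(params: SinePhaseParams, x) -> np.ndarray:
    """Evaluate the model at dyad-relative offsets ``x`` (bp)."""
    x = np.asarray(x, dtype=float)
    return (
        params.amplitude * np.exp(-params.lam * x) * np.sin(params.omega * x + params.theta)
        + params.slope * x
        + params.baseline
    )


def _window_offsets(fit_range=DEFAULT_FIT_RANGE) -> np.ndarray:
    lo, hi = fit_range
    return np.arange(int(lo), int(hi) + 1, dtype=float)


def curve_mean(params: SinePhaseParams, fit_range=DEFAULT_FIT_RANGE) -> float:
    """Mean of the fitted curve over integer offsets of the window."""
    return float(np.mean(sine_eval(params, _window_offsets(fit_range))))


def solve_baseline(
    amplitude: float,
    lam: float,
    omega: float,
    theta: float,
    slope: float,
    target_mean: float,
    fit_range=DEFAULT_FIT_RANGE,
) -> float:
    """Baseline b such that the curve mean over the window equals ``target_mean``.

    The model is linear in b, so b = target − mean(sine term) − slope·mean(x).
    """
    x = _window_offsets(fit_range)
    sine_mean = float(np.mean(amplitude * np.exp(-lam * x) * np.sin(omega * x + theta)))
    return target_mean - sine_mean - slope * float(np.mean(x))


def params_from_descriptors(
    spacing_bp: float,
    amplitude: float,
    slope_per_kb: float,
    decay_per_period: float,
    adj_mean_rate: float,
    theta: float = -math.pi / 2,
    fit_range=DEFAULT_FIT_RANGE,
) -> SinePhaseParams:
    """Build model parameters from the reported descriptor set.

    Inverts the derived quantities: omega = 2*pi/spacing,
    lam = -ln(decay)/spacing, slope = slope_per_kb/1000, and baseline solved
    so the curve mean over the window equals ``adj_mean_rate``.
    """
    if not (0.0 < decay_per_period <= 1.0):
        raise ValueError("decay_per_period must be in (0, 1]")
    omega = 2.0 * math.pi / spacing_bp
    lam = -math.log(decay_per_period) / spacing_bp
    slope = slope_per_kb / 1000.0
    baseline = solve_baseline(amplitude, lam, omega, theta, slope, adj_mean_rate, fit_range)
    return SinePhaseParams(amplitude, lam, omega, theta, slope, baseline)


def adjusted_r2(quality: FitQuality) -> float:
    """Adjusted coefficient of determination of a sine fit.

    1 − (SSR/SST)·(n−1)/(n−p−1) with p = 6 model parameters, so a perfect
    fit gives exactly 1.  Undefined (NaN) when SST = 0.
    """
    if quality.n <= quality.p + 1:
        raise ValueError(f"need n > p + 1 = {quality.p + 1} points, got {quality.n}")
    if quality.sst <= 0:
        warnings.warn("SST = 0: adjusted R^2 undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    n, p = quality.n, quality.p
    return 1.0 - (quality.ssr / quality.sst) * (n - 1) / (n - p - 1)


def derive(
    params: SinePhaseParams, quality: FitQuality, fit_range=DEFAULT_FIT_RANGE
) -> SineFitDerived:
    """Reported descriptors for a fitted model.

    With A = 0 the oscillation is absent and the per-period decay is
    reported as 1 (no amplitude to lose).
    """
    spacing = params.period
    decay = 1.0 if params.amplitude == 0 and params.lam == 0 else math.exp(-params.lam * spacing)
    return SineFitDerived(
        spacing_bp=spacing,
        amplitude=params.amplitude,
        slope_per_kb=1000.0 * params.slope,
        decay_per_period=decay,
        adj_mean_rate=curve_mean(params, fit_range),
        adj_r2=adjusted_r2(quality),
        n_points=quality.n,
    )


def _normalize_theta(theta: float) -> float:
    t = math.fmod(theta + math.pi, 2.0 * math.pi)
    if t <= 0:
        t += 2.0 * math.pi
    return t - math.pi


def _residual_fn(x: np.ndarray, y: np.ndarray):
    def fun(v):
        a, lam, om, th, sl, b = v
        return a * np.exp(-lam * x) * np.sin(om * x + th) + sl * x + b - y

    def jac(v):
        a, lam, om, th, sl, b = v
        e = np.exp(-lam * x)
        s = np.sin(om * x + th)
        c = np.cos(om * x + th)
        J = np.empty((x.size, 6))
        J[:, 0] = e * s
        J[:, 1] = -a * x * e * s
        J[:, 2] = a * e * c * x
        J[:, 3] = a * e * c
        J[:, 4] = x
        J[:, 5] = 1.0
        return J

    return fun, jac


def fit_sine(
    offsets,
    values,
    fit_range=DEFAULT_FIT_RANGE,
    min_points: int = 50,
) -> tuple[SinePhaseParams, FitQuality]:
    """Fit the decaying sine model to per-offset profile points.

    Bounded nonlinear least squares with an analytic Jacobian, multi-started
    over a fixed grid of periods (140-200 bp, step 5) and phases
    (-pi/2, 0, pi/2, pi); the start with the lowest SSR wins.  The period is
    constrained to 120-220 bp and lam, A to be non-negative.  Deterministic:
    no randomness anywhere.

    Parameters
    ----------
    offsets, values
        Profile points (dyad-relative bp, mean rate ratio).  Points outside
        ``fit_range`` are ignored.
    min_points
        Minimum number of in-window points required.
    """
    offsets = np.asarray(offsets, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = fit_range
    keep = (offsets >= lo) & (offsets <= hi) & np.isfinite(values)
    x, y = offsets[keep], values[keep]
    if x.size < min_points:
        raise ValueError(f"need >= {min_points} points in fit range, got {x.size}")

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0 or np.ptp(y) == 0:
        sst = 0.0
    if sst == 0:
        warnings.warn("flat profile: returning A=0 solution", RuntimeWarning, stacklevel=2)
        params = SinePhaseParams(0.0, 0.0, 2 * math.pi / 165.0, -math.pi / 2, 0.0, float(y.mean()))
        return params, FitQuality(ssr=0.0, sst=0.0, n=int(x.size))

    # linear detrend for slope/baseline starting values
    sl0, b0 = np.polyfit(x, y, 1)
    resid = y - (sl0 * x + b0)
    a0 = max(float(np.std(resid)) * math.sqrt(2.0), 1e-6)

    fun, jac = _residual_fn(x, y)
    om_lo = 2 * math.pi / PERIOD_BOUNDS[1]
    om_hi = 2 * math.pi / PERIOD_BOUNDS[0]
    bounds = (
        [0.0, 0.0, om_lo, -math.pi - 1e-9, -np.inf, -np.inf],
        [np.inf, 0.1, om_hi, math.pi + 1e-9, np.inf, np.inf],
    )

    best = None
    best_ssr = np.inf
    for period in START_PERIODS:
        for th0 in START_THETAS:
            v0 = [a0, 1e-3, 2 * math.pi / period, th0, sl0, b0]
            try:
                sol = least_squares(
                    fun, v0, jac=jac, bounds=bounds, method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
                )
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            ssr = float(2.0 * sol.cost)
            if ssr < best_ssr:
                best_ssr = ssr
                best = sol.x
            if best_ssr < 1e-16 * sst:  # already an essentially perfect fit
                break
        else:
            continue
        break

    if best is None:
        raise RuntimeError("sine fit failed from every start")

    a, lam, om, th, sl, b = best
    th = _normalize_theta(th)
    params = SinePhaseParams(float(a), float(lam), float(om), th, float(sl), float(b))
    quality = FitQuality(ssr=best_ssr, sst=sst, n=int(x.size))
    return params, quality


def fit_report(offsets, values, fit_range=DEFAULT_FIT_RANGE, min_points: int = 50) -> FitReport:
    """Convenience wrapper: fit, derive and bundle a :class:`FitReport`."""
    params, quality = fit_sine(offsets, values, fit_range=fit_range, min_points=min_points)
    return FitReport(params, quality, derive(params, quality, fit_range), tuple(fit_range))
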