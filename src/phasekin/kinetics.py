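"""Pseudo-first-order methylation kinetics.

Each site's methylated fraction f(t) after methyltransferase induction is
assumed to follow f(t) = 1 - (1 - f0) * exp(-k t), so

    ln(1 - f) = -k * t + b

and the apparent rate constant k is obtained by ordinary least squares on
the log-transformed fractions.  Fractions above a saturation cap (0.99)
carry almost no rate information; they are capped and, past the first
capped point, dropped.  Rates are made comparable between strains by
dividing by an internal reference: the median rate of the non-nucleosomal
mitochondrial genome (adenine-methylation mode) or the rate implied by the
genome-wide median fraction trajectory (CpG mode).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "fit_first_order",
    "fit_single_trajectory",
    "mtdna_reference",
    "genome_median_reference",
    "normalize",
    "region_rate_summary",
    "CAP_DEFAULT",
    "MIN_POINTS_DEFAULT",
]

CAP_DEFAULT = 0.99
MIN_POINTS_DEFAULT = 3


def _apply_cap(fractions: np.ndarray, cap: float) -> np.ndarray:
    """Saturation rule: cap fractions at ``cap``; of the points exceeding it
    (in time order) keep only the first, dropping the rest (NaN)."""
    f = fractions.astype(float).copy()
    exceed = f > cap
    # count of exceedances strictly before each timepoint, per site
    prior = np.cumsum(exceed, axis=1) - exceed
    f[exceed & (prior == 0)] = cap
    f[exceed & (prior > 0)] = np.nan
    return f


def fit_first_order(
    times,
    fractions,
    cap: float = CAP_DEFAULT,
    min_points: int = MIN_POINTS_DEFAULT,
) -> pd.DataFrame:
    """Per-site log-linear rate fits.

    Parameters
    ----------
    times
        Minutes after induction, ascending, length T.
    fractions
        (n_sites, T) array of methylated fractions in [0, 1]; NaN marks a
        missing observation.
    cap, min_points
        Saturation cap and the minimum retained points for an estimate.

    Returns
    -------
    DataFrame with columns ``k_app`` (per minute, slope sign-flipped),
    ``intercept_b``, ``r2``, ``n_used``, ``capped`` and ``ok``.  Sites with
    fewer than ``min_points`` usable observations are flagged ``ok=False``
    and carry NaN estimates.
    """
    t = np.asarray(times, dtype=float)
    f = np.atleast_2d(np.asarray(fractions, dtype=float))
    if f.shape[1] != t.size:
        raise ValueError(f"fractions have {f.shape[1]} columns but {t.size} times given")
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    with np.errstate(invalid="ignore"):
        if np.nanmin(f) < 0 or np.nanmax(f) > 1:
            raise ValueError("fractions must lie in [0, 1]")

    capped_any = np.any(f > cap, axis=1)
    f = _apply_cap(f, cap)

    y = np.full_like(f, np.nan)
    valid = np.isfinite(f)
    y[valid] = np.log1p(-f[valid])

    use = np.isfinite(y)
    n = use.sum(axis=1)

    tt = np.broadcast_to(t, y.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_t = np.where(use, tt, 0.0).sum(axis=1)
        sum_y = np.where(use, y, 0.0).sum(axis=1)
        mean_t = sum_t / n
        mean_y = sum_y / n
        dt = np.where(use, tt - mean_t[:, None], 0.0)
        dy = np.where(use, y - mean_y[:, None], 0.0)
        sxx = (dt**2).sum(axis=1)
        sxy = (dt * dy).sum(axis=1)
        syy = (dy**2).sum(axis=1)
        slope = sxy / sxx
        intercept = mean_y - slope * mean_t
        ssr = syy - sxy**2 / sxx
        r2 = np.where(syy > 0, 1.0 - ssr / syy, np.nan)

    ok = (n >= min_points) & np.isfinite(slope)
    out = pd.DataFrame(
        {
            "k_app": np.where(ok, -slope, np.nan),
            "intercept_b": np.where(ok, intercept, np.nan),
            "r2": np.where(ok, np.clip(r2, 0.0, 1.0), np.nan),
            "n_used": n,
            "capped": capped_any,
            "ok": ok,
        }
    )
    return out


def fit_single_trajectory(
    times, fractions, cap: float = CAP_DEFAULT, min_points: int = MIN_POINTS_DEFAULT
) -> float:
    """Rate constant of one fraction trajectory (e.g. a per-timepoint median)."""
    res = fit_first_order(times, np.asarray(fractions, dtype=float)[None, :], cap, min_points)
    if not bool(res["ok"].iloc[0]):
        raise ValueError("trajectory has too few usable points for a rate fit")
    return float(res["k_app"].iloc[0])


def mtdna_reference(
    rates: pd.DataFrame,
    sites: pd.DataFrame,
    mode: str = "per_site_median",
    timecourse=None,
    times=None,
) -> float:
    """Reference rate from the mitochondrial internal control.

    ``per_site_median`` (default): median of the per-site apparent rates of
    mtDNA sites.  ``median_trajectory``: fit the first-order model to the
    per-timepoint median mtDNA fraction (requires ``timecourse``/``times``).
    The two agree on kinetically homogeneous mtDNA.
    """
    is_mt = (sites["region"] == "mt").to_numpy()
    if not is_mt.any():
        raise ValueError("no mtDNA sites in catalog; cannot form the internal control")
    if mode == "per_site_median":
        k = rates.loc[is_mt & rates["ok"].to_numpy(), "k_app"]
        if k.empty:
            raise ValueError("no estimable mtDNA site rates")
        return float(k.median())
    if mode == "median_trajectory":
        if timecourse is None or times is None:
            raise ValueError("median_trajectory mode needs timecourse and times")
        med = np.nanmedian(np.asarray(timecourse, dtype=float)[is_mt], axis=0)
        return fit_single_trajectory(times, med)
    raise ValueError(f"unknown mtdna reference mode: {mode!r}")


def genome_median_reference(times, fractions) -> float:
    """Reference rate from the genome-wide median fraction trajectory.

    Per timepoint, the median fraction over every site of every sequence
    (nuclear chromosomes, mtDNA, plasmid if present); the first-order model
    is then fit to that median trajectory.
    """
    f = np.asarray(fractions, dtype=float)
    med = np.nanmedian(f, axis=0)
    return fit_single_trajectory(times, med)


def normalize(k_app, reference_value: float) -> np.ndarray:
    """Dimensionless rate ratios k_app / reference."""
    if not np.isfinite(reference_value) or reference_value <= 0:
        raise ValueError(f"reference rate must be positive, got {reference_value}")
    return np.asarray(k_app, dtype=float) / reference_value


def region_rate_summary(norm_rate, regions) -> pd.DataFrame:
    """Median / quartiles / count of normalized rates per region class.

    Empty or all-NaN classes are omitted with a warning.
    """
    df = pd.DataFrame({"norm_rate": np.asarray(norm_rate, dtype=float),
                       "region": np.asarray(regions)})
    rows = []
    for klass, grp in df.groupby("region", sort=True):
        vals = grp["norm_rate"].dropna()
        if vals.empty:
            warnings.warn(f"region class {klass!r} has no estimable sites; omitted",
                          RuntimeWarning, stacklevel=2)
            continue
        rows.append(
            {
                "region": klass,
                "n": int(vals.size),
                "q25": float(vals.quantile(0.25)),
                "median": float(vals.median()),
                "q75": float(vals.quantile(0.75)),
            }
        )
    return pd.DataFrame(rows, columns=["region", "n", "q25", "median", "q75"])
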