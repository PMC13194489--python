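"""Growth-rate estimation and physiology assays.

Specific growth rates k are estimated by ordinary least squares on
ln(value) vs time over an exponential window; by default the window is
the contiguous span of >=3 points maximizing R^2 (ties broken toward the
longest span), so the estimator is exact on noiseless exponentials for
any k and y0 > 0.  Growth proxies are OD600 (soluble acceptors) or Fe(II)
accumulation (Fe(III) acceptors); the curve carries a units tag and
rate contrasts refuse to mix time bases.

Also included: ferrozine calibration inversion for Fe(II) quantification
at 562 nm, and the crystal-violet attachment index A580(stain)/A600(culture).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CURVE_COLUMNS = ["strain", "acceptor", "replicate", "time", "value", "unit"]


@dataclass
class GrowthCurve:
    """One replicate growth time series."""

    strain: str
    acceptor: str
    replicate: int
    times: np.ndarray
    values: np.ndarray
    unit: str  # time base of k, e.g. 'per-day' or 'per-hour'

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-d arrays")
        if len(self.times) and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.values < 0).any():
            raise ValueError("values must be non-negative")


@dataclass
class RateEstimate:
    """A fitted specific growth rate with its exponential window."""

    strain: str
    k: float  # per unit of the curve's time base
    unit: str
    window: tuple[float, float]
    r_squared: float
    n_points: int


def _loglinear_fit_full(t, y):
    """(slope, intercept, R^2, ss_res, ss_tot) of ln(y) ~ t."""
    ly = np.log(y)
    slope, intercept = np.polyfit(t, ly, 1)
    resid = ly - (slope * t + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    if ss_res < 1e-24:
        r2 = 1.0
    elif ss_tot < 1e-24:
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2, ss_res, ss_tot


def _loglinear_fit(t, y):
    """(slope, intercept, R^2) of ln(y) ~ t; R^2 = 1 for a perfect fit."""
    return _loglinear_fit_full(t, y)[:3]


def fit_growth_rate(curve: GrowthCurve,
                    window: tuple[float, float] | None = None,
                    min_points: int = 3,
                    r2_tolerance: float = 2e-3) -> RateEstimate:
    """Estimate the specific growth rate from one curve.

    ``window=(t0, t1)`` fixes the fit span; otherwise every contiguous run
    of >= min_points points is scored by log-linear R^2 and the longest
    window within ``r2_tolerance`` of the best R^2 wins.  Non-positive
    values inside the fitted window raise, as the log model is undefined
    there.
    """
    t, y = curve.times, curve.values
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
        if len(t) < min_points:
            raise ValueError(f"fewer than {min_points} points in fixed window")
        if (y <= 0).any():
            raise ValueError("non-positive values inside fit window")
        k, _, r2 = _loglinear_fit(t, y)
        return RateEstimate(curve.strain, k, curve.unit,
                            (float(t[0]), float(t[-1])), r2, len(t))

    pos = y > 0
    t, y = t[pos], y[pos]
    n = len(t)
    if n < min_points:
        raise ValueError(f"need >= {min_points} positive points to fit")
    # Raw R^2 is not comparable across window lengths: under noise a short
    # window reaches spuriously high R^2, while a long window on a shallow
    # exponential looks worse simply because its signal variance is small.
    # We therefore floor each window's residual sum at the level implied by
    # the series' own noise (median residual variance of the shortest
    # windows, where model error is negligible) before comparing.  Windows
    # leaving the exponential phase accrue real model error above the floor
    # and drop out; among comparable windows the longest wins.
    fits = []  # (ss_res, ss_tot, slope, i, j)
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            slope, _, r2, ss_res, ss_tot = _loglinear_fit_full(t[i:j], y[i:j])
            fits.append((ss_res, ss_tot, slope, i, j))
    shortest = [f for f in fits if f[4] - f[3] == min_points]
    noise_var = float(np.median([f[0] / (min_points - 2) for f in shortest])) \
        if min_points > 2 else 0.0

    def floored_r2(f):
        ss_res, ss_tot = max(f[0], noise_var * (f[4] - f[3] - 2)), f[1]
        if ss_res < 1e-24:
            return 1.0
        return 1.0 - ss_res / ss_tot if ss_tot > 1e-24 else 0.0

    best = max(floored_r2(f) for f in fits)
    ss_res, ss_tot, slope, i, j = max(
        (f for f in fits if floored_r2(f) >= best - r2_tolerance),
        key=lambda f: (f[4] - f[3], floored_r2(f)))
    _, _, r2 = _loglinear_fit(t[i:j], y[i:j])
    return RateEstimate(curve.strain, slope, curve.unit,
                        (float(t[i]), float(t[j - 1])), r2, j - i)


def fold_change_rates(rates_a: list, rates_b: list) -> tuple[float, float]:
    """Fold difference in mean growth rate between two strain groups.

    fold = mean(k_a) / mean(k_b), with an independent t-test on the k
    values (p is nan when either group has a single member).  Accepts
    RateEstimate lists or raw floats; RateEstimates must share one time
    base across both groups.
    """
    ka, ua = _extract_rates(rates_a)
    kb, ub = _extract_rates(rates_b)
    units = {u for u in ua + ub if u is not None}
    if len(units) > 1:
        raise ValueError(f"cannot contrast rates with mixed time bases: {sorted(units)}")
    if not len(ka) or not len(kb):
        raise ValueError("both rate groups must be nonempty")
    mb = kb.mean()
    if mb == 0:
        raise ZeroDivisionError("denominator group has zero mean rate")
    fold = float(ka.mean() / mb)
    if len(ka) < 2 and len(kb) < 2:
        return fold, float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-variance groups -> nan p
        p = float(stats.ttest_ind(ka, kb).pvalue)
    return fold, p


def _extract_rates(rates):
    ks, units = [], []
    for r in rates:
        if isinstance(r, RateEstimate):
            ks.append(r.k)
            units.append(r.unit)
        else:
            ks.append(float(r))
            units.append(None)
    return np.asarray(ks, dtype=float), units


def ferrozine_fe2(absorbance_562: float, calibration_slope: float,
                  calibration_intercept: float = 0.0,
                  dilution_factor: float = 10.0,
                  calibration_max: float | None = None) -> float:
    """Fe(II) concentration (mM) from a ferrozine A562 reading.

    Inverts the linear calibration A = slope*C + intercept and multiplies
    by the dilution factor (default 10: 0.1 mL culture into 0.9 mL HCl).
    Readings above ``calibration_max`` trigger an extrapolation warning.
    """
    if calibration_slope <= 0:
        raise ValueError("calibration slope must be positive")
    if calibration_max is not None and absorbance_562 > calibration_max:
        warnings.warn("absorbance above calibration range; extrapolating",
                      stacklevel=2)
    return (absorbance_562 - calibration_intercept) / calibration_slope * dilution_factor


def crystal_violet_index(a580_cv, a600_culture):
    """Attachment index: solubilized crystal violet A580 over culture A600.

    Scalar inputs return a scalar index; array inputs (replicates) return
    (per-replicate indices, mean, sd).
    """
    a580 = np.asarray(a580_cv, dtype=float)
    a600 = np.asarray(a600_culture, dtype=float)
    if (a600 == 0).any():
        raise ZeroDivisionError("culture A600 must be nonzero")
    idx = a580 / a600
    if idx.ndim == 0:
        return float(idx)
    return idx, float(idx.mean()), float(idx.std(ddof=1)) if idx.size > 1 else float("nan")


# --------------------------------------------------------------------- I/O


def read_growth_csv(path: str | Path) -> list[GrowthCurve]:
    """Read curves from CSV (strain, acceptor, replicate, time, value, unit)."""
    df = pd.read_csv(path)
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns {sorted(missing)}")
    curves = []
    for (strain, acceptor, rep, unit), g in df.groupby(
            ["strain", "acceptor", "replicate", "unit"], sort=True):
        g = g.sort_values("time")
        curves.append(GrowthCurve(strain, acceptor, int(rep),
                                  g.time.to_numpy(), g.value.to_numpy(), unit))
    return curves


def write_rates_csv(estimates: list[RateEstimate], path: str | Path) -> None:
    rows = [{"strain": e.strain, "k": e.k, "unit": e.unit,
             "window_start": e.window[0], "window_end": e.window[1],
             "r_squared": e.r_squared, "n": e.n_points} for e in estimates]
    pd.DataFrame(rows).to_csv(path, index=False)
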