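"""Analysis-side estimators: indicator calibration, dF/F0, PPR, P_r, decay fits.

These are the computations applied to (synthetic or real) recordings:

* GINKO2 ratiometric K+ calibration, y = a * ln(x + b), its exact inverse
  and a least-squares fit of (a, b) from calibration points;
* fractional fluorescence change dF/F0 against a pre-stimulus baseline;
* paired-pulse ratio from a dF/F0 trace (ratio of 10-ms average peak values
  of the second and first responses) and from quantal success/failure
  counts (P_r = successes / trials per pulse, PPR = P_r2 / P_r1);
* mono-exponential decay-time fitting of current/fluorescence transients,
  and pointwise trace subtraction (e.g. TBOA residual removal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GinkoCalibration",
    "GinkoFitResult",
    "TraceSeries",
    "PrResult",
    "DecayFit",
    "PPRUndefinedError",
    "ginko_response",
    "ginko_invert",
    "fit_ginko_calibration",
    "dff",
    "ppr_from_dff",
    "pr_from_trials",
    "decay_time",
    "efold_time",
    "subtract_residual",
]


class PPRUndefinedError(ValueError):
    """First-pulse release probability is zero; the paired-pulse ratio is undefined."""


@dataclass(frozen=True)
class GinkoCalibration:
    """Logarithmic GINKO2 green/red ratio calibration y = a * ln(x + b).

    Defaults are the fitted values a = 9340 a.u., b = 2.74 mM.
    """

    a: float = 9340.0
    b: float = 2.74

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("calibration coefficients must be positive")


@dataclass(frozen=True)
class GinkoFitResult:
    calibration: GinkoCalibration
    residuals: np.ndarray
    rmse: float


@dataclass
class TraceSeries:
    """A sampled time series (fluorescence or current) with optional stimuli.

    ``t`` is strictly increasing; units (s or ms) are the caller's
    declaration and must be consistent with ``stim_times``.
    """

    t: np.ndarray
    values: np.ndarray
    stim_times: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValueError("t and values must have equal length")
        if self.t.size < 2 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing with >= 2 samples")
        if self.stim_times is not None:
            self.stim_times = np.asarray(self.stim_times, dtype=float)


class PrResult(NamedTuple):
    p1: float
    p2: float
    ppr: float
    n_trials: int


@dataclass(frozen=True)
class DecayFit:
    tau: float
    amplitude: float
    baseline: float
    t_peak: float
    r_squared: float


def ginko_response(k_out, calib: GinkoCalibration = GinkoCalibration()):
    """Ratiometric signal y = a * ln(k_out + b), strictly increasing in k_out."""
    k = np.asarray(k_out, dtype=float)
    if np.any(k < 0):
        raise ValueError("k_out must be non-negative")
    y = calib.a * np.log(k + calib.b)
    return float(y) if y.ndim == 0 else y


def ginko_invert(signal, calib: GinkoCalibration = GinkoCalibration()):
    """Exact inverse of :func:`ginko_response`: k_out = exp(y/a) - b."""
    y = np.asarray(signal, dtype=float)
    k = np.exp(y / calib.a) - calib.b
    if np.any(k < -1e-9):
        raise ValueError("signal implies negative [K+]_out; outside calibration range")
    k = np.maximum(k, 0.0)
    return float(k) if k.ndim == 0 else k


def fit_ginko_calibration(points) -> GinkoFitResult:
    """Least-squares fit of y = a * ln(x + b) to (k_out, ratio) points.

    ``points`` is a sequence of pairs or a DataFrame with columns
    k_out_mM/ratio.  Requires at least 3 distinct k_out values.
    """
    if isinstance(points, pd.DataFrame):
        x = np.asarray(points["k_out_mM"], dtype=float)
        y = np.asarray(points["ratio"], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct k_out values to identify (a, b)")

    def model(xx, a, b):
        return a * np.log(xx + b)

    dy = y.max() - y.min()
    dlx = np.log(x.max() + 1.0) - np.log(x.min() + 1.0)
    a0 = dy / dlx if dlx > 0 else 1.0
    popt, _ = curve_fit(
        model, x, y, p0=(max(a0, 1e-6), 1.0),
        bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
    )
    calib = GinkoCalibration(a=float(popt[0]), b=float(popt[1]))
    resid = y - model(x, *popt)
    return GinkoFitResult(calibration=calib, residuals=resid,
                          rmse=float(np.sqrt(np.mean(resid**2))))


def dff(trace: TraceSeries, baseline_window: tuple[float, float] | None = None) -> TraceSeries:
    """Fractional fluorescence change (F - F0)/F0, F0 = baseline-window mean.

    Default baseline window: the first 100 ms of the trace (pre-stimulus by
    convention); pass an explicit (lo, hi) in the trace's time units
    otherwise.
    """
    if baseline_window is None:
        baseline_window = (trace.t[0], trace.t[0] + 0.1)
    lo, hi = baseline_window
    sel = (trace.t >= lo) & (trace.t <= hi)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    f0 = trace.values[sel].mean()
    if f0 == 0.0:
        raise ValueError("baseline mean is zero; dF/F0 undefined")
    return TraceSeries(
        t=trace.t.copy(),
        values=(trace.values - f0) / f0,
        stim_times=None if trace.stim_times is None else trace.stim_times.copy(),
        meta={**trace.meta, "f0": float(f0)},
    )


def _window_average_peak(t, v, lo, hi, half_width):
    # boundary tolerance keeps the two windows sample-symmetric despite
    # accumulated floating-point error in regularly sampled time bases
    eps = 1e-9 * (t[-1] - t[0])
    idx = np.nonzero((t >= lo - eps) & (t < hi - eps))[0]
    if idx.size == 0:
        raise ValueError("response window contains no samples")
    ip = idx[int(np.argmax(v[idx]))]
    tp = t[ip]
    around = (t >= max(tp - half_width, lo) - eps) & (t <= min(tp + half_width, hi) + eps)
    return float(v[around].mean())


def ppr_from_dff(trace: TraceSeries, stim_times=None, window_ms: float = 10.0) -> float:
    """Paired-pulse ratio of a dF/F0 trace: second / first 10-ms average peak.

    ``trace.t`` and stimulus times are in seconds.  The first response window
    is [stim1, stim2), the second [stim2, stim2 + isi); within each window
    the peak is located and the trace averaged over ``window_ms`` around it.
    """
    stims = np.asarray(trace.stim_times if stim_times is None else stim_times, dtype=float)
    if stims is None or stims.size != 2:
        raise ValueError("exactly two stimulus times are required")
    s1, s2 = float(stims[0]), float(stims[1])
    if s2 <= s1:
        raise ValueError("stimulus times must be increasing")
    isi = s2 - s1
    if s2 + isi > trace.t[-1] + 1e-12:
        raise ValueError("second response window extends beyond the trace")
    half = window_ms * 1e-3 / 2.0
    a1 = _window_average_peak(trace.t, trace.values, s1, s2, half)
    a2 = _window_average_peak(trace.t, trace.values, s2, s2 + isi, half)
    if a1 <= 0:
        raise ValueError("first response is non-positive; PPR undefined")
    return a2 / a1


def pr_from_trials(table: pd.DataFrame, min_trials: int = 15) -> PrResult:
    """Release probabilities and PPR from quantal success/failure trials.

    ``table`` has boolean/0-1 columns ``success1`` and ``success2`` (one row
    per trial) and optionally ``bouton_id``; every bouton must contribute at
    least ``min_trials`` trials (the acquisition floor, lowerable
    explicitly).  P_r = total successes / total trials per pulse;
    PPR = P_r2 / P_r1, undefined (raised) when P_r1 = 0.
    """
    for col in ("success1", "success2"):
        if col not in table.columns:
            raise ValueError(f"trial table lacks required column {col!r}")
    if len(table) < 1:
        raise ValueError("trial table is empty")
    counts = (
        table.groupby("bouton_id").size() if "bouton_id" in table.columns
        else pd.Series({0: len(table)})
    )
    low = counts[counts < min_trials]
    if not low.empty:
        raise ValueError(
            f"boutons {list(low.index)} have fewer than the {min_trials}-trial floor"
        )
    s1 = np.asarray(table["success1"], dtype=float)
    s2 = np.asarray(table["success2"], dtype=float)
    if not (np.isin(s1, (0.0, 1.0)).all() and np.isin(s2, (0.0, 1.0)).all()):
        raise ValueError("trial outcomes must be boolean (0/1)")
    n = len(table)
    p1 = float(s1.sum()) / n
    p2 = float(s2.sum()) / n
    if p1 == 0.0:
        raise PPRUndefinedError("no successes on pulse 1; PPR undefined")
    return PrResult(p1=p1, p2=p2, ppr=p2 / p1, n_trials=n)


def decay_time(trace: TraceSeries, t0: float = 0.0, full: bool = False):
    """Mono-exponential decay time constant of a transient after ``t0``.

    Locates the post-``t0`` peak and least-squares fits
    v(t) = baseline + A * exp(-(t - t_peak)/tau) from the peak onward.
    Invariant under amplitude scaling and baseline offset.  Returns tau in
    the units of ``trace.t`` (a :class:`DecayFit` when ``full=True``).
    Raises on a non-decaying segment.
    """
    sel = trace.t >= t0
    if sel.sum() < 4:
        raise ValueError("too few samples after t0")
    t, v = trace.t[sel], trace.values[sel]
    ip = int(np.argmax(v))
    t_fit, v_fit = t[ip:], v[ip:]
    if t_fit.size < 4:
        raise ValueError("too few samples after the peak")
    base0 = v_fit[-max(3, t_fit.size // 10):].mean()
    amp0 = v_fit[0] - base0
    if amp0 <= 0 or not (v_fit[0] > base0 + 1e-12):
        raise ValueError("segment after t0 does not decay")

    def model(tt, base, amp, tau):
        return base + amp * np.exp(-(tt - t_fit[0]) / tau)

    span = t_fit[-1] - t_fit[0]
    popt, _ = curve_fit(
        model, t_fit, v_fit, p0=(base0, amp0, max(span / 5.0, 1e-9)), maxfev=20000
    )
    base, amp, tau = (float(p) for p in popt)
    if tau <= 0 or amp <= 0:
        raise ValueError("fit did not converge to a decaying exponential")
    resid = v_fit - model(t_fit, *popt)
    ss_tot = float(np.sum((v_fit - v_fit.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    if full:
        return DecayFit(tau=tau, amplitude=amp, baseline=base,
                        t_peak=float(t_fit[0]), r_squared=r2)
    return tau


def efold_time(trace: TraceSeries, t0: float = 0.0) -> float:
    """1/e-crossing alternative to :func:`decay_time` (sensitivity check).

    Time after the post-``t0`` peak at which the transient first falls below
    baseline + amplitude/e, located by linear interpolation; baseline is the
    trailing-decile mean.
    """
    sel = trace.t >= t0
    t, v = trace.t[sel], trace.values[sel]
    if t.size < 4:
        raise ValueError("too few samples after t0")
    ip = int(np.argmax(v))
    t, v = t[ip:], v[ip:]
    base = v[-max(3, v.size // 10):].mean()
    target = base + (v[0] - base) / np.e
    if v[0] <= base + 1e-12:
        raise ValueError("segment after t0 does not decay")
    below = np.nonzero(v <= target)[0]
    if below.size == 0:
        raise ValueError("trace never falls to 1/e of its peak amplitude")
    j = below[0]
    if j == 0:
        return 0.0
    frac = (v[j - 1] - target) / (v[j - 1] - v[j])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]) - t[0])


def subtract_residual(total: TraceSeries, residual: TraceSeries,
                      tol: float | None = None) -> TraceSeries:
    """Subtract a residual trace from a total response, pointwise.

    Identical time bases subtract directly; otherwise the residual is
    linearly interpolated onto ``total.t``, provided the bases overlap
    within half a median sample interval (or ``tol``).
    """
    if total.t.shape == residual.t.shape and np.allclose(total.t, residual.t, rtol=0, atol=1e-12):
        values = total.values - residual.values
    else:
        if tol is None:
            tol = 0.5 * float(np.median(np.diff(total.t)))
        if residual.t[0] > total.t[0] + tol or residual.t[-1] < total.t[-1] - tol:
            raise ValueError("residual trace does not cover the total trace's time base")
        values = total.values - np.interp(total.t, residual.t, residual.values)
    return TraceSeries(t=total.t.copy(), values=values,
                       stim_times=None if total.stim_times is None else total.stim_times.copy(),
                       meta=dict(total.meta))
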