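"""Time-activity curves and cumulated (time-integrated) activity.

The MIRD source term for a region is the cumulated activity
A-tilde = integral of A(t) dt. With terminal sacrifice data the curve is
sparse (typically 24/48/144 h points), so the integral is assembled from a
piecewise model:

* linear rise from (0, 0) to the first measured point (intraperitoneal
  administration implies zero activity in the region at t = 0),
* trapezoids between measured points,
* an analytic mono-exponential tail beyond the last point with rate
  ``lambda_tail = max(fitted effective rate, lambda_phys)``.

The physical floor on the tail makes A-tilde finite for every curve:
apparent biological accumulation cannot outlast physical decay.

Curves handed to the integrator must carry the *physical* activity fraction
(i.e. not decay-corrected); :func:`tac_from_biodist` re-applies physical
decay when built from decay-corrected %IA/g records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nuclide import NuclideProperties

#: conversion from (fraction of IA x hours) to Bq.s per MBq injected
_FRAC_H_TO_BQ_S_PER_MBQ = 3600.0 * 1e6

SCHEMES = ("trapezoid_tail", "single_point_tail")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Fraction of injected activity in one region vs time post-injection."""

    organ: str
    times_h: np.ndarray
    frac_ia: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        a = np.asarray(self.frac_ia, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "frac_ia", a)
        if t.size == 0:
            raise ValueError("time-activity curve needs at least one point")
        if t.shape != a.shape:
            raise ValueError("times_h and frac_ia must have the same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times_h must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times_h must be >= 0")
        if np.any(a < 0):
            raise ValueError("frac_ia must be >= 0")

    def plot(self, ax=None, **kwargs):
        """Plot the curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times_h, self.frac_ia, marker="o", label=self.organ, **kwargs)
        ax.set_xlabel("time post-injection (h)")
        ax.set_ylabel("fraction of injected activity")
        return ax


@dataclass(frozen=True)
class CumulatedActivity:
    """Time-integrated activity per unit injected activity for one region."""

    organ: str
    a_tilde_s_per_MBq: float
    scheme: str
    lambda_eff_per_h: float

    def __post_init__(self) -> None:
        if self.a_tilde_s_per_MBq < 0:
            raise ValueError("a_tilde must be >= 0")


def tac_from_biodist(
    biodist: pd.DataFrame,
    organ: str,
    nuclide: NuclideProperties | None = None,
    decay_corrected: bool = True,
    mouse_id: str | None = None,
) -> TimeActivityCurve:
    """Build a region's physical time-activity curve from %IA/g records.

    Uses the whole-organ ``pct_ia`` column; when several mice contribute at a
    time point (and ``mouse_id`` is not given) their values are averaged,
    which is the mean-curve path of the cohort dosimetry.

    When ``decay_corrected`` is true (the quantification default) the stored
    fractions exclude physical decay, so exp(-lambda_phys t) is re-applied
    here; ``nuclide`` is then required.
    """
    df = biodist[biodist["organ"] == organ]
    if mouse_id is not None:
        df = df[df["mouse_id"] == mouse_id]
    if df.empty:
        raise ValueError(f"no records for organ {organ!r}" + (f", mouse {mouse_id!r}" if mouse_id else ""))
    grouped = df.groupby("time_h", sort=True)["pct_ia"].mean()
    t = grouped.index.to_numpy(float)
    frac = grouped.to_numpy(float) / 100.0
    if decay_corrected:
        if nuclide is None:
            raise ValueError("nuclide required to restore physical decay on decay-corrected records")
        frac = frac * np.exp(-nuclide.lambda_phys_per_h * t)
    return TimeActivityCurve(organ=organ, times_h=t, frac_ia=frac)


def fit_effective_lambda(curve: TimeActivityCurve, window: int = 2) -> float:
    """Effective clearance rate (per hour) from a log-linear tail fit.

    Least-squares fit of log A vs t over the last ``window`` points; with
    ``window=2`` this is the exact two-point formula
    ln(A_i/A_j)/(t_j - t_i). A non-positive result (rising or flat tail) is
    returned as-is with a warning: the integrator applies the physical floor.

    Raises
    ------
    ValueError
        If fewer than two points fall in the window or any activity in the
        window is non-positive (log undefined).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    t = curve.times_h[-window:]
    a = curve.frac_ia[-window:]
    if t.size < 2:
        raise ValueError("need at least 2 points in the tail window")
    if np.any(a <= 0):
        raise ValueError("tail window contains non-positive activities; cannot fit log-linear rate")
    slope = np.polyfit(t, np.log(a), 1)[0]
    lam = -slope
    if lam <= 0:
        warnings.warn(
            f"{curve.organ}: non-positive effective clearance rate ({lam:.3g}/h); "
            "tail appears to rise — the physical decay floor will apply",
            stacklevel=2,
        )
    return float(lam)


def cumulated_activity(
    curve: TimeActivityCurve,
    nuclide: NuclideProperties,
    scheme: str = "trapezoid_tail",
    tail_window: int = 2,
) -> CumulatedActivity:
    """Cumulated activity A-tilde in Bq.s per MBq injected.

    ``trapezoid_tail``: linear ramp from the origin to the first point,
    trapezoids between points, analytic tail A_last / lambda_tail.
    ``single_point_tail``: A-tilde = A(t1) * (t1 + 1/lambda_tail) using the
    first point only — the conservative single-time-point estimate.

    The tail rate is max(fitted effective rate, physical decay constant);
    with fewer than two positive tail points the physical constant is used.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    lam_phys = nuclide.lambda_phys_per_h

    lam_fit = None
    if curve.times_h.size >= 2 and np.all(curve.frac_ia[-tail_window:] > 0):
        lam_fit = fit_effective_lambda(curve, window=min(tail_window, curve.times_h.size))
    lam_tail = max(lam_fit, lam_phys) if lam_fit is not None else lam_phys

    t, a = curve.times_h, curve.frac_ia
    if scheme == "trapezoid_tail":
        ramp = 0.5 * t[0] * a[0]
        body = float(np.trapezoid(a, t)) if t.size > 1 else 0.0
        tail = a[-1] / lam_tail
        area_frac_h = ramp + body + tail
    else:  # single_point_tail
        area_frac_h = a[0] * (t[0] + 1.0 / lam_tail)

    return CumulatedActivity(
        organ=curve.organ,
        a_tilde_s_per_MBq=area_frac_h * _FRAC_H_TO_BQ_S_PER_MBQ,
        scheme=scheme,
        lambda_eff_per_h=float(lam_tail),
    )


def piecewise_model(curve: TimeActivityCurve, lam_tail: float) -> "callable":
    """The piecewise activity model the trapezoid_tail scheme integrates.

    Returns A(t): linear ramp from (0,0) to the first point, linear
    interpolation between points, exponential decay at ``lam_tail`` beyond
    the last point. Exposed so the integral can be cross-checked by direct
    numerical quadrature.
    """
    t, a = curve.times_h, curve.frac_ia

    def model(x):
        x = np.asarray(x, dtype=float)
        inner = np.interp(x, np.concatenate(([0.0], t)), np.concatenate(([0.0], a)))
        tail = a[-1] * np.exp(-lam_tail * (x - t[-1]))
        return np.where(x <= t[-1], inner, tail)

    return model
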