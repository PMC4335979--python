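"""Substrate consumption-rate estimation from concentration time series.

A consumption rate is the magnitude of the fitted linear decrease of an
extracellular substrate concentration over time (g/L/h), with R-squared the
square of the Pearson correlation of the fitted points.  Rates can be fit
over the whole series (truncated at depletion), over an explicit window, or
split at a breakpoint (e.g. the 22-h growth transition) into pre/post
segments.  Mutant-to-reference ratios are rounded half-away-from-zero at a
configurable number of significant figures; the unrounded ratio is always
retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TimeSeries:
    """Concentration (g/L) of one substrate over time (h) for one strain."""

    substrate: str
    strain: str
    points: list  # list[(time_h, concentration_gL)]

    def __post_init__(self) -> None:
        t = np.asarray([p[0] for p in self.points], dtype=float)
        c = np.asarray([p[1] for p in self.points], dtype=float)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.points], dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.points], dtype=float)


@dataclass
class RateFit:
    """One windowed linear fit: rate is the negated slope, >= 0."""

    rate: float
    intercept: float
    r_squared: float
    window: Tuple[float, float]
    n_points: int
    stderr: float = float("nan")


@dataclass
class RateRatio:
    mutant_rate: float
    reference_rate: float
    ratio: float          # unrounded
    ratio_rounded: float
    sig_figs: int


def round_sig(x: float, sig_figs: int) -> float:
    """Round half away from zero at ``sig_figs`` significant figures."""
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    if x == 0:
        return 0.0
    d = Decimal(repr(x)) if not isinstance(x, Decimal) else x
    quantum = Decimal(1).scaleb(d.adjusted() - sig_figs + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def fit_rate(series: TimeSeries,
             window: Optional[Tuple[float, float]] = None) -> RateFit:
    """Ordinary least squares of concentration on time; rate = -slope.

    Without an explicit window the fit stops at depletion: the first
    observation at or below 0 g/L and everything after it are excluded
    (post-depletion zeros would bias the rate downward).  A non-negative
    slope yields rate 0 with a warning.
    """
    t, c = series.times, series.concentrations
    if window is not None:
        t0, t1 = window
        mask = (t >= t0) & (t <= t1)
        t, c = t[mask], c[mask]
    else:
        depleted = np.flatnonzero(c <= 0)
        if depleted.size:
            t, c = t[:depleted[0]], c[:depleted[0]]
    if t.size < 2:
        raise ValueError(
            f"fit_rate: need >= 2 points in the fitting window, got {t.size}")
    if np.ptp(t) == 0:
        raise ValueError("fit_rate: zero time variance in the fitting window")
    win = (float(t[0]), float(t[-1]))
    if np.ptp(c) == 0:
        warnings.warn(
            f"{series.strain}/{series.substrate}: constant concentration; "
            "rate 0, R^2 undefined (reported as 0)")
        return RateFit(0.0, float(c[0]), 0.0, win, int(t.size), 0.0)
    res = stats.linregress(t, c)
    rate = -res.slope
    if rate < 0:
        warnings.warn(
            f"{series.strain}/{series.substrate}: concentration increases "
            "over the window; consumption rate reported as 0")
        rate = 0.0
    return RateFit(float(rate), float(res.intercept), float(res.rvalue ** 2),
                   win, int(t.size), float(res.stderr))


def segmented_rates(series: TimeSeries,
                    breakpoint: float) -> Tuple[RateFit, RateFit]:
    """Independent fits before and after a breakpoint (h).

    A point sampled exactly at the breakpoint belongs to both windows.
    """
    t = series.times
    n_before = int((t <= breakpoint).sum())
    n_after = int((t >= breakpoint).sum())
    if n_before < 2:
        raise ValueError(
            f"segmented_rates: fewer than 2 points before breakpoint {breakpoint}")
    if n_after < 2:
        raise ValueError(
            f"segmented_rates: fewer than 2 points after breakpoint {breakpoint}")
    before = fit_rate(series, window=(float(t[0]), float(breakpoint)))
    after = fit_rate(series, window=(float(breakpoint), float(t[-1])))
    return before, after


def rate_ratio(mutant: RateFit, reference: RateFit,
               sig_figs: int = 2) -> RateRatio:
    """Mutant-to-reference rate ratio, exact then rounded for display."""
    if reference.rate <= 0:
        raise ValueError("rate_ratio: reference rate must be positive")
    exact = Decimal(repr(mutant.rate)) / Decimal(repr(reference.rate))
    return RateRatio(mutant.rate, reference.rate, float(exact),
                     round_sig(exact, sig_figs), sig_figs)


def rate_table(fits: Dict[Tuple[str, str], RateFit], reference_strain: str,
               sig_figs: int = 2) -> pd.DataFrame:
    """One row per strain, one (rate, ratio, R^2) column triple per substrate.

    Reference-strain ratios are exactly 1.  A substrate without a reference
    fit, or with a zero reference rate, is an error.
    """
    substrates = sorted({sub for _, sub in fits})
    strains = list(dict.fromkeys(strain for strain, _ in fits))
    for sub in substrates:
        if (reference_strain, sub) not in fits:
            raise ValueError(
                f"rate_table: no fit for reference strain {reference_strain!r} "
                f"on substrate {sub!r}")
    rows = []
    for strain in strains:
        row: Dict[str, float] = {"strain": strain}
        for sub in substrates:
            key = (strain, sub)
            if key not in fits:
                continue
            fit = fits[key]
            ratio = rate_ratio(fit, fits[(reference_strain, sub)], sig_figs)
            row[f"{sub}_rate"] = fit.rate
            row[f"{sub}_ratio"] = (1.0 if strain == reference_strain
                                   else ratio.ratio_rounded)
            row[f"{sub}_r2"] = fit.r_squared
        rows.append(row)
    return pd.DataFrame(rows)
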