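"""Rhythmicity analysis: Lomb-Scargle periodogram and autocorrelation.

The Lomb-Scargle periodogram estimates spectral power by least-squares
sinusoid fitting, works with unevenly spaced samples, and admits an
analytic false-alarm significance level; the classical (Lomb)
normalisation is used, under which pure Gaussian noise gives power that is
exponentially distributed with unit mean.  The normalised autocorrelation
function contrasts strictly periodic features (the morning peak, sharp
recurrence at 24 h lags) with temporally stochastic ones (the burst, whose
day-to-day timing jitter suppresses the 24 h correlation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .dam_io import ActivitySeries

__all__ = ["Periodogram", "AutocorrResult", "lomb_scargle", "autocorrelation"]


@dataclass
class Periodogram:
    """Normalised Lomb-Scargle power on a period grid (hours)."""

    periods_h: np.ndarray
    power: np.ndarray
    significance_level: float   # power threshold at the requested FAP
    fap: float

    def peak_period(self) -> float:
        """Period of the global power maximum, hours."""
        return float(self.periods_h[int(np.argmax(self.power))])

    def significant(self) -> bool:
        return bool(np.max(self.power) > self.significance_level)


def lomb_scargle(
    series: ActivitySeries,
    period_range: tuple[float, float] = (16.0, 32.0),
    period_step_h: float = 0.05,
    fap: float = 0.05,
    periods_h: np.ndarray | None = None,
) -> Periodogram:
    """Classically normalised Lomb-Scargle periodogram of an activity series.

    The period grid spans ``period_range`` (hours, default the circadian
    band 16-32 h) in steps of ``period_step_h``.  Power is normalised by
    the sample variance, so white noise gives Exp(1)-distributed power and
    the analytic false-alarm threshold is
    ``-ln(1 - (1 - fap)**(1/M))`` with ``M`` the number of independent
    frequencies (naturally spaced count ``T * (f_max - f_min)``).

    A constant series returns zero power everywhere (defined, not an
    error).  Requires a recording of at least two maximal periods; for
    circadian-range analysis use three days or more.  An explicit
    ``periods_h`` grid overrides ``period_range``/``period_step_h``.
    """
    if periods_h is not None:
        periods = np.asarray(periods_h, dtype=float)
        lo, hi = float(periods.min()), float(periods.max())
    else:
        lo, hi = period_range
        periods = np.arange(lo, hi + period_step_h / 2, period_step_h)
    if not 0 < lo <= hi:
        raise ValueError("periods must be positive")
    t_h = (series.bin_starts() + series.bin_width / 2.0) / 3600.0
    duration_h = series.duration_s / 3600.0
    if duration_h < 2 * hi:
        raise ValueError(
            f"recording of {duration_h:.0f} h is too short for periods up to {hi} h"
        )
    m_indep = max(duration_h * (1.0 / lo - 1.0 / hi), 1.0)
    threshold = -math.log(1.0 - (1.0 - fap) ** (1.0 / m_indep))
    y = series.counts.astype(float)
    var = y.var(ddof=1)
    if var == 0:
        return Periodogram(periods, np.zeros_like(periods), threshold, fap)
    omega = 2 * np.pi / periods
    raw = signal.lombscargle(t_h, y - y.mean(), omega)
    return Periodogram(periods, raw / var, threshold, fap)


@dataclass
class AutocorrResult:
    """Normalised autocorrelation; value at lag zero is 1 by construction."""

    lags_h: np.ndarray
    values: np.ndarray


def autocorrelation(series: ActivitySeries, max_lag_h: float = 48.0) -> AutocorrResult:
    """Biased-normalised autocorrelation of a (mean-subtracted) series.

    ``acf(tau) = sum (x_t - xbar)(x_{t+tau} - xbar) / sum (x_t - xbar)^2``
    for lags up to ``max_lag_h``; the lag grid follows the bin width.  A
    constant series has no defined autocorrelation and raises.
    """
    x = series.counts.astype(float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    max_k = min(int(max_lag_h * 3600 / series.bin_width), len(x) - 1)
    # FFT-based full correlation, biased normalisation.
    nfft = 1
    while nfft < 2 * len(x):
        nfft *= 2
    f = np.fft.rfft(x, nfft)
    corr = np.fft.irfft(f * np.conj(f), nfft)[: max_k + 1]
    lags = np.arange(max_k + 1) * (series.bin_width / 3600.0)
    return AutocorrResult(lags_h=lags, values=corr / denom)
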