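"""Population-averaged activity profiles and peak morphometrics.

Population-level analysis folds 30-minute-binned activity on the
zeitgeber cycle and averages across flies and days, which brings out the
synchronized morning (M), evening (E) and midday (A) peaks while washing
out temporally stochastic events.  Peak morphometrics follow the standard
conventions: full width at half maximum above a local baseline, peak area
as total activity within +/-3 h of the peak, and midday activity as the
mean over ZT 4-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dam_io import ActivitySeries, rebin
from .light_model import LightProgram

__all__ = [
    "PopulationProfile",
    "PeakMetrics",
    "CountDistribution",
    "population_average",
    "find_peaks",
    "half_width",
    "peak_area",
    "midday_activity",
    "count_distribution",
]

logger = logging.getLogger(__name__)

PROFILE_BIN_S = 1800


@dataclass
class PopulationProfile:
    """Cross-fly mean activity per 30-min bin folded on one zeitgeber cycle."""

    zt_grid: np.ndarray        # bin start times, hours in [0, cycle length)
    mean_counts: np.ndarray    # mean counts per 30-min bin per fly
    n_flies: int
    n_days: int
    bin_width: int = PROFILE_BIN_S

    @property
    def bin_h(self) -> float:
        return self.bin_width / 3600.0

    @property
    def cycle_h(self) -> float:
        return float(len(self.mean_counts) * self.bin_h)

    def centers(self) -> np.ndarray:
        return self.zt_grid + self.bin_h / 2.0

    def value_near(self, zt_h: float) -> float:
        """Profile value of the bin containing the given ZT (circular)."""
        i = int((zt_h % self.cycle_h) // self.bin_h)
        return float(self.mean_counts[i])


@dataclass
class PeakMetrics:
    """Morphometrics of one activity peak on the folded profile."""

    peak_kind: str             # "M", "E" or "A"
    peak_time: float           # ZT hours (bin center)
    height: float              # counts per 30-min bin
    half_width: float | None = None   # FWHM, hours
    area: float | None = None         # counts within +/-3 h
    offset: float | None = None       # M: hours after lights-on; E: before lights-off
    width_clipped: bool = False       # FWHM hit the search-window edge


def population_average(
    series_list: list[ActivitySeries],
    program: LightProgram,
) -> PopulationProfile:
    """Fold a cohort on the zeitgeber cycle: 30-min bins, mean over flies x days."""
    if not series_list:
        raise ValueError("at least one fly is required")
    if program.period_s <= 0 or program.pattern_kind == "pulse_train":
        raise ValueError("population folding requires a periodic program")
    per_bins = program.period_s / PROFILE_BIN_S
    if per_bins != int(per_bins):
        raise ValueError("cycle length must be a multiple of 30 minutes")
    per_bins = int(per_bins)
    n = len(series_list[0])
    folded = []
    for s in series_list:
        if len(s) != n or s.bin_width != series_list[0].bin_width:
            raise ValueError("ragged cohort: series lengths/bin widths differ")
        r = rebin(s, PROFILE_BIN_S)
        n_days = len(r) // per_bins
        if n_days < 1:
            raise ValueError("series shorter than one full cycle")
        folded.append(r.counts[: n_days * per_bins].reshape(n_days, per_bins).mean(axis=0))
    mean = np.mean(folded, axis=0)
    return PopulationProfile(
        zt_grid=np.arange(per_bins) * (PROFILE_BIN_S / 3600.0),
        mean_counts=mean,
        n_flies=len(series_list),
        n_days=n_days,
    )


# ----------------------------------------------------------------------
# Peak localisation
# ----------------------------------------------------------------------

def _window_indices(profile: PopulationProfile, lo_h: float, hi_h: float) -> np.ndarray:
    """Bin indices whose centers fall in [lo, hi) ZT hours, circularly."""
    c = profile.centers()
    lo = lo_h % profile.cycle_h
    hi = hi_h % profile.cycle_h
    if lo < hi:
        mask = (c >= lo) & (c < hi)
    else:  # wraps midnight
        mask = (c >= lo) | (c < hi)
    return np.nonzero(mask)[0]


def find_peaks(
    profile: PopulationProfile,
    program: LightProgram,
    a_peak_frac: float = 0.2,
) -> list[PeakMetrics]:
    """Locate the M, E and (optional) A peaks on the folded profile.

    M is the maximum within +/-2 h of lights-on, E within the 4 h before
    lights-off, and A an optional midday (ZT 4-8) maximum that exceeds the
    midday trough by at least ``a_peak_frac`` of the M height.  A flat
    profile yields no peaks.
    """
    y = profile.mean_counts
    if np.ptp(y) == 0:
        return []
    day = program.day_length_h
    out: list[PeakMetrics] = []

    m_idx = _window_indices(profile, -2.0, 2.0)
    i = m_idx[int(np.argmax(y[m_idx]))]
    t = float(profile.centers()[i])
    m_height = float(y[i])
    m_offset = t if t <= profile.cycle_h / 2 else t - profile.cycle_h
    out.append(PeakMetrics("M", t, m_height, offset=m_offset))

    e_idx = _window_indices(profile, day - 4.0, day)
    i = e_idx[int(np.argmax(y[e_idx]))]
    t = float(profile.centers()[i])
    out.append(PeakMetrics("E", t, float(y[i]), offset=day - t))

    if day >= 8:
        a_idx = _window_indices(profile, 4.0, 8.0)
        i = a_idx[int(np.argmax(y[a_idx]))]
        trough = float(np.min(y[a_idx]))
        if float(y[i]) - trough >= a_peak_frac * m_height:
            t = float(profile.centers()[i])
            out.append(PeakMetrics("A", t, float(y[i])))
    return out


def half_width(profile: PopulationProfile, peak: PeakMetrics,
               baseline_window_h: float = 3.0) -> float:
    """Full width at half maximum of a baseline-subtracted peak, in hours.

    The baseline is the profile minimum within +/-3 h of the peak.  Half
    crossings are located by linear interpolation between 30-min grid
    points, scanning circularly up to half a cycle each side; if the half
    level is never crossed on one side the width is measured to the scan
    edge and the peak is flagged ``width_clipped``.
    """
    y = profile.mean_counts
    n = len(y)
    c = profile.centers()
    ip = int(((peak.peak_time % profile.cycle_h) // profile.bin_h))
    base_idx = _window_indices(profile, peak.peak_time - baseline_window_h,
                               peak.peak_time + baseline_window_h)
    baseline = float(np.min(y[base_idx]))
    height = float(y[ip]) - baseline
    if height <= 0:
        raise ValueError("peak has no height above local baseline")
    half = baseline + height / 2.0

    def scan(direction: int) -> tuple[float, bool]:
        # hours from peak center to the half crossing in one direction
        prev = float(y[ip])
        max_steps = n // 2
        for step in range(1, max_steps + 1):
            j = (ip + direction * step) % n
            cur = float(y[j])
            if cur <= half:
                frac = (prev - half) / (prev - cur) if prev != cur else 1.0
                return (step - 1 + frac) * profile.bin_h, False
            prev = cur
        return max_steps * profile.bin_h, True

    left, lclip = scan(-1)
    right, rclip = scan(+1)
    if lclip or rclip:
        logger.warning("half level not crossed on one side; width clipped")
    peak.half_width = left + right
    peak.width_clipped = lclip or rclip
    return peak.half_width


def peak_area(profile: PopulationProfile, peak: PeakMetrics,
              window_h: float = 3.0) -> float:
    """Total activity from 3 h before to 3 h after the peak (counts).

    The sum of the 30-min mean counts over the window, wrapping across
    midnight when necessary.
    """
    idx = _window_indices(profile, peak.peak_time - window_h, peak.peak_time + window_h)
    peak.area = float(np.sum(profile.mean_counts[idx]))
    return peak.area


def midday_activity(profile: PopulationProfile, program: LightProgram) -> float:
    """Mean 30-min activity over ZT 4-8 (requires a day of at least 8 h)."""
    if program.day_length_h < 8:
        raise ValueError("midday activity is defined for days of >= 8 h")
    idx = _window_indices(profile, 4.0, 8.0)
    return float(np.mean(profile.mean_counts[idx]))


# ----------------------------------------------------------------------
# Activity-count probability distribution
# ----------------------------------------------------------------------

@dataclass
class CountDistribution:
    """Normalised histogram of pooled 3-min activity counts."""

    values: np.ndarray       # distinct counts (0..max)
    probs: np.ndarray        # probabilities, summing to 1
    burst_marker: float | None = None  # mean detected-burst count, if supplied

    def mode(self) -> int:
        return int(self.values[int(np.argmax(self.probs))])

    def mean(self) -> float:
        return float(np.sum(self.values * self.probs))


def count_distribution(series_list: list[ActivitySeries],
                       burst_events=None) -> CountDistribution:
    """Probability distribution of all 3-min counts in a cohort.

    ``burst_events`` (detected :class:`~flyburst.burst_detector.BurstEvent`
    records) optionally supply the cohort's mean burst count, reported as a
    marker alongside the distribution.
    """
    if not series_list:
        raise ValueError("at least one series is required")
    pooled = np.concatenate([np.asarray(s.counts) for s in series_list])
    values = np.arange(int(pooled.max()) + 1)
    probs = np.bincount(pooled.astype(int), minlength=len(values)) / pooled.size
    marker = None
    if burst_events:
        marker = float(np.mean([e.count for e in burst_events]))
    return CountDistribution(values=values, probs=probs, burst_marker=marker)
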