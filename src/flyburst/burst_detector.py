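"""Single-fly detection of the stochastic post-dawn activity burst.

The burst is a transient (~2-3 min) spike in a single fly's beam-crossing
counts that appears at most once per light cycle, typically 0.5-5 h after
lights-on, with a magnitude around ten standard deviations above the fly's
mean 3-minute activity and roughly five-fold the morning-peak maximum.

Detection operates on 3-minute-binned series, one candidate per light
cycle (lights-on to next lights-on):

1. take the bin with the highest count in the cycle (earliest wins ties);
2. if other bins within a +/-10 min window carry comparably high counts
   (>= ``merge_frac`` of the maximum) replace them by one averaged event
   (count = mean of qualifying counts, time = count-weighted mean time);
3. discard the candidate if it falls within +/-5 min of any light
   transition (startle response);
4. discard it unless its count exceeds the fly's whole-recording mean by
   at least ``z_min`` standard deviations.

Night-time candidates are retained but flagged ``in_light=False`` so the
late (~10 h) minority cluster of delays can be studied separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dam_io import ActivitySeries
from .light_model import LightProgram

__all__ = [
    "BurstEvent",
    "fly_baseline",
    "detect_bursts",
    "burst_delay",
    "m_peak_activity",
    "morning_window_indices",
]

#: Half-width of the startle-exclusion window around light transitions (s).
STARTLE_HALFWIDTH_S = 300.0

#: Morning-peak search window after lights-on (s).
M_WINDOW_S = 3600.0


@dataclass
class BurstEvent:
    """A detected activity burst and its per-event statistics."""

    fly_id: str
    cycle_index: int
    bin_time: float          # seconds from program zero (start of the bin)
    count: float             # counts per 3 min (mean of merged bins)
    zscore: float            # (count - fly mean) / fly SD
    delta_t: float           # hours since the cycle's lights-on
    ratio_to_m: float | None  # count / morning-peak maximum (None if M == 0)
    merged_from: int = 1
    in_light: bool = True


def fly_baseline(series_3min: ActivitySeries) -> tuple[float, float]:
    """Mean and standard deviation over all 3-min bins of the recording.

    The moments are computed over the whole recording, burst bins included
    (at one burst bin per day they barely move the mean; see the package
    methods note for the variance caveat).  An all-zero series returns
    ``(0, 0)`` and the detection threshold degenerates downstream.
    """
    c = np.asarray(series_3min.counts, dtype=float)
    if c.size == 0:
        raise ValueError("empty series")
    return float(c.mean()), float(c.std(ddof=0))


def _startle_mask(bin_starts: np.ndarray, bin_width: float, program: LightProgram,
                  halfwidth_s: float) -> np.ndarray:
    """True where a bin's center lies within +/-halfwidth of any transition."""
    centers = bin_starts + bin_width / 2.0
    mask = np.zeros(len(centers), dtype=bool)
    for t, _d in program.transitions:
        mask |= np.abs(centers - t) < halfwidth_s
    return mask


def morning_window_indices(
    series_3min: ActivitySeries,
    program: LightProgram,
    cycle_on_s: float,
    window_s: float = M_WINDOW_S,
    startle_halfwidth_s: float = STARTLE_HALFWIDTH_S,
) -> np.ndarray:
    """Indices of the 3-min bins scanned for the morning-peak maximum.

    The window spans ``[lights_on, lights_on + window_s)`` with bins in the
    startle-exclusion zone of any transition removed.
    """
    starts = series_3min.bin_starts()
    in_win = (starts >= cycle_on_s) & (starts < cycle_on_s + window_s)
    startle = _startle_mask(starts, series_3min.bin_width, program, startle_halfwidth_s)
    return np.nonzero(in_win & ~startle)[0]


def m_peak_activity(
    series_3min: ActivitySeries,
    program: LightProgram,
    cycle_on_s: float,
    window_s: float = M_WINDOW_S,
    exclude: tuple[int, ...] = (),
    statistic: str = "max",
) -> float:
    """Morning-peak activity of one cycle, in counts per 3 min.

    By default the maximum 3-min count within one hour of lights-on
    (startle bins excluded); ``statistic="mean"`` gives the window-average
    variant.  Bins listed in ``exclude`` (e.g. an accepted burst that falls
    inside the window) are not considered.  Returns 0 for a flat window;
    callers flag the ratio as missing in that case.
    """
    idx = morning_window_indices(series_3min, program, cycle_on_s, window_s)
    idx = np.array([i for i in idx if i not in set(exclude)], dtype=int)
    if idx.size == 0:
        return 0.0
    vals = series_3min.counts[idx].astype(float)
    if statistic == "max":
        return float(vals.max())
    if statistic == "mean":
        return float(vals.mean())
    raise ValueError(f"unknown statistic {statistic!r}")


def detect_bursts(
    series_3min: ActivitySeries,
    program: LightProgram,
    z_min: float = 10.0,
    merge_window_s: float = 600.0,
    merge_frac: float = 0.8,
    startle_halfwidth_s: float = STARTLE_HALFWIDTH_S,
    m_statistic: str = "max",
) -> list[BurstEvent]:
    """Detect at most one burst per light cycle in a 3-min-binned series.

    Returns accepted events only; an empty list is a valid result (e.g. in
    constant darkness, where there are no light cycles).
    """
    if series_3min.bin_width != 180:
        raise ValueError("burst detection operates on 3-minute bins")
    mean, sd = fly_baseline(series_3min)
    if sd > 0:
        threshold = mean + z_min * sd
    else:
        # Degenerate flat baseline: accept any positive excursion.
        threshold = mean + 1.0
    starts = series_3min.bin_starts()
    startle = _startle_mask(starts, series_3min.bin_width, program, startle_halfwidth_s)
    counts = series_3min.counts.astype(float)
    events: list[BurstEvent] = []
    for ci, (on, nxt) in enumerate(program.cycles()):
        sel = np.nonzero((starts >= on) & (starts < nxt))[0]
        if sel.size == 0:
            continue
        # (1) maximum bin of the cycle; earliest wins ties.
        imax = sel[int(np.argmax(counts[sel]))]
        cmax = counts[imax]
        if cmax <= 0:
            continue
        # (2) merge comparably high neighbours within the merge window.
        near = sel[
            (np.abs(starts[sel] - starts[imax]) <= merge_window_s)
            & (counts[sel] >= merge_frac * cmax)
        ]
        count = float(counts[near].mean())
        time = float(np.average(starts[near], weights=counts[near]))
        merged_from = int(near.size)
        # (3) startle exclusion on the maximum bin.
        if startle[imax]:
            continue
        # (4) amplitude threshold.
        if count < threshold:
            continue
        zscore = (count - mean) / sd if sd > 0 else math.inf
        delta_t = (time - on) / 3600.0
        in_light = bool(program.intensity(time + series_3min.bin_width / 2.0) > 0)
        m_act = m_peak_activity(
            series_3min, program, on, exclude=tuple(near), statistic=m_statistic
        )
        ratio = count / m_act if m_act > 0 else None
        events.append(
            BurstEvent(
                fly_id=series_3min.fly_id,
                cycle_index=ci,
                bin_time=time,
                count=count,
                zscore=zscore,
                delta_t=delta_t,
                ratio_to_m=ratio,
                merged_from=merged_from,
                in_light=in_light,
            )
        )
    return events


def burst_delay(event: BurstEvent, program: LightProgram) -> float:
    """Hours from the event's cycle lights-on to the event bin."""
    on, _ = program.cycles()[event.cycle_index]
    return (event.bin_time - on) / 3600.0
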