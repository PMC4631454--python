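"""Reading, writing and rebinning DAM-style activity monitor files.

The Drosophila Activity Monitor (DAM, TriKinetics) records infra-red beam
crossings per fly per fixed time bin and dumps them into tab-delimited text
"monitor" files.  This module fixes one dialect and rejects others rather
than guessing:

    <index>\t<DD Mon YY>\t<HH:MM:SS>\t<status>\t<ch1>\t...\t<chN>

with one row per bin, a constant status column of ``1`` for OK rows, and up
to 32 channel columns.  Timestamps are translated to/from seconds from
program zero using a fixed synthetic epoch, so a write/read round trip is
the identity on counts, bin width and start time.

Binning is half-open ``[t, t + w)`` throughout.  Recordings are made in
20-second bins and rebinned to 3 minutes for single-fly analysis and to 30
minutes for population-level analysis.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["ActivitySeries", "read_dam", "write_dam", "rebin", "series_to_frame"]

logger = logging.getLogger(__name__)

#: Synthetic epoch mapping seconds-from-program-zero to calendar timestamps.
DAM_EPOCH = _dt.datetime(2015, 1, 1, 0, 0, 0)

MAX_CHANNELS = 32

OK_STATUS = "1"


@dataclass
class ActivitySeries:
    """One fly's beam-crossing counts at fixed bin width.

    ``start_time`` is in seconds from program zero (the first lights-on);
    ``counts`` are non-negative integers, one per ``bin_width``-second bin.
    """

    fly_id: str
    start_time: float
    bin_width: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.dtype.kind not in "iu":
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def duration_s(self) -> float:
        return float(len(self.counts) * self.bin_width)

    def bin_starts(self) -> np.ndarray:
        """Start time of every bin, seconds from program zero."""
        return self.start_time + self.bin_width * np.arange(len(self.counts), dtype=float)


def rebin(series: ActivitySeries, target_width: int) -> ActivitySeries:
    """Aggregate counts into wider bins by summation.

    ``target_width`` must be an integer multiple of the series bin width.
    A trailing partial bin is dropped with a logged warning; otherwise
    total counts are conserved exactly.
    """
    w = series.bin_width
    if target_width == w:
        return replace(series, counts=series.counts.copy())
    if target_width % w != 0:
        raise ValueError(
            f"target width {target_width} is not a multiple of bin width {w}"
        )
    k = target_width // w
    n_full = len(series.counts) // k
    tail = len(series.counts) - n_full * k
    if tail:
        logger.warning(
            "rebin: dropping trailing partial bin of %d x %d s", tail, w
        )
    counts = series.counts[: n_full * k].reshape(n_full, k).sum(axis=1)
    return ActivitySeries(
        fly_id=series.fly_id,
        start_time=series.start_time,
        bin_width=target_width,
        counts=counts,
    )


# ----------------------------------------------------------------------
# Monitor file dialect
# ----------------------------------------------------------------------

def write_dam(series_list: list[ActivitySeries], path) -> None:
    """Write a cohort as a tab-delimited DAM monitor file.

    All series must share bin width, start time and length; at most 32
    channels.  Output is bit-stable: fixed column order and date format.
    """
    if len(series_list) > MAX_CHANNELS:
        raise ValueError(f"at most {MAX_CHANNELS} channels per monitor file")
    if series_list:
        ref = series_list[0]
        for s in series_list[1:]:
            if s.bin_width != ref.bin_width or len(s) != len(ref) or s.start_time != ref.start_time:
                raise ValueError("all series must share bin width, length and start time")
        n_rows, w, t0 = len(ref), ref.bin_width, ref.start_time
    else:
        n_rows, w, t0 = 0, 0, 0.0
    with open(path, "w") as fh:
        fh.write("#DAM\tbin_s=%d\n" % w)
        for i in range(n_rows):
            ts = DAM_EPOCH + _dt.timedelta(seconds=t0 + i * w)
            row = [
                str(i + 1),
                ts.strftime("%d %b %y"),
                ts.strftime("%H:%M:%S"),
                OK_STATUS,
            ] + [str(int(s.counts[i])) for s in series_list]
            fh.write("\t".join(row) + "\n")


def read_dam(path) -> list[ActivitySeries]:
    """Read a monitor file written in this package's DAM dialect.

    Returns one series per channel column, fly ids ``ch1`` .. ``chN``.
    Rows with a non-OK status are flagged in the log but still parsed;
    malformed rows or non-monotone timestamps raise with the line number.
    """
    rows: list[list[str]] = []
    bin_s = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#DAM"):
                for tok in line.split("\t")[1:]:
                    if tok.startswith("bin_s="):
                        bin_s = int(tok[6:])
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}: malformed row at line {lineno}")
            try:
                _dt.datetime.strptime(parts[1] + " " + parts[2], "%d %b %y %H:%M:%S")
                [int(p) for p in parts[4:]]
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from None
            if parts[3] != OK_STATUS:
                logger.warning("%s: line %d flagged with status %s", path, lineno, parts[3])
            rows.append(parts)
    if not rows:
        return []
    stamps = [
        _dt.datetime.strptime(r[1] + " " + r[2], "%d %b %y %H:%M:%S") for r in rows
    ]
    secs = np.array([(ts - DAM_EPOCH).total_seconds() for ts in stamps])
    if len(secs) > 1:
        steps = np.diff(secs)
        if np.any(steps <= 0):
            bad = int(np.argmax(steps <= 0)) + 2
            raise ValueError(f"{path}: non-monotone timestamps at row {bad}")
        if bin_s is None:
            bin_s = int(steps[0])
        if not np.all(steps == bin_s):
            raise ValueError(f"{path}: irregular row spacing (expected {bin_s} s)")
    elif bin_s is None:
        raise ValueError(f"{path}: single-row file without a bin_s header")
    n_ch = len(rows[0]) - 4
    if any(len(r) - 4 != n_ch for r in rows):
        raise ValueError(f"{path}: inconsistent channel count across rows")
    counts = np.array([[int(v) for v in r[4:]] for r in rows], dtype=np.int64)
    return [
        ActivitySeries(
            fly_id=f"ch{c + 1}",
            start_time=float(secs[0]),
            bin_width=int(bin_s),
            counts=counts[:, c],
        )
        for c in range(n_ch)
    ]


def series_to_frame(series: ActivitySeries) -> pd.DataFrame:
    """CSV-friendly two-column representation ``(time_s, count)``."""
    return pd.DataFrame({"time_s": series.bin_starts(), "count": series.counts})
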