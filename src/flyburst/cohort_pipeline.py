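"""Cohort-level burst statistics and end-to-end orchestration.

Aggregates single-fly burst detections into the population quantities of
interest: incidence (percent of flies showing a light-associated burst per
cycle), the delay (lights-on to burst) distribution and its two-cluster
Gaussian-mixture decomposition, burst-to-morning-peak ratio summaries, and
nonparametric group comparisons.  ``run_report`` strings the full pipeline
together from a monitor file and a light program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .activity_metrics import (count_distribution, find_peaks, half_width,
                               midday_activity, peak_area, population_average)
from .burst_detector import BurstEvent, detect_bursts
from .dam_io import ActivitySeries, read_dam, rebin
from .light_model import LightProgram
from .rhythm_analysis import lomb_scargle

__all__ = [
    "IncidenceResult",
    "DelayClusters",
    "RatioSummary",
    "is_light_associated",
    "incidence",
    "delay_clusters",
    "ratio_summary",
    "compare_incidence",
    "run_report",
]

logger = logging.getLogger(__name__)

#: A burst is attributed to its light pulse if it occurs during the light
#: phase or within this many hours of lights-on (the observed response
#: window), whichever window is longer.  Short pulses elicit bursts that
#: fall in the following darkness and still count.
BURST_WINDOW_H = 5.0


def is_light_associated(event: BurstEvent, program: LightProgram,
                        window_h: float = BURST_WINDOW_H) -> bool:
    """Whether an accepted event is attributed to its cycle's light pulse."""
    day_h = program.cycle_day_length_h(event.cycle_index)
    return event.delta_t <= max(day_h, window_h)


@dataclass
class IncidenceResult:
    """Percent of flies showing a light-associated burst, per cycle."""

    group_label: str
    per_cycle_percent: np.ndarray
    n_flies: int
    n_cycles: int

    @property
    def mean_percent(self) -> float:
        return float(np.mean(self.per_cycle_percent))

    @property
    def sd_percent(self) -> float:
        return float(np.std(self.per_cycle_percent, ddof=1)) if self.n_cycles > 1 else 0.0


def incidence(
    events: list[BurstEvent],
    n_flies: int,
    program: LightProgram,
    group_label: str = "",
    window_h: float = BURST_WINDOW_H,
    per: str = "cycle",
) -> IncidenceResult:
    """Burst incidence of a cohort.

    ``per="cycle"`` (default): for each light cycle, the percent of flies
    with at least one accepted light-associated event, reported per cycle
    and averaged.  ``per="experiment"``: a single percent of flies with at
    least one such event anywhere in the recording.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be positive")
    cycles = program.cycles()
    keep = [e for e in events if is_light_associated(e, program, window_h)]
    if per == "experiment":
        frac = len({e.fly_id for e in keep}) / n_flies
        return IncidenceResult(group_label, np.array([100.0 * frac]), n_flies, 1)
    if per != "cycle":
        raise ValueError("per must be 'cycle' or 'experiment'")
    pct = []
    for ci in range(len(cycles)):
        flies = {e.fly_id for e in keep if e.cycle_index == ci}
        pct.append(100.0 * len(flies) / n_flies)
    return IncidenceResult(group_label, np.asarray(pct), n_flies, len(cycles))


# ----------------------------------------------------------------------
# Delay clustering: one-dimensional Gaussian mixture via EM
# ----------------------------------------------------------------------

@dataclass
class DelayClusters:
    """Two-component Gaussian-mixture decomposition of burst delays."""

    means: np.ndarray        # hours, sorted ascending
    sds: np.ndarray
    weights: np.ndarray      # sum to 1
    assignments: np.ndarray  # hard labels per delay (into sorted components)
    log_likelihood: float
    degenerate: bool = False


def _em_1d(x: np.ndarray, mu: np.ndarray, sd: np.ndarray, w: np.ndarray,
           max_iter: int, tol: float, sd_floor: float):
    """EM for a 1-D Gaussian mixture; the log-likelihood never decreases."""
    n, k = len(x), len(mu)
    prev_ll = -np.inf
    for _ in range(max_iter):
        logp = (np.log(w)[None, :]
                - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
                - np.log(sd)[None, :] - 0.5 * np.log(2 * np.pi))
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        if ll < prev_ll - 1e-8:
            raise AssertionError("EM log-likelihood decreased")
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, sd_floor ** 2))
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    return mu, sd, w, prev_ll


def delay_clusters(
    delays,
    k: int = 2,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-10,
    sd_floor: float = 1e-2,
) -> DelayClusters:
    """Fit a ``k``-component 1-D Gaussian mixture to burst delays (hours).

    Expectation-maximisation with ``n_restarts`` random initialisations
    (best final likelihood wins) and a fixed seed.  Components are
    returned sorted by mean.  An (effectively) constant sample yields a
    degenerate-flagged result with the SD floor applied.  At least 10
    delays are recommended; fewer than ``k`` is an error.
    """
    x = np.asarray(delays, dtype=float)
    if x.size < k:
        raise ValueError(f"need at least {k} delays to fit {k} components")
    if x.size < 10:
        logger.warning("fitting a mixture to only %d delays", x.size)
    rng = np.random.default_rng(seed)
    if np.ptp(x) < sd_floor:
        mu = np.full(k, x.mean())
        return DelayClusters(mu, np.full(k, sd_floor), np.full(k, 1.0 / k),
                             np.zeros(x.size, dtype=int), float("nan"),
                             degenerate=True)
    best = None
    for _ in range(n_restarts):
        mu0 = rng.choice(x, size=k, replace=False)
        sd0 = np.full(k, max(x.std(ddof=0), sd_floor))
        w0 = np.full(k, 1.0 / k)
        fit = _em_1d(x, mu0.copy(), sd0, w0, max_iter, tol, sd_floor)
        if best is None or fit[3] > best[3]:
            best = fit
    mu, sd, w, ll = best
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    logp = (np.log(w)[None, :]
            - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
            - np.log(sd)[None, :])
    labels = np.argmax(logp, axis=1)
    return DelayClusters(mu, sd, w, labels, ll)


# ----------------------------------------------------------------------
# Ratio summaries and group comparison
# ----------------------------------------------------------------------

@dataclass
class RatioSummary:
    """Mean/SD of the burst-to-morning-peak ratio over accepted events."""

    mean: float
    sd: float
    n: int
    n_missing: int


def ratio_summary(events: list[BurstEvent]) -> RatioSummary:
    """Summarise ``ratio_to_m`` over events; missing ratios are excluded."""
    ratios = [e.ratio_to_m for e in events if e.ratio_to_m is not None
              and np.isfinite(e.ratio_to_m)]
    n_missing = len(events) - len(ratios)
    if not ratios:
        raise ValueError("no finite burst/morning-peak ratios")
    r = np.asarray(ratios)
    sd = float(r.std(ddof=1)) if r.size > 1 else 0.0
    return RatioSummary(mean=float(r.mean()), sd=sd, n=r.size, n_missing=n_missing)


def compare_incidence(group_a, group_b) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value between per-day incidences.

    The exact null distribution is used for small tie-free samples (both
    groups of 8 or fewer); otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 day-level observations")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


# ----------------------------------------------------------------------
# End-to-end report
# ----------------------------------------------------------------------

def events_to_frame(events: list[BurstEvent]) -> pd.DataFrame:
    cols = ["fly_id", "cycle", "time_s", "count", "zscore", "delta_t_h",
            "ratio_to_m", "merged_from", "in_light"]
    rows = [
        [e.fly_id, e.cycle_index, e.bin_time, e.count, e.zscore, e.delta_t,
         "" if e.ratio_to_m is None else e.ratio_to_m, e.merged_from,
         int(e.in_light)]
        for e in events
    ]
    return pd.DataFrame(rows, columns=cols)


def run_report(
    monitor_path,
    program: LightProgram,
    outdir,
    z_min: float = 10.0,
    seed: int | None = None,
) -> dict:
    """Run detect -> metrics -> rhythm -> cohort stats and write a bundle.

    Emits fixed-name CSVs (bursts, incidence, delays, ratio, peaks,
    periodogram) plus a text summary into ``outdir`` and returns the
    computed objects.  Stages tag their errors; outputs are deterministic
    for a given input and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        series = read_dam(monitor_path)
    except Exception as exc:
        raise RuntimeError(f"[intake] {exc}") from exc
    if not series:
        raise RuntimeError("[intake] empty cohort")

    try:
        s3 = [rebin(s, 180) for s in series]
        events = [e for s in s3 for e in detect_bursts(s, program, z_min=z_min)]
    except Exception as exc:
        raise RuntimeError(f"[detect] {exc}") from exc

    try:
        inc = incidence(events, len(series), program, group_label="cohort")
        delays = np.array([e.delta_t for e in events])
        clusters = delay_clusters(delays, seed=seed or 0) if delays.size >= 10 else None
        ratios = ratio_summary(events) if events else None
        dist = count_distribution(s3, events)
    except Exception as exc:
        raise RuntimeError(f"[cohort-stats] {exc}") from exc

    profile = peaks = None
    if program.period_s > 0:
        try:
            profile = population_average(series, program)
            peaks = find_peaks(profile, program)
            for p in peaks:
                half_width(profile, p)
                peak_area(profile, p)
        except Exception as exc:
            raise RuntimeError(f"[metrics] {exc}") from exc

    pgram = None
    try:
        pooled = np.sum([rebin(s, 1800).counts for s in series], axis=0)
        total_series = ActivitySeries("population", series[0].start_time, 1800,
                                      pooled.astype(int))
        if total_series.duration_s / 3600.0 >= 64:
            pgram = lomb_scargle(total_series)
    except Exception as exc:
        raise RuntimeError(f"[rhythm] {exc}") from exc

    events_to_frame(events).to_csv(outdir / "bursts.csv", index=False)
    pd.DataFrame({"cycle": np.arange(inc.n_cycles),
                  "percent": inc.per_cycle_percent}).to_csv(
        outdir / "incidence.csv", index=False)
    pd.DataFrame({"delta_t_h": delays}).to_csv(outdir / "delays.csv", index=False)
    if peaks is not None:
        pd.DataFrame(
            [[p.peak_kind, p.peak_time, p.height, p.half_width, p.area, p.offset]
             for p in peaks],
            columns=["peak_kind", "zt_h", "height", "fwhm_h", "area", "offset_h"],
        ).to_csv(outdir / "peaks.csv", index=False)
    if pgram is not None:
        pd.DataFrame({"period_h": pgram.periods_h, "power": pgram.power}).to_csv(
            outdir / "periodogram.csv", index=False)

    with open(outdir / "summary.txt", "w") as fh:
        fh.write(f"flyburst report (seed={seed})\n")
        fh.write(f"flies: {len(series)}  cycles: {inc.n_cycles}\n")
        fh.write(f"accepted bursts: {len(events)}\n")
        fh.write(f"incidence: {inc.mean_percent:.1f} +/- {inc.sd_percent:.1f} % per cycle\n")
        if ratios is not None:
            fh.write(f"burst/M ratio: {ratios.mean:.2f} +/- {ratios.sd:.2f} (n={ratios.n})\n")
        if delays.size:
            fh.write(f"mean delay: {delays.mean():.2f} h\n")
        if clusters is not None and not clusters.degenerate:
            fh.write(
                "delay clusters: mu1=%.2f h (sd %.2f), mu2=%.2f h (sd %.2f)\n"
                % (clusters.means[0], clusters.sds[0], clusters.means[1], clusters.sds[1])
            )
        if peaks is not None:
            for p in peaks:
                fh.write(f"{p.peak_kind} peak at ZT {p.peak_time:.2f} h, "
                         f"height {p.height:.2f}, FWHM {p.half_width:.2f} h\n")
        if pgram is not None:
            fh.write(f"LS peak period: {pgram.peak_period():.2f} h "
                     f"(significant: {pgram.significant()})\n")
    return {
        "events": events,
        "incidence": inc,
        "clusters": clusters,
        "ratios": ratios,
        "distribution": dist,
        "profile": profile,
        "peaks": peaks,
        "periodogram": pgram,
        "outdir": outdir,
    }
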