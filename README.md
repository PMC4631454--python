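# flyburst

Analysis of the **stochastic post-dawn activity burst** in single-fly
*Drosophila* locomotor recordings.

Fruit-fly locomotion under light/dark (LD) cycles is dominated by two
clock-driven peaks — a morning (M) peak around lights-on and an evening (E)
peak before lights-off — that are synchronized across flies and therefore
prominent in population averages. Individual recordings additionally contain
a very different feature: a brief (~2–3 min) burst of beam-crossing
activity that appears at most once per light cycle, typically 0.5–5 h after
lights-on (mean delay Δt ≈ 2.3 h), with counts ~10 standard deviations above
the fly's mean 3-minute activity and roughly 5–6× the morning-peak maximum.
Because its timing is stochastic from day to day and fly to fly, averaging
or coarse binning erases it: it is only detectable in single-fly data.
Its incidence rises with daytime light intensity (≈25 % of flies at 50 lux
to ≈85 % at 8000 lux) and with day length (≈40 % after a 1-h pulse,
saturating at ≈85 % for ≥8 h).

`flyburst` is for chronobiologists working with Drosophila Activity Monitor
(DAM, TriKinetics-style) beam-crossing data who want to detect and
characterize this burst alongside the standard population-level analyses.
It provides:

* **`light_model`** — illumination programs (square / trapezoid /
  half-sine / pulse-train zeitgebers) with exact transition lists, plus the
  photosensor calibration math (`I = a·S^b` low range, `I = e^{αS+β}` high
  range, 38-lux switching, 1 lux = 0.243 µW/cm² for white LEDs) and the
  ±2.5 % stability check.
* **`dam_io`** — a fixed tab-delimited DAM monitor dialect, reading/writing,
  and count-conserving rebinning (20 s → 3 min for single-fly analysis,
  30 min for population analysis).
* **`synthetic_cohort`** — a calibrated generator of per-fly 20-s count
  series (basal counts, M/E peaks, startle spikes, stochastic bursts) with
  ground-truth event records; strain presets `yw`, `iso31`, `hdc`, `norpa`.
* **`burst_detector`** — the per-cycle detection algorithm (max 3-min bin,
  ±10-min merge of comparable bins, ±5-min startle exclusion at light
  transitions, acceptance at ≥10 SD above the fly's mean).
* **`activity_metrics`** — folded population profiles, M/E/A peak
  localization, FWHM, ±3-h peak areas, midday (ZT 4–8) activity, and
  activity-count probability distributions.
* **`rhythm_analysis`** — Lomb–Scargle periodogram with analytic false-alarm
  threshold, and normalized autocorrelation.
* **`cohort_pipeline`** — incidence, delay-distribution clustering
  (two-component Gaussian mixture via EM), burst/M ratio summaries,
  Mann–Whitney–Wilcoxon group comparison, and an end-to-end report.

## The detection algorithm

On each fly's 3-minute-binned series, per light cycle (lights-on to next
lights-on):

1. find the bin with the highest count (earliest wins ties);
2. if other bins within ±10 min carry counts ≥ 0.8× the maximum, replace
   them by one averaged event (count-weighted mean time);
3. discard the candidate if it lies within ±5 min of any light transition
   (startle response);
4. accept only if `count ≥ mean + 10·SD` of the fly's whole recording.

Accepted events carry the delay Δt from lights-on, the z-score, and the
ratio to the morning-peak maximum (highest 3-min bin within 1 h of
lights-on, startle bins excluded).

## Worked example

```python
import numpy as np
from flyburst import (make_program, get_preset, simulate_cohort, detect_bursts,
                      rebin, incidence, ratio_summary)
from flyburst.synthetic_cohort import cohort_to_series

program = make_program("square", day_length_h=12, night_length_h=12,
                       max_lux=8000, n_cycles=5)
cohort = simulate_cohort(32, get_preset("yw"), program, seed=7)
events = [e for s in cohort_to_series(cohort)
          for e in detect_bursts(rebin(s, 180), program)]

inc = incidence(events, n_flies=32, program=program)
ratios = ratio_summary(events)
delays = [e.delta_t for e in events if e.delta_t <= 12]
print(f"accepted bursts : {len(events)}")
print(f"incidence       : {inc.mean_percent:.1f} +/- {inc.sd_percent:.1f} % of flies per cycle")
print(f"mean delay      : {np.mean(delays):.2f} h after lights-on")
print(f"burst/M ratio   : {ratios.mean:.2f} +/- {ratios.sd:.2f}")
print(f"min z-score     : {min(e.zscore for e in events):.1f} SD above the fly mean")
```

which prints:

```
accepted bursts : 133
incidence       : 83.1 +/- 5.2 % of flies per cycle
mean delay      : 2.39 h after lights-on
burst/M ratio   : 6.25 +/- 0.17
min z-score     : 12.4 SD above the fly mean
```

Of 32 simulated control flies over 5 days, ~83 % show an accepted burst per
cycle, arriving on average ~2.4 h after lights-on, with activity ~6× the
morning-peak maximum and at least 12 SD above each fly's mean 3-minute
count — the single-fly signature that population averaging hides.

The same pipeline runs from the shell:

```bash
flyburst lightgen --pattern square --day 12 --night 12 --lux 8000 --cycles 5 --out program.yaml
flyburst simulate --preset yw --flies 32 --days 5 --seed 7 --out monitor.txt
flyburst report --monitor monitor.txt --program program.yaml --seed 7 --outdir results/
```

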