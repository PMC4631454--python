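# Methods

This note documents the models, calibrations and numerical choices behind
`flyburst`: what the synthetic cohort generator emulates (and what it does
not), how the burst detector and population metrics are defined where the
underlying conventions are genuinely open, and the limitations a user
should keep in mind.

## 1. Light programs

A `LightProgram` stores its lights-on/off transition times **exactly**;
sampled intensity traces (default step 60 s) are derived, never the other
way around, which avoids off-by-one-bin ambiguity downstream. Program time
zero is the first lights-on, and zeitgeber time (ZT) is hours since the
most recent lights-on. Periodic kinds (square, trapezoid, half-sine)
repeat with period `day + night`; trapezoid dawn/dusk ramps each span
exactly `ramp_h` (default 1 h); for the half-sine, "day" is the positive
half-wave and the transitions are its zero crossings. Pulse trains
concatenate rectangular segments of varying day/night length; a night
shorter than 5 h after a pulse is accepted with a warning, since bursts
can follow lights-on by up to ~5 h and protocols normally leave room for
them.

Sensor calibration follows the two-sensor scheme: low range `I = a·S^b`
(defaults a = 0.29, b = 0.86), high range `I = exp(α·S + β)` (defaults
α = 2.33×10⁻², β = 6.71×10⁻²), fused by reporting the low-range estimate
when it is below the 38-lux switch point and the high-range estimate
otherwise. The arbiter is the low-range estimate alone, because that is
the sensor that is reliable in the low regime. The LED band conversion is
1 lux = 0.243 µW/cm², and intensity stability is checked against a
±2.5 % tolerance band.

## 2. Synthetic cohort generator

The generator emulates single-beam DAM recordings at 20-s resolution as a
sum of independent components:

* **Basal counts** — iid per 20-s bin from a moment-matched count family:
  negative binomial when the requested variance exceeds the mean, binomial
  (thinning) when below, Poisson at equality. Means are matched exactly;
  the binomial branch rounds the trial count to an integer so its variance
  match is approximate.
* **M and E peaks** — Poisson counts around Gaussian rate bumps: M centred
  at each lights-on (σ = 0.4 h, height 6 counts/3 min at centre — the
  anticipation rises into dawn and decays after), E centred at each
  lights-off (σ = 0.6 h, height 4.5). A virtual lights-on anchor at the
  end of the recording supplies the final anticipation ramp so every cycle
  carries one full M bump of rate mass. Heights/widths are per-fly
  parameters; any smooth unimodal bump would serve, as no shape is
  otherwise constrained.
* **Daytime elevation** — a uniform light-driven rate elevation
  (default 1 count/3 min) during the light phase. This is the midday
  activity drive seen in population profiles and the dominant source of
  genuine 24-h spectral power under LD; without it (and with near-equal
  M/E bump masses in antiphase) the 24-h Fourier component of the profile
  nearly cancels, which real recordings do not show.
* **Startle spikes** — a fixed count (default 10) added to the single
  20-s bin at each light transition.
* **Bursts** — per light cycle, with probability given by the incidence
  model, one event: onset delay drawn from the two-component mixture
  below, snapped down to the 3-min grid; injected count
  `round(factor × M_max)` where `M_max` is that cycle's realised
  morning-window 3-min maximum (the same statistic the detector uses as
  the ratio denominator) and `factor` is 6 for the `yw` preset, 5 for
  `iso31`; the count is spread multinomially over the nine 20-s bins of
  one 3-min bin (configurable duration). Ground truth (onset, count,
  mixture component) is returned for every injection.

**Delay mixture.** Delays are drawn from
`0.97 · N(2.0, 1.3²) |[0.5, 5]  +  0.03 · N(10, 2.7²)` hours after
lights-on. The early component is centred at the observed early-cluster
centre (~2 h) and truncated to the observed 0.5–5 h response window, which
places its post-truncation mean at ≈2.27 h; together with the small late
(~10 h) cluster the mean *observable* daytime delay lands at the reported
≈2.3 h. The late-cluster weight is not separately published; 0.03 is the
value consistent with that overall mean and with late events being rare,
chosen once and fixed. The late cluster is generated and labelled so it
can be studied, not filtered out at source.

**Incidence model.** The probability that a fly bursts in a given cycle is
`p(L, d) = p_lux(L) · p_day(d) / 0.85`, where `p_lux` is a logistic in
log₁₀(lux) with ceiling 0.90 anchored exactly at p(50) = 0.25 and
p(8000) = 0.85 (the ceiling sits slightly above the highest observed
incidence because the dose-response is still rising at 8000 lux), and
`p_day` is a saturating exponential anchored at p(1 h) = 0.40 with plateau
0.85 for ≥8 h. The multiplicative combination reduces to each published
curve at the other's reference condition (12-h day, 8000 lux). In
darkness p = 0: no bursts are generated under DD, matching observation.

These anchors are *observed* incidences — what the detection pipeline
reports — not latent event rates. The pipeline cannot see every true
burst: an event whose bin falls within ±5 min of a light transition is
discarded as startle (under a 1-h pulse this swallows the ≈7 % of
early-cluster delays near 1 h), and events outside the attribution window
(`Δt > max(day, 5 h)`, e.g. the late cluster at night) are not counted.
The generator therefore divides its latent per-cycle Bernoulli rate by
the observable-burst fraction of that cycle, computed exactly as the
delay-mixture probability mass on detectable bins
(`observable_burst_fraction`), so the *detected* incidence reproduces the
anchors (0.993 for 12:12 LD, 0.92 for a 1-h pulse). Swallowed bursts are
still injected into the counts; they are real activity the detector
attributes to startle, exactly as in a real recording.

**Calibration of the control presets.** The published population statistic
for control flies — 2.84 ± 2.38 counts per 3 min — describes whole
recordings, not an isolated "basal" process (its consistency with the
≥10 SD criterion and ~30-count bursts requires that reading). The presets
therefore solve for the basal moments analytically such that, under the
reference 12:12 LD cycle at 8000 lux:

* the pooled whole-recording 3-min mean (basal + peaks + startles +
  bursts at 85 % incidence) equals 2.84, and
* the pooled *burst-free* 3-min SD equals 2.38.

The burst's expected mean contribution needs E[morning-window max], which
is computed exactly as `Σₓ (1 − Πⱼ Fⱼ(x))` over the window bins (negative-
binomial basal pmf convolved with each bin's Poisson bump pmf); since the
basal moments depend on that term, the solution is a short fixed-point
iteration. The burst's own variance is excluded from the SD budget
deliberately: one ~60-count bin per day adds ~4–7 to the pooled variance,
so no parameterisation can hold the with-burst SD at 2.38 while keeping
bursts detectable — an internal tension in the published numbers. The
realised with-burst SD is ≈3.5, and the detector's `mean + 10·SD`
threshold is computed from each fly's own realised moments either way.

**Seeding.** One master integer seed; per-fly generators come from
`SeedSequence(seed).spawn(n)`, so output is bit-reproducible and fly *i*'s
stream does not depend on cohort size.

**What the generator does not emulate** (and hence what passing tests do
not show about real data): sleep architecture and within-day
autocorrelation of basal activity; inter-fly parameter heterogeneity
beyond the incidence Bernoulli; startle dynamics beyond a single bin;
burst substructure (the real event is a 2–3-min bout, possibly grooming,
not literally one rectangular bin); temperature effects; and any
dependence of burst magnitude on light (observed to be absent, so none is
modelled).

## 3. Burst detection

Per light cycle (lights-on → next lights-on) on the 3-min series: take the
maximum bin (earliest on ties); merge neighbours within ±10 min whose
counts are ≥ `merge_frac` (default 0.8 — the published criterion says only
"comparably high", so the fraction is an exposed parameter) into one
averaged event with count-weighted mean time; discard candidates whose
maximum bin centre lies within ±5 min of any transition (startle); accept
if `count ≥ mean + z_min·SD` with `z_min = 10` and moments taken over the
fly's whole 3-min recording, bursts included (≤1 bin/day barely moves the
mean; see §2 for the variance caveat). If SD = 0 (flat recording) the
threshold degenerates to "any positive excursion", and this is logged.
At most one event is accepted per cycle. Night-time candidates are kept
but flagged `in_light = False` so the late delay cluster remains
observable. Under DD there are no cycles and the detector returns nothing.

The ratio denominator `m_peak_activity` is the maximum 3-min count within
1 h of lights-on, startle bins excluded — the "maximum of the morning
peak" definition; a window-mean variant is available
(`statistic="mean"`), since the published figure caption uses "average
morning activity" while the abstract uses the maximum. When the accepted
event itself falls inside the morning window, its bins are excluded from
the denominator scan (otherwise the burst would be its own denominator and
the ratio would collapse to 1). A flat-zero window yields ratio `None`,
reported as missing.

**Burst attribution for incidence.** An accepted event is attributed to
its cycle's light pulse if `Δt ≤ max(day length, 5 h)`. Under short
pulses, bursts land in the darkness after lights-off and must still count
(the 0.5–5-h response window is the point of the ≥5-h-darkness protocol
design); under 12:12 LD, daytime late-cluster events count. `in_light`
alone is therefore the wrong filter on both ends.

## 4. Population metrics

Profiles fold 30-min-binned activity on the zeitgeber cycle (half-open
bins `[t, t+w)` everywhere, circular indexing at ZT 24) and average over
flies and days. Peaks are located on this folded profile: M as the
maximum within ±2 h of lights-on, E within the 4 h before lights-off, A as
an optional ZT 4–8 maximum that exceeds the midday trough by ≥20 % of the
M height (the acceptance fraction is a parameter; no published criterion
exists). FWHM is measured above a local baseline — the profile minimum
within ±3 h of the peak, again a convention the source leaves open — with
linear interpolation between grid points; if the half level is never
crossed on one side the width is measured to the scan edge and flagged.
Peak area is the sum of 30-min means within ±3 h; midday activity is the
ZT 4–8 mean (requires a ≥8-h day). No smoothing is applied before width
measurements.

## 5. Rhythm analysis

The Lomb–Scargle periodogram uses the classical Lomb normalisation
(power = raw least-squares periodogram / sample variance), under which
white noise is Exp(1) distributed; it is computed via
`scipy.signal.lombscargle` on demeaned data and verified against a direct
DFT periodogram on even sampling (they agree to 1e-6 at Fourier
frequencies). The period grid is 16–32 h in 0.05-h steps. The analytic
false-alarm threshold at level α is `−ln(1 − (1−α)^{1/M})` with
`M = T·(f_max − f_min)` independent frequencies — the standard
independent-frequencies approximation, which the white-noise calibration
test shows holds to within the expected tolerance. Autocorrelation is the
biased-normalised estimator on mean-subtracted counts (3-min bins for
burst analysis, 30-min for M-peak comparison); a constant series raises.

## 6. Cohort statistics

Incidence is the percent of flies with ≥1 accepted, light-associated
event, computed per cycle and averaged (per-day framing); a
per-experiment aggregation is available. Delay clustering is a
two-component 1-D Gaussian mixture fitted by EM with 10 random restarts
(best likelihood wins, fixed seed, SD floor 0.01 h); the log-likelihood is
asserted non-decreasing at every iteration, and the fit is cross-checked
against an independent mixture implementation in the tests. Group
comparison uses the two-sided Mann–Whitney–Wilcoxon test: exact null
distribution for tie-free samples of ≤8 per group, normal approximation
with tie correction otherwise; no multiple-testing correction is applied
by default (raw p-values are reported; a correction can be layered on by
the caller). Every report header records the master seed.

## 7. Problem sizes and determinism

The acceptance script uses 200-fly cohorts for incidence/delay recovery
and 32-fly cohorts (the published cohort size) for per-strain statistics,
5 days each; these sizes put binomial standard errors near 1 percentage
point, comfortably inside the quoted tolerances, and the whole script runs
in a few seconds. All stochastic tests are seeded; hypothesis profiles are
derandomised.

## 8. Known limitations

* The DAM dialect is fixed; real monitor files from other firmware need a
  shim.
* The generator's basal process is iid per bin, so estimates of variance-
  sensitive quantities on real (autocorrelated) data will differ.
* The burst/M ratio depends on the denominator convention (max vs mean of
  the morning window); results are only comparable under a fixed choice.
* The late (~10 h) delay cluster is modelled phenomenologically with a
  fixed small weight; nothing here explains it.
* Peak morphometrics operate on 30-min folded profiles and inherit that
  resolution (half a bin, 0.25 h, in peak location; one grid step in
  FWHM).
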