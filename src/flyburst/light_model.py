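"""Illumination programs (zeitgebers) and photosensor calibration.

A :class:`LightProgram` is a deterministic, time-resolved description of
incubator illumination in lux, anchored at program time zero = first
lights-on.  Zeitgeber time (ZT) is measured in hours since the most recent
lights-on of the current cycle.  Four periodic pattern families are
supported (square, trapezoid, half-rectified sine, pulse train) plus fully
custom traces.

The calibration functions model the two analog photosensors used to close
the loop on light delivery: a low-range sensor with power-law response
``I = a * S**b`` (reliable below ~65 lux) and a high-range sensor with
logarithmic response ``I = exp(alpha * S + beta)``.  Acquisition switches
between the two at 38 lux, arbitrated on the low-range estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "LightProgram",
    "SensorCalibration",
    "make_program",
    "make_pulse_train",
    "calibrate_low",
    "calibrate_high",
    "fuse_sensors",
    "lux_to_irradiance",
    "entrainment_band_ratio",
    "check_stability",
    "load_program",
    "save_program",
]

logger = logging.getLogger(__name__)

#: Conversion factor for the white-LED band: 1 lux = 0.243 uW/cm^2.
LUX_TO_UW_PER_CM2 = 0.243

_PATTERN_KINDS = ("square", "trapezoid", "halfsine", "pulse_train", "custom")


@dataclass(frozen=True)
class LightProgram:
    """Time-resolved illumination program.

    Attributes
    ----------
    pattern_kind:
        One of ``square``, ``trapezoid``, ``halfsine``, ``pulse_train``,
        ``custom``.
    step:
        Default sampling resolution in seconds for intensity traces.
        Transitions are stored exactly and never inferred from samples.
    transitions:
        Ordered ``(time_s, direction)`` pairs with direction ``"on"`` or
        ``"off"``, alternating, starting with ``"on"``.
    day_length_h / night_length_h:
        Photoperiod components in hours (periodic kinds only; for pulse
        trains these describe the *first* segment).
    max_lux:
        Peak intensity in lux.
    n_cycles:
        Number of zeitgeber cycles (periodic kinds) or segments (pulse
        trains).
    segments:
        For pulse trains, the ``(day_h, night_h)`` list.
    ramp_h:
        Trapezoid ramp duration in hours (dawn and dusk each span exactly
        this long).
    """

    pattern_kind: str
    day_length_h: float
    night_length_h: float
    max_lux: float
    n_cycles: int
    step: float = 60.0
    ramp_h: float = 1.0
    segments: tuple[tuple[float, float], ...] | None = None
    transitions: tuple[tuple[float, str], ...] = field(default_factory=tuple)
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern_kind not in _PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.pattern_kind!r}")
        if self.max_lux < 0:
            raise ValueError("max_lux must be non-negative")
        for i, (t, d) in enumerate(self.transitions):
            expect = "on" if i % 2 == 0 else "off"
            if d != expect:
                raise ValueError("transitions must alternate on/off starting with 'on'")
            if i and t <= self.transitions[i - 1][0]:
                raise ValueError("transition times must be strictly increasing")

    # ------------------------------------------------------------------
    @property
    def period_s(self) -> float:
        """Zeitgeber period in seconds (periodic kinds)."""
        return 3600.0 * (self.day_length_h + self.night_length_h)

    def on_times(self) -> np.ndarray:
        return np.array([t for t, d in self.transitions if d == "on"], dtype=float)

    def off_times(self) -> np.ndarray:
        return np.array([t for t, d in self.transitions if d == "off"], dtype=float)

    def cycles(self) -> list[tuple[float, float]]:
        """Light cycles as ``(lights_on_s, next_lights_on_s)`` intervals.

        The last cycle is closed by the program end.  A program without
        lights-on transitions (e.g. constant darkness) has no cycles.
        """
        ons = self.on_times()
        out = []
        for i, t in enumerate(ons):
            end = ons[i + 1] if i + 1 < len(ons) else self.duration_s
            out.append((float(t), float(end)))
        return out

    def cycle_day_length_h(self, cycle_index: int) -> float:
        """Length of the light phase of a given cycle, in hours."""
        ons = self.on_times()
        offs = self.off_times()
        on = ons[cycle_index]
        later = offs[offs > on]
        if later.size == 0:
            return 0.0
        return float((later[0] - on) / 3600.0)

    # ------------------------------------------------------------------
    def intensity(self, t) -> np.ndarray:
        """Illumination in lux at time(s) ``t`` (seconds from program zero)."""
        t = np.asarray(t, dtype=float)
        if self.pattern_kind == "pulse_train":
            out = np.zeros_like(t)
            for on, d in zip(self.on_times(), [s[0] for s in self.segments]):
                out = np.where((t >= on) & (t < on + d * 3600.0), self.max_lux, out)
            return out
        if self.period_s == 0:
            return np.zeros_like(t)
        tt = np.mod(t, self.period_s)
        day = self.day_length_h * 3600.0
        in_range = (t >= 0) & (t < self.duration_s)
        if self.pattern_kind == "square" or self.pattern_kind == "custom":
            out = np.where(tt < day, self.max_lux, 0.0)
        elif self.pattern_kind == "halfsine":
            out = np.where(tt < day, self.max_lux * np.sin(np.pi * tt / day), 0.0)
        elif self.pattern_kind == "trapezoid":
            ramp = self.ramp_h * 3600.0
            up = np.clip(tt / ramp, 0.0, 1.0)
            down = np.clip((day - tt) / ramp, 0.0, 1.0)
            out = np.where(tt < day, self.max_lux * np.minimum(up, down), 0.0)
        else:  # pragma: no cover
            raise AssertionError(self.pattern_kind)
        if self.max_lux == 0 or day == 0:
            out = np.zeros_like(t)
        return np.where(in_range, out, 0.0)

    def intensity_trace(self, step: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Sampled ``(times_s, lux)`` trace at the given step (default: self.step)."""
        step = step or self.step
        t = np.arange(0.0, self.duration_s, step)
        return t, self.intensity(t)

    # ------------------------------------------------------------------
    def to_config(self) -> dict:
        cfg = {
            "pattern_kind": self.pattern_kind,
            "day_length_h": self.day_length_h,
            "night_length_h": self.night_length_h,
            "max_lux": self.max_lux,
            "n_cycles": self.n_cycles,
            "ramp_h": self.ramp_h,
            "step": self.step,
        }
        if self.segments is not None:
            cfg["segments"] = [list(s) for s in self.segments]
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "LightProgram":
        kind = cfg["pattern_kind"]
        if kind == "pulse_train":
            return make_pulse_train(
                [tuple(s) for s in cfg["segments"]],
                max_lux=cfg["max_lux"],
                step=cfg.get("step", 60.0),
            )
        return make_program(
            kind,
            day_length_h=cfg["day_length_h"],
            night_length_h=cfg["night_length_h"],
            max_lux=cfg["max_lux"],
            n_cycles=cfg["n_cycles"],
            ramp_h=cfg.get("ramp_h", 1.0),
            step=cfg.get("step", 60.0),
        )


def make_program(
    pattern_kind: str,
    day_length_h: float,
    night_length_h: float,
    max_lux: float,
    n_cycles: int,
    ramp_h: float = 1.0,
    step: float = 60.0,
) -> LightProgram:
    """Build a periodic illumination program.

    ``ramp_h`` applies to trapezoid patterns only; dawn and dusk ramps each
    span exactly ``ramp_h`` hours (the standard protocol uses one hour).
    Lights-on transitions mark the start of each intensity rise from zero,
    lights-off each return to zero.  A zero-amplitude program (``max_lux``
    = 0, i.e. constant darkness) has an empty transition list.
    """
    if day_length_h < 0 or night_length_h < 0:
        raise ValueError("day and night lengths must be non-negative")
    if max_lux < 0:
        raise ValueError("max_lux must be non-negative")
    if day_length_h + night_length_h == 0:
        raise ValueError("day_length_h + night_length_h must be positive")
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    if pattern_kind == "trapezoid" and 2 * ramp_h > day_length_h:
        raise ValueError("trapezoid ramps cannot exceed the day length")
    period = 3600.0 * (day_length_h + night_length_h)
    transitions: list[tuple[float, str]] = []
    if max_lux > 0 and day_length_h > 0:
        for k in range(n_cycles):
            transitions.append((k * period, "on"))
            transitions.append((k * period + day_length_h * 3600.0, "off"))
    return LightProgram(
        pattern_kind=pattern_kind,
        day_length_h=day_length_h,
        night_length_h=night_length_h,
        max_lux=max_lux,
        n_cycles=n_cycles,
        ramp_h=ramp_h,
        step=step,
        transitions=tuple(transitions),
        duration_s=n_cycles * period,
    )


def make_pulse_train(
    segments: list[tuple[float, float]],
    max_lux: float,
    step: float = 60.0,
    min_night_h: float = 5.0,
) -> LightProgram:
    """Concatenate rectangular light pulses of varying day/night lengths.

    Each segment is ``(day_h, night_h)`` at ``max_lux``.  Because the burst
    can follow lights-on by up to ~5 h, protocols keep at least
    ``min_night_h`` hours of darkness after each pulse; shorter nights are
    accepted with a logged warning (the constraint is experimental design,
    not a format rule).
    """
    if not segments:
        raise ValueError("at least one segment is required")
    if max_lux < 0:
        raise ValueError("max_lux must be non-negative")
    transitions: list[tuple[float, str]] = []
    t = 0.0
    for i, (day_h, night_h) in enumerate(segments):
        if day_h <= 0 or night_h < 0:
            raise ValueError("segment durations must be positive")
        if night_h < min_night_h:
            logger.warning(
                "segment %d: night of %.1f h is shorter than the recommended "
                "minimum of %.1f h after a light pulse",
                i, night_h, min_night_h,
            )
        if max_lux > 0:
            transitions.append((t, "on"))
            transitions.append((t + day_h * 3600.0, "off"))
        t += (day_h + night_h) * 3600.0
    return LightProgram(
        pattern_kind="pulse_train",
        day_length_h=segments[0][0],
        night_length_h=segments[0][1],
        max_lux=max_lux,
        n_cycles=len(segments),
        step=step,
        segments=tuple(tuple(s) for s in segments),
        transitions=tuple(transitions),
        duration_s=t,
    )


# ----------------------------------------------------------------------
# Sensor calibration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SensorCalibration:
    """Calibration constants for the low/high-range photosensor pair.

    Defaults are the fit parameters of a representative sensor pair:
    ``I = a * S**b`` (low range) and ``I = exp(alpha * S + beta)`` (high
    range), with the acquisition software switching regimes at 38 lux.
    """

    a: float = 0.29
    b: float = 0.86
    alpha: float = 2.33e-2
    beta: float = 6.71e-2
    switch_lux: float = 38.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.alpha <= 0 or self.switch_lux <= 0:
            raise ValueError("a, alpha and switch_lux must be positive")


def calibrate_low(signal, cal: SensorCalibration = SensorCalibration()):
    """Low-range sensor reading -> lux via the power law ``a * S**b``."""
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValueError("analog signal must be non-negative")
    out = cal.a * signal ** cal.b
    return float(out) if out.ndim == 0 else out


def calibrate_high(signal, cal: SensorCalibration = SensorCalibration()):
    """High-range sensor reading -> lux via ``exp(alpha * S + beta)``."""
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValueError("analog signal must be non-negative")
    out = np.exp(cal.alpha * signal + cal.beta)
    return float(out) if out.ndim == 0 else out


def fuse_sensors(signal_low, signal_high, cal: SensorCalibration = SensorCalibration()):
    """Fused lux estimate from both sensors.

    The regime is arbitrated on the low-range estimate alone: below the
    switch point the (more reliable) low-range value is reported, otherwise
    the high-range value.
    """
    low = np.asarray(calibrate_low(signal_low, cal))
    high = np.asarray(calibrate_high(signal_high, cal))
    out = np.where(low < cal.switch_lux, low, high)
    return float(out) if out.ndim == 0 else out


def lux_to_irradiance(lux):
    """Convert lux to uW/cm^2 for the white-LED band (factor 0.243)."""
    lux = np.asarray(lux, dtype=float)
    if np.any(lux < 0):
        raise ValueError("lux must be non-negative")
    out = lux * LUX_TO_UW_PER_CM2
    return float(out) if out.ndim == 0 else out


def entrainment_band_ratio(power_led: float, power_fluor: float) -> int:
    """Ratio of blue-band powers of two light sources, rounded to an integer.

    Used to compare the entraining strength of the LED 450 nm band against
    the fluorescent 440 nm band at matched lux.
    """
    if power_led <= 0 or power_fluor <= 0:
        raise ValueError("band powers must be positive")
    return int(round(power_led / power_fluor))


def check_stability(intensity_trace, target_lux: float, tolerance_frac: float = 0.025):
    """Check an intensity trace against the +/-2.5 % stability requirement.

    Returns ``(ok, max_fractional_deviation)``; ``ok`` is True iff every
    sample lies within ``target_lux * (1 +/- tolerance_frac)``.
    """
    trace = np.asarray(intensity_trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty intensity trace")
    if target_lux <= 0:
        raise ValueError("target_lux must be positive")
    dev = float(np.max(np.abs(trace - target_lux)) / target_lux)
    return dev <= tolerance_frac, dev


# ----------------------------------------------------------------------
# Config file round trip
# ----------------------------------------------------------------------

def save_program(program: LightProgram, path) -> None:
    """Write a program definition as a YAML key-value config."""
    with open(path, "w") as fh:
        yaml.safe_dump(program.to_config(), fh, sort_keys=True)


def load_program(path) -> LightProgram:
    """Read a program definition written by :func:`save_program`."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return LightProgram.from_config(cfg)
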