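"""From raw sensor voltage traces to dual-temperature resistance-ratio observations.

The acquisition chain: the MOX sensor sits in a voltage divider driven at
4.55 V; the sensing-layer resistance follows from the measured output
voltage as

    Rg = RL * (4.55 / Vg - 1)

with RL the load resistance.  The heater alternates between two voltages
(two temperatures, 90 s each); right after each switch the output shows a
transient whose peak height is the measurement point.  A trace is
mean-filtered, the peak voltage of each phase is extracted, and the
observation is the ratio x_i = R0_i / Rg_i of clean-air to gas-exposed
resistance at each temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coefficients import ObservationPair

__all__ = [
    "SUPPLY_VOLTAGE",
    "TemporalTrace",
    "HeaterSchedule",
    "PeakReadout",
    "voltage_to_resistance",
    "resistance_ratio",
    "smooth_trace",
    "extract_peak_readout",
    "observation_from_readouts",
]

#: divider supply voltage fixed by the sensor's front-end electronics
SUPPLY_VOLTAGE = 4.55


@dataclass(frozen=True)
class TemporalTrace:
    """Sampled sensor output with its heater drive.

    t in seconds (strictly increasing), v_out and v_heater in volts,
    fs the sampling frequency in Hz (consistent with the spacing of t).
    """

    t: np.ndarray
    v_out: np.ndarray
    v_heater: np.ndarray
    fs: float

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v_out = np.asarray(self.v_out, dtype=float)
        v_heater = np.asarray(self.v_heater, dtype=float)
        if not (t.shape == v_out.shape == v_heater.shape) or t.ndim != 1:
            raise ValueError("t, v_out, v_heater must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("trace must hold at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("t must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if abs(np.median(dt) * self.fs - 1.0) > 1e-3:
            raise ValueError("fs inconsistent with the spacing of t")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v_out", v_out)
        object.__setattr__(self, "v_heater", v_heater)


@dataclass(frozen=True)
class HeaterSchedule:
    """Square-wave heater drive: two voltage levels, phase_duration seconds each."""

    phase_duration: float = 90.0
    levels: tuple = (0.5, 0.9)
    n_cycles: int = 1

    def __post_init__(self):
        if self.phase_duration <= 0:
            raise ValueError("phase_duration must be positive")
        if len(self.levels) != 2 or self.levels[0] == self.levels[1]:
            raise ValueError("levels must be two distinct heater voltages")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")


@dataclass(frozen=True)
class PeakReadout:
    """Peak output voltages (V) at the two temperatures and their times (s)."""

    v_peak: np.ndarray
    t_peak: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.v_peak, dtype=float)
        t = np.asarray(self.t_peak, dtype=float)
        if v.shape != (2,) or t.shape != (2,):
            raise ValueError("PeakReadout holds one (T1, T2) pair")
        object.__setattr__(self, "v_peak", v)
        object.__setattr__(self, "t_peak", t)


def voltage_to_resistance(v_g: float, r_load: float) -> float:
    """Sensing-layer resistance from the divider output voltage.

    Valid for 0 < v_g < 4.55 V (the supply); r_load in ohms.
    """
    v_g = float(v_g)
    if r_load <= 0:
        raise ValueError("load resistance must be positive")
    if not 0.0 < v_g < SUPPLY_VOLTAGE:
        raise ValueError(
            f"output voltage must lie in (0, {SUPPLY_VOLTAGE}) V, got {v_g}"
        )
    return r_load * (SUPPLY_VOLTAGE / v_g - 1.0)


def resistance_ratio(r0: float, rg: float) -> float:
    """Observable x = R0/Rg (clean air over gas-exposed)."""
    if r0 <= 0 or rg <= 0:
        raise ValueError("resistances must be strictly positive")
    return float(r0) / float(rg)


def smooth_trace(trace: TemporalTrace, window: float = 0.5) -> TemporalTrace:
    """Centered moving-average of v_out; edge windows shrink symmetrically.

    window is in seconds and must be shorter than one heater phase.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    w = max(int(round(window * trace.fs)), 1)
    if w >= trace.t.size:
        raise ValueError("window longer than the trace")
    half = w // 2
    n = trace.v_out.size
    csum = np.concatenate([[0.0], np.cumsum(trace.v_out)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return TemporalTrace(trace.t, smoothed, trace.v_heater, trace.fs)


def _phase_starts(trace: TemporalTrace, schedule: HeaterSchedule) -> list:
    """Indices where a heater phase begins (trace start + level crossings)."""
    threshold = 0.5 * (schedule.levels[0] + schedule.levels[1])
    high = trace.v_heater > threshold
    switches = np.flatnonzero(high[1:] != high[:-1]) + 1
    return [0, *switches.tolist()]


def extract_peak_readout(
    trace: TemporalTrace,
    schedule: HeaterSchedule,
    search_window: float = 20.0,
) -> list[PeakReadout]:
    """Per-cycle peak voltages at the two temperatures.

    For each heater phase the extremum of v_out inside ``search_window``
    seconds after the switch is taken (the post-switch transient peak).
    Phases are attributed to T1/T2 by the heater level; one PeakReadout per
    complete (T1, T2) cycle.  The trace should already be smoothed.
    """
    if search_window <= 0 or search_window > schedule.phase_duration:
        raise ValueError("search_window must lie in (0, phase_duration]")
    starts = _phase_starts(trace, schedule)
    if len(starts) < 2:
        raise ValueError("no heater switch detectable in v_heater")
    threshold = 0.5 * (schedule.levels[0] + schedule.levels[1])
    n = trace.t.size
    bounds = [*starts, n]

    phase_peaks = []  # (level_index, v_peak, t_peak)
    for k in range(len(starts)):
        i0, i1 = bounds[k], bounds[k + 1]
        t0 = trace.t[i0]
        in_win = i0 + np.searchsorted(
            trace.t[i0:i1], t0 + search_window, side="right"
        )
        seg = trace.v_out[i0:in_win]
        j = int(np.argmax(seg))
        is_high = trace.v_heater[i0] > threshold
        level_idx = 1 if (is_high == (schedule.levels[1] > schedule.levels[0])) else 0
        phase_peaks.append((level_idx, seg[j], trace.t[i0 + j]))

    readouts = []
    k = 0
    while k + 1 < len(phase_peaks):
        (l1, v1, t1), (l2, v2, t2) = phase_peaks[k], phase_peaks[k + 1]
        if l1 == 0 and l2 == 1:
            readouts.append(PeakReadout(np.array([v1, v2]), np.array([t1, t2])))
            k += 2
        else:
            k += 1
    if not readouts:
        raise ValueError("no complete (T1, T2) cycle found in trace")
    return readouts


def observation_from_readouts(
    gas: PeakReadout, air: PeakReadout, r_load: float = 10_000.0
) -> ObservationPair:
    """Resistance-ratio observation from gas-phase and clean-air peak readouts.

    Both readouts must come from the same heater schedule; r_load defaults
    to 10 kOhm.  A reducing gas lowers the sensing resistance, so the gas
    peak voltage exceeds the air one and x > 1.
    """
    x = np.empty(2)
    for i in range(2):
        r0 = voltage_to_resistance(air.v_peak[i], r_load)
        rg = voltage_to_resistance(gas.v_peak[i], r_load)
        x[i] = resistance_ratio(r0, rg)
    return ObservationPair(x)
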