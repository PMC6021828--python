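"""Synthetic inputs: calibration grids, simulation series, noisy observations, traces.

Everything the pipeline consumes can be generated here, seeded and
bit-reproducible.  The defaults emulate the reference study conditions:

* a 39-mixture calibration grid over acetone 0-20 ppm x ethanol 0-40 ppm,
  containing the four corner mixtures (clean air included);
* a 200-sample series with sinusoidal acetone (a diurnal-like variation)
  and uniformly drawn ethanol, observed through the linear-quadratic model
  with additive Gaussian noise of variance 0.28 (the model's cross-validated
  misfit) on the resistance ratios;
* dual-phase temporal voltage traces (90 s per heater phase at 500 Hz) with
  a post-switch double-exponential transient whose peak encodes a programmed
  observation pair, for end-to-end testing of the preprocessing chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coefficients import ModelCoefficients, forward_lq, sources_from_concentrations
from .dataset import CalibrationDataset
from .preprocess import SUPPLY_VOLTAGE, HeaterSchedule, TemporalTrace

__all__ = [
    "SimulationConfig",
    "gen_concentration_series",
    "gen_calibration_grid",
    "gen_observations",
    "gen_temporal_trace",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulated concentration series.

    noise_mode "variance" adds iid Gaussian noise of the given variance
    (observation units squared) to every resistance ratio; "target_snr_db"
    scales the realised noise so the pooled observation-domain SNR
    10*log10(sum x^2 / sum noise^2) hits the target exactly.
    """

    n: int = 200
    acetone_range: tuple = (0.0, 20.0)
    ethanol_range: tuple = (0.0, 40.0)
    acetone_law: str = "sinusoid"
    sinusoid_periods: int = 2
    noise_mode: str = "variance"
    noise_value: float = 0.28
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be at least 1")
        for name, rng in (("acetone_range", self.acetone_range),
                          ("ethanol_range", self.ethanol_range)):
            lo, hi = rng
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be ordered and nonnegative")
        if self.acetone_law not in ("sinusoid", "uniform"):
            raise ValueError("acetone_law must be 'sinusoid' or 'uniform'")
        if self.noise_mode not in ("variance", "target_snr_db"):
            raise ValueError("noise_mode must be 'variance' or 'target_snr_db'")
        if self.noise_mode == "variance" and self.noise_value < 0:
            raise ValueError("noise variance must be nonnegative")
        if self.sinusoid_periods < 1:
            raise ValueError("sinusoid_periods must be at least 1")


def gen_concentration_series(cfg: SimulationConfig) -> np.ndarray:
    """(n, 2) concentration series: sinusoidal (or uniform) acetone, uniform ethanol.

    The sinusoid spans exactly the acetone range: c1(i) = mid + half *
    sin(2 pi periods i / n).  Ethanol is iid uniform on its range.  Seeded
    and bit-reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    lo1, hi1 = cfg.acetone_range
    lo2, hi2 = cfg.ethanol_range
    i = np.arange(cfg.n)
    if cfg.acetone_law == "sinusoid":
        mid, half = 0.5 * (lo1 + hi1), 0.5 * (hi1 - lo1)
        c1 = mid + half * np.sin(2.0 * np.pi * cfg.sinusoid_periods * i / cfg.n)
    else:
        c1 = rng.uniform(lo1, hi1, cfg.n)
    c2 = rng.uniform(lo2, hi2, cfg.n)
    return np.column_stack([c1, c2])


def gen_calibration_grid(
    n_samples: int = 39,
    ranges: tuple = ((0.0, 20.0), (0.0, 40.0)),
    seed: int = 0,
) -> np.ndarray:
    """(n, 2) stratified coverage of the concentration rectangle, corners included.

    The four corner mixtures -- clean air (0, 0) among them, anchoring the
    x = (1, 1) baseline in every calibration -- are always present; the
    remaining points form a seeded Latin-hypercube-style stratified sample.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    (lo1, hi1), (lo2, hi2) = ranges
    corners = np.array([[lo1, lo2], [hi1, lo2], [lo1, hi2], [hi1, hi2]])
    corners = corners[: min(4, n_samples)]
    n_fill = n_samples - len(corners)
    if n_fill <= 0:
        return corners.copy()
    rng = np.random.default_rng(seed)
    # Latin hypercube: one point per stratum on each axis, strata paired by
    # a random permutation so the rectangle is covered without clumping.
    u = (np.arange(n_fill) + rng.uniform(size=n_fill)) / n_fill
    v = (rng.permutation(n_fill) + rng.uniform(size=n_fill)) / n_fill
    fill = np.column_stack([lo1 + u * (hi1 - lo1), lo2 + v * (hi2 - lo2)])
    return np.vstack([corners, fill])


def gen_observations(
    samples: np.ndarray,
    m: ModelCoefficients,
    cfg: SimulationConfig,
) -> CalibrationDataset:
    """Forward-map concentrations and add seeded Gaussian observation noise.

    Noisy ratios that would come out nonpositive are redrawn (counted and
    logged); with realistic coefficient scales this never triggers.
    """
    c = np.atleast_2d(np.asarray(samples, dtype=float))
    s = sources_from_concentrations(c, m.r)
    x_clean = forward_lq(s, m)
    rng = np.random.default_rng(cfg.seed)

    if cfg.noise_mode == "variance":
        sd = float(np.sqrt(cfg.noise_value))
        noise = rng.normal(0.0, sd, x_clean.shape) if sd > 0 else np.zeros_like(x_clean)
    else:
        noise = rng.normal(0.0, 1.0, x_clean.shape)
        target_power = float(np.sum(x_clean**2)) / 10.0 ** (cfg.noise_value / 10.0)
        noise *= np.sqrt(target_power / float(np.sum(noise**2)))
        sd = float(np.sqrt(target_power / noise.size))

    x = x_clean + noise
    n_resampled = 0
    bad = x <= 0
    while np.any(bad):
        n_resampled += int(bad.sum())
        x[bad] = x_clean[bad] + rng.normal(0.0, sd, int(bad.sum()))
        bad = x <= 0
    if n_resampled:
        logger.info("gen_observations: resampled %d nonpositive ratios", n_resampled)

    meta = {"noise_mode": cfg.noise_mode, "noise_value": cfg.noise_value,
            "seed": cfg.seed, "n_resampled": n_resampled}
    return CalibrationDataset(c, x, meta=meta)


def gen_temporal_trace(
    sample,
    m: ModelCoefficients,
    schedule: HeaterSchedule | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    fs: float = 500.0,
    r_load: float = 10_000.0,
    r0: tuple = (50_000.0, 20_000.0),
    tau_rise: float = 5.0,
    tau_fall: float = 30.0,
):
    """Raw voltage trace whose post-switch peaks encode the model observation.

    After each heater switch the output follows a double-exponential
    transient exp(-t/tau_fall) - exp(-t/tau_rise), normalised so its peak
    voltage corresponds (through the voltage divider) to the resistance
    ratio forward_lq predicts for ``sample``; it then relaxes towards a
    steady level between the air baseline and the peak.  Returns
    (TemporalTrace, ground_truth) where ground_truth is the exact (x1, x2)
    encoded -- the oracle for testing the preprocessing chain.
    """
    schedule = schedule or HeaterSchedule()
    c = np.asarray(sample, dtype=float)
    s = sources_from_concentrations(c, m.r)
    x_true = forward_lq(s, m)
    if np.any(x_true <= 0):
        raise ValueError("model predicts nonpositive resistance ratio for this sample")

    r0 = np.asarray(r0, dtype=float)
    rg = r0 / x_true
    v_peak = SUPPLY_VOLTAGE * r_load / (r_load + rg)      # divider, gas phase
    v_air = SUPPLY_VOLTAGE * r_load / (r_load + r0)       # divider, clean air
    v_steady = v_air + 0.7 * (v_peak - v_air)

    n_phase = int(round(schedule.phase_duration * fs))
    tau = np.arange(n_phase) / fs
    h = np.exp(-tau / tau_fall) - np.exp(-tau / tau_rise)
    t_star = np.log(tau_fall / tau_rise) / (1.0 / tau_rise - 1.0 / tau_fall)
    h /= np.exp(-t_star / tau_fall) - np.exp(-t_star / tau_rise)

    v_out, v_heater = [], []
    for _ in range(schedule.n_cycles):
        for i, level in enumerate(schedule.levels):
            v_out.append(v_steady[i] + (v_peak[i] - v_steady[i]) * h)
            v_heater.append(np.full(n_phase, level))
    v_out = np.concatenate(v_out)
    v_heater = np.concatenate(v_heater)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v_out = v_out + rng.normal(0.0, noise_sd, v_out.size)
    t = np.arange(v_out.size) / fs
    return TemporalTrace(t, v_out, v_heater, fs), x_true
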