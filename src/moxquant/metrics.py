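"""Performance measures used for calibration, validation and inversion.

All four measures are computed per column (per gas source, or per
temperature channel when applied to observations); a single-number summary
is the arithmetic mean over the columns.

* correlation: sample Pearson coefficient (N-1 normalisation).
* relative_error (%): mean of 2|u - v| / |u + v| * 100 -- a symmetric,
  scale-free discrepancy.
* snr (dB): 10 log10(||true||^2 / ||true - est||^2); +inf flags perfect
  recovery.
* mse: mean squared deviation, ppm**(2 r_j) in source units (or squared
  observation units).

They satisfy snr = 10 log10(mean(true^2) / mse) exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["correlation", "relative_error", "snr", "mse", "PerformanceReport"]


def _pair(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    if a.size == 0:
        raise ValueError("inputs must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    return a, b


def correlation(a, b) -> float:
    """Sample Pearson correlation coefficient in [-1, 1]."""
    a, b = _pair(a, b)
    if a.size < 2:
        raise ValueError("correlation requires at least 2 samples")
    da, db = a - a.mean(), b - b.mean()
    sa, sb = np.sqrt(da @ da), np.sqrt(db @ db)
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.clip((da @ db) / (sa * sb), -1.0, 1.0))


def relative_error(meas, mod) -> float:
    """Symmetric mean relative error in percent."""
    meas, mod = _pair(meas, mod)
    denom = meas + mod
    if np.any(denom == 0):
        raise ValueError("relative error undefined where meas + mod = 0")
    return float(np.mean(2.0 * np.abs(meas - mod) / np.abs(denom)) * 100.0)


def snr(true, est) -> float:
    """Signal-to-noise ratio of an estimate in dB; +inf on exact recovery."""
    true, est = _pair(true, est)
    err = true - est
    err_power = float(err @ err)
    sig_power = float(true @ true)
    if err_power == 0.0:
        return math.inf
    return 10.0 * math.log10(sig_power / err_power)


def mse(true, est) -> float:
    """Mean squared deviation."""
    true, est = _pair(true, est)
    return float(np.mean((true - est) ** 2))


@dataclass(frozen=True)
class PerformanceReport:
    """Per-column metrics with mean-over-columns aggregates.

    ``labels`` names the columns (gas names for source-domain reports,
    temperature channels for observation-domain ones).
    """

    rho: tuple
    sigma_rel: tuple
    snr_db: tuple
    mse: tuple
    labels: tuple = ("col1", "col2")

    @classmethod
    def from_columns(cls, true, est, labels=("col1", "col2")) -> "PerformanceReport":
        """Compute all four measures column-wise for (N, M) arrays.

        The relative error is undefined where a true/estimate pair sums to
        zero (e.g. a perfectly recovered zero concentration); such columns
        report NaN rather than failing the whole report.
        """
        true = np.asarray(true, dtype=float)
        est = np.asarray(est, dtype=float)
        if true.shape != est.shape or true.ndim != 2:
            raise ValueError("expected matching (N, M) arrays")
        cols = range(true.shape[1])

        def _sigma_rel(j):
            try:
                return relative_error(true[:, j], est[:, j])
            except ValueError:
                return math.nan

        return cls(
            rho=tuple(correlation(true[:, j], est[:, j]) for j in cols),
            sigma_rel=tuple(_sigma_rel(j) for j in cols),
            snr_db=tuple(snr(true[:, j], est[:, j]) for j in cols),
            mse=tuple(mse(true[:, j], est[:, j]) for j in cols),
            labels=tuple(labels),
        )

    @property
    def rho_mean(self) -> float:
        return float(np.mean(self.rho))

    @property
    def sigma_rel_mean(self) -> float:
        return float(np.mean(self.sigma_rel))

    @property
    def snr_db_mean(self) -> float:
        return float(np.mean(self.snr_db))

    @property
    def mse_mean(self) -> float:
        return float(np.mean(self.mse))

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "rho": list(self.rho),
            "sigma_rel_percent": list(self.sigma_rel),
            "snr_db": [v if math.isfinite(v) else "inf" for v in self.snr_db],
            "mse": list(self.mse),
            "aggregates": {
                "rho_mean": self.rho_mean,
                "sigma_rel_percent_mean": self.sigma_rel_mean,
                "snr_db_mean": self.snr_db_mean if math.isfinite(self.snr_db_mean) else "inf",
                "mse_mean": self.mse_mean,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def __str__(self) -> str:
        header = f"{'':12s}" + "".join(f"{lab:>14s}" for lab in self.labels) + f"{'mean':>14s}"
        rows = [header]
        for name, vals, agg in (
            ("rho", self.rho, self.rho_mean),
            ("sigma_rel %", self.sigma_rel, self.sigma_rel_mean),
            ("SNR dB", self.snr_db, self.snr_db_mean),
            ("MSE", self.mse, self.mse_mean),
        ):
            rows.append(
                f"{name:12s}"
                + "".join(f"{v:14.4g}" for v in vals)
                + f"{agg:14.4g}"
            )
        return "\n".join(rows)
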