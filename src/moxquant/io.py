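"""CSV and JSON exchange formats.

Calibration CSV: comma-separated, '.' decimal, UTF-8, mandatory header
``acetone_ppm,ethanol_ppm,x_T1,x_T2``.  Trace CSV: ``time_s,v_out_V,
v_heater_V``.  Fit artifacts are JSON documents carrying the coefficient
vector at full floating precision, the variant id, a version tag and fit
metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coefficients import FORMAT_VERSION, ModelCoefficients, VariantCoefficients
from .dataset import CSV_COLUMNS, CalibrationDataset
from .preprocess import TemporalTrace

__all__ = [
    "read_calibration_csv",
    "write_calibration_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_observations_csv",
    "FitArtifact",
    "write_fit_json",
    "read_fit_json",
]

TRACE_COLUMNS = ("time_s", "v_out_V", "v_heater_V")


def read_calibration_csv(path) -> CalibrationDataset:
    """Parse a calibration table, validating schema and value domains."""
    df = pd.read_csv(path, float_precision="round_trip")
    try:
        return CalibrationDataset.from_dataframe(df, meta={"path": str(path)})
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_calibration_csv(data: CalibrationDataset, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    data.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_observations_csv(path) -> np.ndarray:
    """(N, 2) observation pairs from a CSV with x_T1, x_T2 columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("x_T1", "x_T2") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    arr = df.loc[:, ["x_T1", "x_T2"]].to_numpy(dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        row = int(np.flatnonzero(~(np.isfinite(arr) & (arr > 0)).all(axis=1))[0])
        raise ValueError(f"{path}: invalid resistance ratio at row {row}")
    return arr


def read_trace_csv(path, fs: float | None = None) -> TemporalTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return TemporalTrace(t, df["v_out_V"].to_numpy(float), df["v_heater_V"].to_numpy(float), fs)


def write_trace_csv(trace: TemporalTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.t, "v_out_V": trace.v_out, "v_heater_V": trace.v_heater}
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class FitArtifact:
    """A fit result as re-read from disk."""

    coefficients: VariantCoefficients
    report: dict
    converged: bool
    n_iter: int
    final_cost: float

    @property
    def variant_id(self) -> str:
        return self.coefficients.variant_id

    def as_model_coefficients(self) -> ModelCoefficients:
        return self.coefficients.as_model_coefficients()


def write_fit_json(fit, path) -> None:
    """Serialise a MixtureFitResults (or FitArtifact) losslessly."""
    doc = {
        "format_version": FORMAT_VERSION,
        "coefficients": fit.coefficients.to_dict(),
        "report": fit.report.to_dict() if hasattr(fit.report, "to_dict") else fit.report,
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "final_cost": float(fit.final_cost),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)


def read_fit_json(path) -> FitArtifact:
    """Re-read a fit artifact; version mismatches and truncation are errors."""
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid fit artifact ({exc})") from None
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported format version {doc.get('format_version')!r}"
        )
    coeffs = VariantCoefficients.from_dict(doc["coefficients"])
    return FitArtifact(
        coefficients=coeffs,
        report=doc.get("report", {}),
        converged=bool(doc["converged"]),
        n_iter=int(doc["n_iter"]),
        final_cost=float(doc["final_cost"]),
    )
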