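"""Paired (concentration, observation) records used for fitting and validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Tuple

import numpy as np
import pandas as pd

from .coefficients import GAS_NAMES, GasSample, ObservationPair

__all__ = ["CalibrationDataset", "CSV_COLUMNS"]

CSV_COLUMNS = ("acetone_ppm", "ethanol_ppm", "x_T1", "x_T2")


@dataclass(frozen=True)
class CalibrationDataset:
    """N known gas mixtures paired with their dual-temperature observations.

    concentrations: (N, 2) ppm, nonnegative; observations: (N, 2) strictly
    positive resistance ratios.
    """

    concentrations: np.ndarray
    observations: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        x = np.atleast_2d(np.asarray(self.observations, dtype=float))
        if c.shape != x.shape or c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("concentrations and observations must both be (N, 2)")
        if c.shape[0] < 1:
            raise ValueError("dataset must hold at least one record")
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(x))):
            raise ValueError("dataset contains non-finite values")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any(x <= 0):
            raise ValueError("resistance ratios must be strictly positive")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "observations", x)

    @property
    def n(self) -> int:
        return self.concentrations.shape[0]

    def __len__(self) -> int:
        return self.n

    def records(self) -> Iterator[Tuple[GasSample, ObservationPair]]:
        for c, x in zip(self.concentrations, self.observations):
            yield GasSample(c), ObservationPair(x)

    def subset(self, index) -> "CalibrationDataset":
        idx = np.asarray(index)
        return CalibrationDataset(
            self.concentrations[idx], self.observations[idx], meta=dict(self.meta)
        )

    def distinct_levels(self, gas: int) -> int:
        """Number of distinct concentration values for one gas (design rank check)."""
        return int(np.unique(self.concentrations[:, gas]).size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.hstack([self.concentrations, self.observations]),
            columns=list(CSV_COLUMNS),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta: dict | None = None) -> "CalibrationDataset":
        missing = [col for col in CSV_COLUMNS if col not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        sub = df.loc[:, list(CSV_COLUMNS)]
        for col in CSV_COLUMNS:
            bad = pd.to_numeric(sub[col], errors="coerce").isna() & sub[col].notna()
            if sub[col].isna().any() or bad.any():
                row = int(np.flatnonzero(sub[col].isna() | bad)[0])
                raise ValueError(f"non-numeric or missing value at row {row}, column {col!r}")
        arr = sub.to_numpy(dtype=float)
        for j, gas in enumerate(GAS_NAMES):
            if np.any(arr[:, j] < 0):
                row = int(np.flatnonzero(arr[:, j] < 0)[0])
                raise ValueError(f"negative concentration at row {row}, column {CSV_COLUMNS[j]!r}")
        return cls(arr[:, :2], arr[:, 2:], meta=dict(meta or {}))
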