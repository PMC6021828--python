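"""Calibration of the mixture sensing model by nonlinear least squares.

`MixtureResponseModel` is built from a `CalibrationDataset` (or a DataFrame
/ CSV in the standard dialect) and one of the four model variants; `fit()`
estimates the variant's parameters by Levenberg-Marquardt with a two-stage
initialisation (exponents at 0.5, gains from an ordinary linear
least-squares fit of x - 1 on the powered-concentration design) plus
seeded multi-start, and returns a `MixtureFitResults` carrying the
coefficients, residuals, per-temperature performance report and a
`summary()` table.

The power-law exponents are shared across the two temperatures and bounded
to (0.05, 1.5): SnO2 response exponents are sub-linear in practice, and the
bounds prevent exponent/gain aliasing during the nonconvex fit.
"""

from __future__ import annotations

import datetime
import hashlib
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coefficients import (
    GAS_NAMES,
    VARIANT_IDS,
    VARIANT_NPARAMS,
    ModelCoefficients,
    VariantCoefficients,
    forward_variant,
)
from .dataset import CalibrationDataset
from .lm import FitOptions, levenberg_marquardt
from .metrics import PerformanceReport

__all__ = [
    "MixtureResponseModel",
    "MixtureFitResults",
    "fit_lq",
    "fit_variant",
    "compare_models",
    "R_BOUNDS",
]

logger = logging.getLogger(__name__)

#: box constraints on the power-law exponents
R_BOUNDS = (0.05, 1.5)

_VARIANT_ALIASES = {
    "lq": "linear_quadratic",
    "log": "logarithmic",
    **{v: v for v in VARIANT_IDS},
}

#: index of the first exponent inside each variant's flat parameter vector
_R_SLICE = {
    "linear": slice(4, 6),
    "bilinear": slice(6, 8),
    "linear_quadratic": slice(10, 12),
    "logarithmic": slice(0, 0),
}


def _dataset_hash(data: CalibrationDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(data.concentrations).tobytes())
    h.update(np.ascontiguousarray(data.observations).tobytes())
    return h.hexdigest()[:16]


class MixtureResponseModel:
    """Dual-temperature sensing model to be calibrated on known mixtures.

    Parameters
    ----------
    data : CalibrationDataset
        Known concentrations paired with observed resistance ratios.
    variant : str
        One of 'linear_quadratic' (default), 'linear', 'bilinear',
        'logarithmic' (aliases 'lq', 'log' accepted).

    Zero-concentration records are excluded (with a logged count) for the
    logarithmic variant, which is undefined there.
    """

    def __init__(self, data: CalibrationDataset, variant: str = "linear_quadratic"):
        try:
            self.variant = _VARIANT_ALIASES[variant]
        except KeyError:
            raise ValueError(f"unknown model variant {variant!r}") from None
        self.n_excluded = 0
        if self.variant == "logarithmic":
            keep = np.all(data.concentrations > 0, axis=1)
            self.n_excluded = int((~keep).sum())
            if self.n_excluded:
                logger.info(
                    "logarithmic variant: excluded %d record(s) with a zero concentration",
                    self.n_excluded,
                )
            if not np.any(keep):
                raise ValueError("no strictly positive records for the logarithmic variant")
            data = data.subset(np.flatnonzero(keep))
        self.data = data
        self._check_design()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variant: str = "linear_quadratic"):
        return cls(CalibrationDataset.from_dataframe(df), variant)

    @classmethod
    def from_csv(cls, path, variant: str = "linear_quadratic"):
        from .io import read_calibration_csv

        return cls(read_calibration_csv(path), variant)

    # ------------------------------------------------------------------
    def _check_design(self):
        n_params = VARIANT_NPARAMS[self.variant]
        n_min = 10 if self.variant == "linear_quadratic" else (n_params + 2 + 1) // 2
        if self.data.n < n_min:
            raise ValueError(
                f"{self.variant} fit needs at least {n_min} records, got {self.data.n}"
            )
        for j, gas in enumerate(GAS_NAMES):
            if self.data.distinct_levels(j) < 2:
                raise ValueError(
                    f"unidentifiable design: {gas} concentration never varies "
                    "(rank-deficient Jacobian)"
                )

    # ------------------------------------------------------------------
    def _residuals(self, params: np.ndarray) -> np.ndarray:
        # domain failures (e.g. a logarithmic trial predicting nonpositive
        # resistance) surface as FloatingPointError so the solver treats the
        # step as rejected instead of aborting the fit
        try:
            v = VariantCoefficients(self.variant, params)
            pred = forward_variant(self.data.concentrations, v)
        except ValueError as exc:
            raise FloatingPointError(str(exc)) from None
        return (pred - self.data.observations).ravel()

    def _project(self, params: np.ndarray) -> np.ndarray:
        r_slice = _R_SLICE[self.variant]
        out = params.copy()
        out[r_slice] = np.clip(out[r_slice], *R_BOUNDS)
        return out

    def _initial_params(self) -> np.ndarray:
        """Two-stage start: r = 0.5, gains by ordinary least squares at that r."""
        c = self.data.concentrations
        x = self.data.observations
        if self.variant == "logarithmic":
            lc = np.log(c)
            design = np.column_stack(
                [np.ones(len(c)), lc[:, 0], lc[:, 1], lc[:, 0] * lc[:, 1]]
            )
            # the variant predicts Rg = 1/x
            target = 1.0 / x
            gains = [np.linalg.lstsq(design, target[:, i], rcond=None)[0] for i in (0, 1)]
            theta = np.concatenate(gains)
            if np.any(design @ np.reshape(theta, (2, 4)).T <= 0):
                # noisy targets can make the LS plane cross zero resistance;
                # start from a constant positive resistance per channel instead
                theta = np.concatenate(
                    [[float(np.mean(target[:, i])), 0.0, 0.0, 0.0] for i in (0, 1)]
                )
            return theta

        r0 = np.array([0.5, 0.5])
        s = np.power(c, r0[None, :])
        if self.variant == "linear":
            design = s
        elif self.variant == "bilinear":
            design = np.column_stack([s, s[:, 0] * s[:, 1]])
        else:  # linear_quadratic: per-temperature gains (a_i1, a_i2, b_i1, b_i2, d_i)
            design = np.column_stack([s, s**2, s[:, 0] * s[:, 1]])
        gains = [np.linalg.lstsq(design, x[:, i] - 1.0, rcond=None)[0] for i in (0, 1)]
        if self.variant == "linear_quadratic":
            g1, g2 = gains
            theta = np.concatenate(
                [[g1[0], g1[1], g2[0], g2[1]],   # a
                 [g1[2], g1[3], g2[2], g2[3]],   # b
                 [g1[4], g2[4]],                 # d
                 r0]
            )
        else:
            theta = np.concatenate([*gains, r0])
        return theta

    # ------------------------------------------------------------------
    def fit(self, options: FitOptions | None = None) -> "MixtureFitResults":
        """Levenberg-Marquardt fit with multi-start; the best cost is kept."""
        opts = options or FitOptions()
        theta0 = self._project(self._initial_params())
        rng = np.random.default_rng(opts.seed)

        starts = [theta0]
        for _ in range(opts.n_restarts):
            factors = np.exp(rng.uniform(np.log(0.5), np.log(1.5), theta0.size))
            starts.append(self._project(theta0 * factors))

        best = None
        n_failed = 0
        for start in starts:
            try:
                res = levenberg_marquardt(
                    self._residuals, start, options=opts, project=self._project
                )
            except FloatingPointError:
                n_failed += 1
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError(
                f"all {len(starts)} starts diverged ({n_failed} with non-finite residuals)"
            )

        params = best.params
        v = VariantCoefficients(
            self.variant,
            params,
            meta={
                "fit_date": datetime.date.today().isoformat(),
                "dataset_hash": _dataset_hash(self.data),
                "n_records": self.data.n,
                "n_excluded": self.n_excluded,
                "seed": opts.seed,
            },
        )
        pred = forward_variant(self.data.concentrations, v)
        residuals = pred - self.data.observations
        report = PerformanceReport.from_columns(
            self.data.observations, pred, labels=("T1", "T2")
        )
        return MixtureFitResults(
            model=self,
            coefficients=v,
            report=report,
            residuals=residuals,
            converged=best.converged,
            n_iter=best.n_iter,
            final_cost=best.cost,
            cost_history=best.cost_history,
        )


@dataclass
class MixtureFitResults:
    """Fitted coefficients with diagnostics.

    ``report`` holds per-temperature correlation / relative error / SNR /
    MSE between model output and measures; ``final_cost`` is the summed
    squared residual over all records and both temperatures.
    """

    model: MixtureResponseModel
    coefficients: VariantCoefficients
    report: PerformanceReport
    residuals: np.ndarray
    converged: bool
    n_iter: int
    final_cost: float
    cost_history: list

    @property
    def variant(self) -> str:
        return self.coefficients.variant_id

    @property
    def params(self) -> np.ndarray:
        return self.coefficients.params

    def as_model_coefficients(self) -> ModelCoefficients:
        return self.coefficients.as_model_coefficients()

    def predict(self, concentrations) -> np.ndarray:
        """Model observations for new concentration pairs (ppm)."""
        return forward_variant(concentrations, self.coefficients)

    def invert(self, observations, options=None, truths=None):
        """Estimate concentrations for observed ratio pairs (linear-quadratic only)."""
        from .invert import invert_dataset

        return invert_dataset(observations, self.as_model_coefficients(), options, truths)

    def summary(self) -> str:
        lines = [
            f"Mixture sensing model: {self.variant}",
            f"records: {self.model.data.n}   converged: {self.converged}   "
            f"iterations: {self.n_iter}   cost: {self.final_cost:.6g}",
            "",
            "parameters:",
        ]
        if self.variant == "linear_quadratic":
            m = self.as_model_coefficients()
            for i, temp in enumerate(("T1", "T2")):
                lines.append(
                    f"  {temp}: a = ({m.a[i, 0]:.4g}, {m.a[i, 1]:.4g})  "
                    f"b = ({m.b[i, 0]:.4g}, {m.b[i, 1]:.4g})  d = {m.d[i]:.4g}"
                )
            lines.append(f"  r (acetone, ethanol) = ({m.r[0]:.4g}, {m.r[1]:.4g})")
        else:
            lines.append("  " + np.array2string(self.params, precision=4))
        lines += ["", str(self.report)]
        return "\n".join(lines)

    def save(self, path) -> None:
        from .io import write_fit_json

        write_fit_json(self, path)

    def plot_fit(self, ax=None):
        """Measured vs modelled ratios per temperature (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pred = self.predict(self.model.data.concentrations)
        meas = self.model.data.observations
        for i, temp in enumerate(("T1", "T2")):
            ax.scatter(meas[:, i], pred[:, i], s=12, label=temp)
        lims = [meas.min(), meas.max()]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("measured x = R0/Rg")
        ax.set_ylabel("model x")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def fit_lq(data: CalibrationDataset, opts: FitOptions | None = None) -> MixtureFitResults:
    """Fit the full linear-quadratic model (12 coefficients, shared exponents)."""
    return MixtureResponseModel(data, "linear_quadratic").fit(opts)


def fit_variant(
    data: CalibrationDataset, variant_id: str, opts: FitOptions | None = None
) -> MixtureFitResults:
    """Fit one of the four variants on the common x = R0/Rg observable."""
    return MixtureResponseModel(data, variant_id).fit(opts)


def compare_models(
    data: CalibrationDataset,
    opts: FitOptions | None = None,
    variants: Sequence[str] = VARIANT_IDS,
) -> pd.DataFrame:
    """Fit every variant and rank by mean-over-temperatures correlation.

    Returns a DataFrame indexed by variant with columns ``rho`` (mean
    Pearson correlation of model vs measures over the two temperatures),
    ``sigma_rel_percent`` and ``cost``.
    """
    rows = {}
    for variant in variants:
        fit = MixtureResponseModel(data, variant).fit(opts)
        rows[variant] = {
            "rho": fit.report.rho_mean,
            "sigma_rel_percent": fit.report.sigma_rel_mean,
            "cost": fit.final_cost,
            "converged": fit.converged,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table.sort_values("rho", ascending=False)
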