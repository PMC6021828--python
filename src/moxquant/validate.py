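"""Repeated K-fold cross-validation of a fitted sensing model.

The record set is shuffled (seeded) and split into K folds of equal size
(differing by at most one when K does not divide N); each fold in turn is
held out, the model is refit on the rest, and the mean squared error
between held-out measures and model predictions -- in observation units --
is recorded.  The whole segmentation is repeated ``repeats`` times and the
reported value is the mean of the per-segmentation means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import MixtureResponseModel
from .dataset import CalibrationDataset
from .lm import FitOptions

__all__ = ["CVConfig", "CVResult", "kfold_cv"]


@dataclass(frozen=True)
class CVConfig:
    """k folds, ``repeats`` independent segmentations, one master seed."""

    k: int = 13
    repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")


@dataclass(frozen=True)
class CVResult:
    """Per-fold MSE matrix (repeats x k), its grand mean, and fold assignments."""

    mse_per_fold: np.ndarray
    mse_mean: float
    segmentations: np.ndarray  # (repeats, N) fold label of each sample

    @property
    def mse_per_segmentation(self) -> np.ndarray:
        return self.mse_per_fold.mean(axis=1)

    def to_dict(self) -> dict:
        return {
            "k": int(self.mse_per_fold.shape[1]),
            "repeats": int(self.mse_per_fold.shape[0]),
            "mse_mean": self.mse_mean,
            "mse_per_segmentation": self.mse_per_segmentation.tolist(),
        }


def kfold_cv(
    data: CalibrationDataset,
    cfg: CVConfig | None = None,
    opts: FitOptions | None = None,
    variant: str = "linear_quadratic",
) -> CVResult:
    """Repeated K-fold cross-validation; bit-reproducible under a fixed seed.

    ``opts`` defaults to a single-start fit (no random restarts), which is
    accurate here because every training fold is a large fraction of the
    data; pass explicit FitOptions to enable multi-start inside folds.
    """
    cfg = cfg or CVConfig()
    if cfg.k > data.n:
        raise ValueError("k cannot exceed the number of records")
    opts = opts or FitOptions(n_restarts=0)
    rng = np.random.default_rng(cfg.seed)

    n = data.n
    mse_per_fold = np.empty((cfg.repeats, cfg.k))
    segmentations = np.empty((cfg.repeats, n), dtype=int)
    for rep in range(cfg.repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, cfg.k)
        labels = np.empty(n, dtype=int)
        for fold_id, fold in enumerate(folds):
            labels[fold] = fold_id
        segmentations[rep] = labels
        for fold_id, fold in enumerate(folds):
            train = np.setdiff1d(perm, fold)
            try:
                fit = MixtureResponseModel(data.subset(train), variant).fit(opts)
            except ValueError as exc:
                raise ValueError(
                    f"training set of fold {fold_id} (segmentation {rep}) is invalid: {exc}"
                ) from exc
            pred = fit.predict(data.concentrations[fold])
            mse_per_fold[rep, fold_id] = float(
                np.mean((pred - data.observations[fold]) ** 2)
            )
    return CVResult(
        mse_per_fold=mse_per_fold,
        mse_mean=float(mse_per_fold.mean(axis=1).mean()),
        segmentations=segmentations,
    )
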