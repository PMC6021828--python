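"""Forward sensing models for a dual-temperature MOX virtual-sensor pair.

A single tin-oxide (SnO2) sensor operated alternately at two heater
temperatures yields two "virtual sensors".  The observable of each is the
resistance ratio ``x_i = R0/Rg`` (clean-air over gas-exposed resistance) at
temperature ``T_i``.  For a two-gas mixture (gas 1 = acetone, gas 2 =
ethanol, concentrations in ppm) the response is modelled on the *sources*

    s_j = c_j ** r_j        (units: ppm**r_j)

where the power-law exponents ``r_j`` are per-gas but shared across the two
temperatures.  The linear-quadratic model is

    x_i - 1 = sum_j a_ij s_j + sum_j b_ij s_j**2 + d_i s_1 s_2

so a clean-air sample (c = 0) gives x = (1, 1) for every coefficient set.

Three simpler literature models (linear, bilinear, logarithmic) are exposed
through the same interface for comparison; all four are expressed on the
common observable x = R0/Rg with the normalisation R0 = 1 where a variant is
natively stated on another quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "ModelCoefficients",
    "VariantCoefficients",
    "GasSample",
    "SourceVector",
    "ObservationPair",
    "GAS_NAMES",
    "VARIANT_IDS",
    "VARIANT_NPARAMS",
    "sources_from_concentrations",
    "concentrations_from_sources",
    "forward_lq",
    "forward_variant",
    "jacobian_lq",
    "reference_coefficients",
]

GAS_NAMES = ("acetone", "ethanol")

FORMAT_VERSION = 1


def _as_2d(arr, name: str) -> np.ndarray:
    """Coerce to float ndarray of shape (N, 2); accepts a single length-2 vector."""
    a = np.asarray(arr, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError(f"{name} must have shape (2,) or (N, 2), got {np.shape(arr)}")
    return a


@dataclass(frozen=True)
class GasSample:
    """Concentrations of the two gases in ppm (acetone, ethanol)."""

    c: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        if c.shape != (2,):
            raise ValueError("GasSample requires a length-2 vector")
        if not np.all(np.isfinite(c)):
            raise ValueError("concentrations must be finite")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "c", c)


@dataclass(frozen=True)
class SourceVector:
    """Powered concentrations s_j = c_j**r_j, units ppm**r_j."""

    s: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        if s.shape != (2,):
            raise ValueError("SourceVector requires a length-2 vector")
        if not np.all(np.isfinite(s)):
            raise ValueError("sources must be finite")
        if np.any(s < 0):
            raise ValueError("sources must be nonnegative")
        object.__setattr__(self, "s", s)


@dataclass(frozen=True)
class ObservationPair:
    """Dimensionless resistance ratios x = R0/Rg at the two heater temperatures."""

    x: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if x.shape != (2,):
            raise ValueError("ObservationPair requires a length-2 vector")
        if not np.all(np.isfinite(x)):
            raise ValueError("observations must be finite")
        if np.any(x <= 0):
            raise ValueError("resistance ratios must be strictly positive")
        object.__setattr__(self, "x", x)


@dataclass(frozen=True)
class ModelCoefficients:
    """The 12 parameters of the linear-quadratic dual-temperature model.

    Attributes
    ----------
    a : (2, 2) array
        Linear gains, indexed [temperature i][gas j], ratio units per ppm**r_j.
    b : (2, 2) array
        Quadratic gains, same indexing.
    d : (2,) array
        Interaction (cross-product) gains per temperature.
    r : (2,) array
        Power-law exponents per gas, shared across temperatures; strictly
        positive (sub-linear for SnO2 sensors in practice).
    meta : dict
        Free-form provenance metadata carried through serialisation.
    """

    a: np.ndarray
    b: np.ndarray
    d: np.ndarray
    r: np.ndarray
    meta: Mapping = field(default_factory=dict, compare=False)

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        d = np.asarray(self.d, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if a.shape != (2, 2) or b.shape != (2, 2):
            raise ValueError("a and b must be 2x2 matrices")
        if d.shape != (2,) or r.shape != (2,):
            raise ValueError("d and r must be length-2 vectors")
        for name, arr in (("a", a), ("b", b), ("d", d), ("r", r)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"coefficient block {name!r} contains non-finite entries")
        if np.any(r <= 0):
            raise ValueError("exponents r must be strictly positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "r", r)

    # -- flat-vector view used by the fitting machinery -------------------
    def to_params(self) -> np.ndarray:
        """Flatten to (a row-major, b row-major, d, r), length 12."""
        return np.concatenate([self.a.ravel(), self.b.ravel(), self.d, self.r])

    @classmethod
    def from_params(cls, params, meta: Mapping | None = None) -> "ModelCoefficients":
        p = np.asarray(params, dtype=float)
        if p.shape != (12,):
            raise ValueError("expected 12 parameters")
        return cls(
            a=p[0:4].reshape(2, 2),
            b=p[4:8].reshape(2, 2),
            d=p[8:10],
            r=p[10:12],
            meta=dict(meta or {}),
        )

    # -- JSON serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "variant_id": "linear_quadratic",
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "d": self.d.tolist(),
            "r": self.r.tolist(),
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ModelCoefficients":
        version = doc.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported coefficient format version: {version!r}")
        if doc.get("variant_id", "linear_quadratic") != "linear_quadratic":
            raise ValueError("document does not hold linear-quadratic coefficients")
        return cls(
            a=np.array(doc["a"], dtype=float),
            b=np.array(doc["b"], dtype=float),
            d=np.array(doc["d"], dtype=float),
            r=np.array(doc["r"], dtype=float),
            meta=dict(doc.get("meta", {})),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ModelCoefficients":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Model variants
# ---------------------------------------------------------------------------

VARIANT_IDS = ("linear", "bilinear", "logarithmic", "linear_quadratic")

#: flat parameter-vector length per variant (two temperatures)
VARIANT_NPARAMS = {
    # x_i - 1 = A_i1 s1 + A_i2 s2 ; exponents r1, r2 shared across temperatures
    "linear": 4 + 2,
    # x_i - 1 = A_i1 s1 + A_i2 s2 + A_i3 s1 s2   (R0 = 1 normalisation)
    "bilinear": 6 + 2,
    # Rg_i = A_i1 + A_i2 log c1 + A_i3 log c2 + A_i4 log c1 log c2 ; x_i = 1/Rg_i
    "logarithmic": 8,
    # full model: a (4) + b (4) + d (2) + r (2)
    "linear_quadratic": 12,
}


@dataclass(frozen=True)
class VariantCoefficients:
    """Flat parameter vector for one of the four model variants.

    Layouts (temperature-major):
      linear:            (A11, A12, A21, A22, r1, r2)
      bilinear:          (A11, A12, A13, A21, A22, A23, r1, r2)
      logarithmic:       (A11, A12, A13, A14, A21, A22, A23, A24)
      linear_quadratic:  (a11, a12, a21, a22, b11, b12, b21, b22, d1, d2, r1, r2)
    """

    variant_id: str
    params: np.ndarray
    meta: Mapping = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.variant_id not in VARIANT_IDS:
            raise ValueError(f"unknown variant {self.variant_id!r}")
        p = np.asarray(self.params, dtype=float)
        expected = VARIANT_NPARAMS[self.variant_id]
        if p.shape != (expected,):
            raise ValueError(
                f"variant {self.variant_id!r} takes {expected} parameters, got {p.shape}"
            )
        if not np.all(np.isfinite(p)):
            raise ValueError("variant parameters must be finite")
        object.__setattr__(self, "params", p)

    def to_dict(self) -> dict:
        doc = {
            "format_version": FORMAT_VERSION,
            "variant_id": self.variant_id,
            "params": self.params.tolist(),
            "meta": dict(self.meta),
        }
        if self.variant_id == "linear_quadratic":
            doc.update(self.as_model_coefficients().to_dict())
            doc["meta"] = dict(self.meta)
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "VariantCoefficients":
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported coefficient format version: {doc.get('format_version')!r}"
            )
        return cls(
            variant_id=doc["variant_id"],
            params=np.array(doc["params"], dtype=float),
            meta=dict(doc.get("meta", {})),
        )

    def as_model_coefficients(self) -> ModelCoefficients:
        if self.variant_id != "linear_quadratic":
            raise ValueError("only the linear_quadratic variant maps to ModelCoefficients")
        return ModelCoefficients.from_params(self.params, meta=self.meta)

    @classmethod
    def from_model_coefficients(cls, m: ModelCoefficients) -> "VariantCoefficients":
        return cls("linear_quadratic", m.to_params(), meta=m.meta)


# ---------------------------------------------------------------------------
# Concentration <-> source transforms
# ---------------------------------------------------------------------------

def sources_from_concentrations(c, r) -> np.ndarray:
    """Power-law transform s_j = c_j**r_j (with 0**r = 0).

    Parameters
    ----------
    c : array_like, shape (2,) or (N, 2)
        Concentrations in ppm, nonnegative.
    r : array_like, shape (2,)
        Strictly positive exponents.
    """
    c_arr = _as_2d(c, "c")
    r_arr = np.asarray(r, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentrations must be nonnegative")
    if np.any(r_arr <= 0):
        raise ValueError("exponents must be strictly positive")
    s = np.power(c_arr, r_arr[None, :])
    return s if np.ndim(c) == 2 else s[0]


def concentrations_from_sources(s, r) -> np.ndarray:
    """Inverse transform c_j = s_j**(1/r_j), exact on the nonnegative orthant."""
    s_arr = _as_2d(s, "s")
    r_arr = np.asarray(r, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("sources must be nonnegative")
    if np.any(r_arr <= 0):
        raise ValueError("exponents must be strictly positive")
    c = np.power(s_arr, 1.0 / r_arr[None, :])
    return c if np.ndim(s) == 2 else c[0]


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def forward_lq(s, m: ModelCoefficients) -> np.ndarray:
    """Linear-quadratic response x_i = 1 + sum_j a_ij s_j + b_ij s_j^2 + d_i s1 s2.

    ``s`` may be a single source pair (2,) or a batch (N, 2); the output
    matches the input shape.
    """
    s_arr = _as_2d(s, "s")
    cross = s_arr[:, 0] * s_arr[:, 1]
    x = s_arr @ m.a.T + (s_arr**2) @ m.b.T + cross[:, None] * m.d[None, :] + 1.0
    return x if np.ndim(s) == 2 else x[0]


def jacobian_lq(s, m: ModelCoefficients) -> np.ndarray:
    """Sensitivity matrix dx/ds, entry (i, j) = a_ij + 2 b_ij s_j + d_i s_{3-j}."""
    s_arr = np.asarray(s, dtype=float)
    if s_arr.shape != (2,):
        raise ValueError("jacobian_lq takes a single source pair of shape (2,)")
    swap = s_arr[::-1]
    return m.a + 2.0 * m.b * s_arr[None, :] + np.outer(m.d, swap)


def forward_variant(c, v: VariantCoefficients) -> np.ndarray:
    """Predict the common observable x = R0/Rg for any model variant.

    The bilinear model is natively stated on 1/Rg - 1/R0 = (x - 1)/R0 and the
    logarithmic one on Rg itself; both are mapped to x with R0 = 1 so that
    all variants are compared on the same measured quantity.  The logarithmic
    variant requires strictly positive concentrations.
    """
    c_arr = _as_2d(c, "c")
    if np.any(c_arr < 0):
        raise ValueError("concentrations must be nonnegative")
    p = v.params
    vid = v.variant_id

    if vid == "linear_quadratic":
        m = v.as_model_coefficients()
        s = sources_from_concentrations(c_arr, m.r)
        x = forward_lq(s, m)
    elif vid == "linear":
        A = p[:4].reshape(2, 2)
        r = p[4:6]
        s = sources_from_concentrations(c_arr, r)
        x = s @ A.T + 1.0
    elif vid == "bilinear":
        A = p[:6].reshape(2, 3)
        r = p[6:8]
        s = sources_from_concentrations(c_arr, r)
        design = np.column_stack([s, s[:, 0] * s[:, 1]])
        x = design @ A.T + 1.0
    elif vid == "logarithmic":
        if np.any(c_arr == 0):
            bad = np.argwhere(c_arr == 0)[0]
            raise ValueError(
                "logarithmic variant is undefined at zero concentration "
                f"(sample {bad[0]}, gas {GAS_NAMES[bad[1]]})"
            )
        A = p.reshape(2, 4)
        lc = np.log(c_arr)
        design = np.column_stack(
            [np.ones(len(c_arr)), lc[:, 0], lc[:, 1], lc[:, 0] * lc[:, 1]]
        )
        rg = design @ A.T
        if np.any(rg <= 0):
            raise ValueError("logarithmic variant predicted nonpositive resistance")
        x = 1.0 / rg
    else:  # pragma: no cover - guarded by VariantCoefficients
        raise ValueError(f"unknown variant {vid!r}")
    return x if np.ndim(c) == 2 else x[0]


# ---------------------------------------------------------------------------
# Packaged reference coefficients
# ---------------------------------------------------------------------------

def reference_coefficients() -> ModelCoefficients:
    """Reference calibration of the SB-30 tin-oxide sensor on acetone-ethanol mixtures.

    These are the published least-squares estimates for the dual-temperature
    (131 degC / 462 degC) virtual-sensor pair; exponents r = (0.60, 0.44).
    """
    text = resources.files("moxquant.data").joinpath("reference_coefficients.json").read_text()
    return ModelCoefficients.from_dict(json.loads(text))
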