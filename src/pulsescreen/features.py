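"""Fourier-series featurisation of periodic waveforms and feature assembly.

Each pressure/flow waveform (one cardiac cycle, uniformly sampled) is
represented by a Fourier series truncated at order N:

    u(t) = sum_{n=0..N} a_n sin(n w t) + b_n cos(n w t),   w = 2 pi / T.

The n = 0 sine term is identically zero, so a waveform is described by
2N + 1 coefficients ordered ``[b0, a1..aN, b1..bN]`` — 11 for the default
N = 5, hence 22 per bilateral measurement.  Coefficients are estimated by
discrete projection on the uniform grid (equivalent to least squares there,
and exact for signals band-limited to N harmonics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations as _combinations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FourierFeatures",
    "MeasurementCombination",
    "MEASUREMENTS",
    "fourier_coefficients",
    "reconstruct",
    "coefficient_names",
    "assemble_features",
    "all_combinations",
    "FourierFeaturizer",
    "ZScoreScaler",
]

#: canonical measurement order used everywhere (three flows, three pressures)
MEASUREMENTS = ("Q1", "Q2", "Q3", "P1", "P2", "P3")
#: side order within a bilateral block
SIDES = ("R", "L")

DEFAULT_ORDER = 5


def _design(m: int, order: int) -> np.ndarray:
    """Projection matrix: rows are the sampled basis functions."""
    k = np.arange(m)
    rows = [np.ones(m)]
    for n in range(1, order + 1):
        rows.append(np.sin(2.0 * np.pi * n * k / m))
    for n in range(1, order + 1):
        rows.append(np.cos(2.0 * np.pi * n * k / m))
    return np.asarray(rows)


@dataclass
class FourierFeatures:
    """Truncated Fourier description of one waveform."""

    coefficients: np.ndarray  # [b0, a1..aN, b1..bN]
    order: int
    omega: float  # rad/s
    site: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (2 * self.order + 1,):
            raise ValueError(
                f"expected {2 * self.order + 1} coefficients for order {self.order}")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")


def fourier_coefficients(
    waveform: np.ndarray,
    period: float,
    order: int = DEFAULT_ORDER,
    site: str = "",
) -> FourierFeatures:
    """Project a uniformly sampled single-cycle waveform onto the basis.

    ``waveform`` holds M >= 2(2N+1) samples at times k*T/M, k = 0..M-1.
    b0 is the sample mean; a_n, b_n carry the factor 2/M.
    """
    u = np.asarray(waveform, dtype=float)
    if u.ndim != 1:
        raise ValueError("waveform must be a 1D array")
    m = u.shape[0]
    if m < 2 * (2 * order + 1):
        raise ValueError(
            f"need at least {2 * (2 * order + 1)} samples for order {order}, got {m}")
    design = _design(m, order)
    coefs = design @ u * (2.0 / m)
    coefs[0] *= 0.5  # b0 is the plain mean
    return FourierFeatures(coefficients=coefs, order=order,
                           omega=2.0 * np.pi / period, site=site)


def reconstruct(features: FourierFeatures, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the truncated series at time(s) t (periodic in 2 pi / omega)."""
    t = np.asarray(t, dtype=float)
    n = np.arange(1, features.order + 1)
    c = features.coefficients
    phase = features.omega * np.multiply.outer(t, n)
    out = c[0] + np.sin(phase) @ c[1:features.order + 1] \
        + np.cos(phase) @ c[features.order + 1:]
    if out.ndim == 0:
        return float(out)
    return out


def coefficient_names(order: int = DEFAULT_ORDER) -> list[str]:
    return (["b0"] + [f"a{n}" for n in range(1, order + 1)]
            + [f"b{n}" for n in range(1, order + 1)])


@dataclass(frozen=True)
class MeasurementCombination:
    """A non-empty subset of the six measurements plus a laterality."""

    measurements: tuple[str, ...]
    laterality: str = "bilateral"  # "bilateral" | "right" | "left"

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError("combination must be non-empty")
        bad = set(self.measurements) - set(MEASUREMENTS)
        if bad:
            raise ValueError(f"unknown measurements: {sorted(bad)}")
        if len(set(self.measurements)) != len(self.measurements):
            raise ValueError("duplicate measurements in combination")
        if self.laterality not in ("bilateral", "right", "left"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        # canonical order
        object.__setattr__(
            self, "measurements",
            tuple(sorted(self.measurements, key=MEASUREMENTS.index)))

    @property
    def sides(self) -> tuple[str, ...]:
        if self.laterality == "bilateral":
            return SIDES
        return ("R",) if self.laterality == "right" else ("L",)

    @property
    def width(self) -> int:
        """Feature count: 11 coefficients per included single-side waveform."""
        return (2 * DEFAULT_ORDER + 1) * len(self.measurements) * len(self.sides)

    @property
    def label(self) -> str:
        tag = "" if self.laterality == "bilateral" else f"[{self.laterality[0].upper()}]"
        return "+".join(self.measurements) + tag

    def column_names(self, order: int = DEFAULT_ORDER) -> list[str]:
        return [f"{m}_{s}_{c}" for m in self.measurements for s in self.sides
                for c in coefficient_names(order)]


def all_combinations(
    measurements: tuple[str, ...] = MEASUREMENTS,
    laterality: str = "bilateral",
) -> list[MeasurementCombination]:
    """All non-empty subsets (2^k - 1), ordered by size then canonically."""
    out = []
    for k in range(1, len(measurements) + 1):
        for sub in _combinations(measurements, k):
            out.append(MeasurementCombination(sub, laterality))
    return out


def assemble_features(
    patients,
    combination: MeasurementCombination,
    order: int = DEFAULT_ORDER,
):
    """Feature matrix + labels for a patient collection.

    Column order is fixed: measurements in canonical order, right side before
    left within a bilateral block, coefficients ``b0, a1..aN, b1..bN``.
    Returns ``(X, y, subject_ids, column_names)`` with y = 1 for diseased.
    """
    cols = combination.column_names(order)
    X = np.empty((len(patients), len(cols)))
    y = np.empty(len(patients), dtype=int)
    ids = []
    for i, p in enumerate(patients):
        row = []
        for m in combination.measurements:
            for s in combination.sides:
                key = f"{m}_{s}"
                if key not in p.waveforms.series:
                    raise KeyError(f"patient {p.subject_id} lacks site {key}")
                row.append(p.fourier(key, order).coefficients)
        X[i] = np.concatenate(row)
        y[i] = 1 if p.label == "diseased" else 0
        ids.append(p.subject_id)
    return X, y, np.asarray(ids), cols


class FourierFeaturizer(BaseEstimator, TransformerMixin):
    """sklearn transformer: rows of sampled single-cycle waveforms to rows of
    2N+1 Fourier coefficients.  Stateless apart from the grid size check."""

    def __init__(self, order: int = DEFAULT_ORDER, period: float = 1.0):
        self.order = order
        self.period = period

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2 * (2 * self.order + 1):
            raise ValueError("X must be (n_waveforms, n_samples) with enough samples")
        self.n_samples_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        design = _design(X.shape[1], self.order)
        out = X @ design.T * (2.0 / X.shape[1])
        out[:, 0] *= 0.5
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(coefficient_names(self.order))


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """Column-wise standardisation to zero mean, unit (population) variance.

    Fitted on the training matrix only; the same affine transform is applied
    to validation/test data (no refitting, no leakage).  Columns with zero
    variance in the training data carry no information and are dropped with
    a warning.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)  # population (1/M) convention
        self.keep_ = self.scale_ > 0
        self.n_dropped_ = int((~self.keep_).sum())
        if self.n_dropped_:
            warnings.warn(
                f"dropping {self.n_dropped_} zero-variance column(s)",
                UserWarning, stacklevel=2)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X[:, self.keep_] - self.mean_[self.keep_]) / self.scale_[self.keep_]

    def inverse_transform(self, Z):
        Z = np.asarray(Z, dtype=float)
        return Z * self.scale_[self.keep_] + self.mean_[self.keep_]
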