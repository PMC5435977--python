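"""In-memory containers for the predictor matrix and the outcome."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FAMILIES = ("gaussian", "binomial", "cox")


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric n x p predictor matrix with feature labels.

    No missing values are allowed.  Zero-variance columns are permitted at
    construction but are excluded from penalized fitting (their coefficient
    is fixed at 0) with a logged warning.
    """

    values: np.ndarray
    feature_names: tuple

    def __init__(self, values, feature_names=None):
        values = np.ascontiguousarray(np.asarray(values, dtype=float))
        if values.ndim != 2:
            raise ValueError("design matrix must be 2-d")
        if values.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(f"non-finite value at row {bad[0]}, column {bad[1]}")
        if feature_names is None:
            feature_names = tuple(f"V{j + 1}" for j in range(values.shape[1]))
        else:
            feature_names = tuple(str(f) for f in feature_names)
            if len(feature_names) != values.shape[1]:
                raise ValueError("feature_names length must equal column count")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_names", feature_names)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def as_matrix(X) -> np.ndarray:
    """Accept a DesignMatrix or a raw array; return the float ndarray."""
    if isinstance(X, DesignMatrix):
        return X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-d")
    return X


@dataclass(frozen=True)
class Outcome:
    """Response for one of the three supported model families.

    gaussian : continuous y
    binomial : 0/1 class labels (both classes required for fitting)
    cox      : right-censored survival times with 0/1 event status
    """

    family: str
    y: np.ndarray
    time: np.ndarray = None
    status: np.ndarray = None

    @classmethod
    def gaussian(cls, y) -> "Outcome":
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite outcome values")
        return cls("gaussian", y)

    @classmethod
    def binomial(cls, y) -> "Outcome":
        y = np.asarray(y, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial outcome must be coded 0/1")
        return cls("binomial", y)

    @classmethod
    def cox(cls, time, status) -> "Outcome":
        time = np.asarray(time, dtype=float)
        status = np.asarray(status, dtype=float)
        if time.shape != status.shape:
            raise ValueError("time and status must have equal length")
        if np.any(time <= 0) or not np.all(np.isfinite(time)):
            raise ValueError("survival times must be positive and finite")
        if not np.isin(status, (0.0, 1.0)).all():
            raise ValueError("status must be coded 0 (censored) / 1 (event)")
        obj = cls("cox", time, time=time, status=status)
        return obj

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def check_fittable(self):
        """Raise if the outcome cannot support a fit (degenerate response)."""
        if self.family == "gaussian" and np.ptp(self.y) == 0:
            raise ValueError("all-constant gaussian outcome")
        if self.family == "binomial" and np.unique(self.y).size < 2:
            raise ValueError("binomial outcome has a single class")
        if self.family == "cox" and self.status.sum() < 1:
            raise ValueError("survival outcome has no events")

    def subset(self, idx) -> "Outcome":
        if self.family == "cox":
            return Outcome.cox(self.time[idx], self.status[idx])
        return Outcome(self.family, self.y[idx])
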