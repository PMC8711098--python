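"""Cohort container, CSV I/O and per-column standardization.

A cohort is a plain tabular dataset: one row per patient, ``d`` predictor
columns and ``q`` continuous target columns (clinically ``d=7``, ``q=1``,
target in kg).  Standardization is always *fit on the training rows* and the
resulting :class:`Scaler` travels with the data / model so the identical
affine transform can be applied to held-out rows.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

#: Canonical clinical predictor schema (gender coded female=1, male=0 --
#: this orientation makes the gender column negatively correlated with dry
#: weight, matching the sign convention of the cohort summary it emulates).
CLINICAL_FEATURES = [
    "gender",
    "age",
    "bmi",
    "heart_rate",
    "dbp",
    "sbp",
    "years_dialysis",
]

DEFAULT_TARGET = "dry_weight"


class CohortError(ValueError):
    """Raised for invalid cohort data (missing values, bad shapes, ...)."""


@dataclasses.dataclass
class Scaler:
    """Per-column affine standardizer: ``z = (x - mean) / sd``.

    ``sd`` is the sample standard deviation (ddof=1).  All entries of ``sd``
    are strictly positive.
    """

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.sd = np.asarray(self.sd, dtype=float).ravel()
        if self.mean.shape != self.sd.shape:
            raise CohortError("scaler mean and sd must have equal length")
        if not np.all(self.sd > 0):
            raise CohortError("scaler sds must be strictly positive")

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean.shape[0]:
            raise CohortError(
                f"scaler expects {self.mean.shape[0]} columns, got {X.shape[-1]}"
            )
        return (X - self.mean) / self.sd

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(np.asarray(d["mean"]), np.asarray(d["sd"]))


@dataclasses.dataclass
class CohortTable:
    """Predictor matrix ``X`` (N x d) plus target matrix ``Y`` (N x q).

    ``scaler`` is ``None`` for raw data and records the (mean, sd) used when
    the predictors were standardized.  Validation rejects missing values and
    shape mismatches at construction time.
    """

    X: np.ndarray
    Y: np.ndarray
    feature_names: list[str]
    target_names: list[str] = dataclasses.field(default_factory=lambda: [DEFAULT_TARGET])
    scaler: Scaler | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.asarray(self.Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        self.Y = Y
        self.feature_names = list(self.feature_names)
        self.target_names = list(self.target_names)
        if self.X.shape[0] < 1:
            raise CohortError("cohort must contain at least one row")
        if self.X.shape[0] != self.Y.shape[0]:
            raise CohortError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        if len(self.feature_names) != self.X.shape[1]:
            raise CohortError("feature_names length does not match X columns")
        if len(self.target_names) != self.Y.shape[1]:
            raise CohortError("target_names length does not match Y columns")
        for name, arr in (("X", self.X), ("Y", self.Y)):
            bad = ~np.isfinite(arr)
            if bad.any():
                row = int(np.argwhere(bad)[0, 0])
                raise CohortError(f"missing/non-finite value in {name} at row {row}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_targets(self) -> int:
        return self.Y.shape[1]

    def subset(self, rows: np.ndarray) -> "CohortTable":
        """Row-indexed view (copy) keeping metadata; scaler is dropped."""
        return CohortTable(
            self.X[rows].copy(),
            self.Y[rows].copy(),
            self.feature_names,
            self.target_names,
            scaler=None,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        for j, t in enumerate(self.target_names):
            df[t] = self.Y[:, j]
        return df


def standardize(cohort: CohortTable) -> CohortTable:
    """Z-score every predictor column (sample sd, ddof=1); targets untouched.

    The fitted :class:`Scaler` is stored on the returned table so the same
    transform can later be applied to held-out rows via :func:`apply_scaler`.

    Raises :class:`CohortError` naming the column if any predictor is
    constant (zero variance).
    """
    X = cohort.X
    mean = X.mean(axis=0)
    # single row: sample sd undefined -> treat as constant column
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        name = cohort.feature_names[int(bad[0])]
        raise CohortError(f"constant predictor column {name!r}: sd is zero")
    scaler = Scaler(mean, sd)
    return CohortTable(
        scaler.transform(X), cohort.Y.copy(), cohort.feature_names,
        cohort.target_names, scaler=scaler,
    )


def apply_scaler(cohort: CohortTable, scaler: Scaler) -> CohortTable:
    """Apply a previously fitted scaler (training-fold statistics) to rows."""
    return CohortTable(
        scaler.transform(cohort.X), cohort.Y.copy(), cohort.feature_names,
        cohort.target_names, scaler=scaler,
    )


def load_cohort_csv(path, target: str | list[str] = DEFAULT_TARGET) -> CohortTable:
    """Read a cohort from headered CSV; ``target`` names the target column(s).

    Lines starting with ``#`` (provenance comments) are ignored.
    """
    df = pd.read_csv(path, comment="#")
    targets = [target] if isinstance(target, str) else list(target)
    missing = [t for t in targets if t not in df.columns]
    if missing:
        raise CohortError(f"target column(s) {missing} not found in {path}")
    features = [c for c in df.columns if c not in targets]
    if not features:
        raise CohortError("no predictor columns found")
    sub = df[features + targets]
    if sub.isna().any().any():
        row = int(sub.isna().any(axis=1).idxmax())
        raise CohortError(f"missing value in {path} at row {row}")
    return CohortTable(
        df[features].to_numpy(float), df[targets].to_numpy(float),
        features, targets,
    )


def save_cohort_csv(cohort: CohortTable, path, metadata: dict | None = None) -> None:
    """Write the cohort as CSV, prefixed with ``# key=value`` provenance lines."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        cohort.to_frame().to_csv(fh, index=False)
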