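"""Evaluation battery: regression metrics, Bland–Altman agreement, k-fold CV.

Metrics follow the clinical evaluation convention for method comparison:
RMSE / Pearson R / R^2 on pooled cross-validated predictions, the signed
prediction errors summarized by their min / median / max (the three numbers
read off a folded empirical cumulative distribution plot), and Bland–Altman
limits of agreement with the 5% out-of-interval acceptability rule.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from .cohort import CohortTable
from .rbf import fit_rbfn_model
from .solver import Hyperparams, fit_mlaprbfn

MODEL_KINDS = ("rbfn", "mlaprbfn")


@dataclasses.dataclass
class MetricsReport:
    """RMSE (target units), Pearson r, R^2, and signed-error summaries."""

    rmse: float
    r: float
    r_squared: float
    ecdp_min: float
    ecdp_median: float
    ecdp_max: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class AgreementReport:
    """Bland–Altman summary of the differences ``pred - ref`` (target units).

    ``loa_low/loa_high`` are the 95% limits of agreement
    ``mean_diff ± 1.96 sd_diff``; ``ci_low/ci_high`` the 95% CI of the mean
    difference; ``n_outside`` counts differences strictly outside the limits.
    The method pair is clinically acceptable when fewer than 5% of points
    fall outside (``n_outside < threshold = ceil(0.05 N)``).
    """

    mean_diff: float
    sd_diff: float
    ci_low: float
    ci_high: float
    loa_low: float
    loa_high: float
    n_outside: int
    ratio_outside: float
    threshold: int
    acceptable: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _as_1d(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


def regression_metrics(pred, ref) -> MetricsReport:
    """Compute RMSE, Pearson r, R^2 and signed-error order statistics.

    Raises if ``ref`` is constant (Pearson r undefined).
    """
    pred = _as_1d(pred, "pred")
    ref = _as_1d(ref, "ref")
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have equal length")
    if pred.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(ref) == 0:
        raise ValueError("reference values are constant: Pearson r undefined")
    err = pred - ref
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.ptp(pred) == 0:
        r = 0.0  # degenerate constant prediction: no linear association
    else:
        r = float(stats.pearsonr(pred, ref).statistic)
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot
    return MetricsReport(
        rmse=rmse,
        r=r,
        r_squared=r_squared,
        ecdp_min=float(err.min()),
        ecdp_median=float(np.median(err)),
        ecdp_max=float(err.max()),
    )


def agreement_threshold(n: int) -> int:
    """Maximum tolerated out-of-agreement count at the 5% rule: ceil(0.05 n)."""
    return math.ceil(0.05 * n)


def bland_altman(pred, ref) -> AgreementReport:
    """Bland–Altman analysis of paired differences ``pred - ref``.

    Uses the sample sd (ddof=1) and the conventional 1.96 multiplier for both
    the limits of agreement and the CI of the mean difference.  Points
    exactly on a limit count as inside.
    """
    pred = _as_1d(pred, "pred")
    ref = _as_1d(ref, "ref")
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have equal length")
    n = pred.size
    if n < 3:
        raise ValueError("Bland–Altman analysis needs at least 3 pairs")
    d = pred - ref
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half_ci = 1.96 * sd / math.sqrt(n)
    loa_low = mean - 1.96 * sd
    loa_high = mean + 1.96 * sd
    outside = int(np.sum((d < loa_low) | (d > loa_high)))
    thr = agreement_threshold(n)
    return AgreementReport(
        mean_diff=mean,
        sd_diff=sd,
        ci_low=mean - half_ci,
        ci_high=mean + half_ci,
        loa_low=loa_low,
        loa_high=loa_high,
        n_outside=outside,
        ratio_outside=outside / n,
        threshold=thr,
        acceptable=outside < thr,
    )


@dataclasses.dataclass
class CVResult:
    """Pooled k-fold predictions (original row order) plus both reports."""

    predictions: np.ndarray
    reference: np.ndarray
    fold_assignment: np.ndarray
    metrics: MetricsReport
    agreement: AgreementReport
    eta_per_fold: list[np.ndarray]


def kfold_cv(
    cohort: CohortTable,
    k: int,
    seed: int,
    hp: Hyperparams,
    model_kind: str = "mlaprbfn",
) -> CVResult:
    """Shuffled k-fold CV with per-fold standardization and graph building.

    Rows are shuffled with ``seed`` and split into folds whose sizes differ
    by at most one.  Each fold's model is fit on the training rows only (the
    scaler and the Laplacians never see the held-out rows); held-out
    predictions are pooled in original row order and the metric and
    agreement reports are computed once on the pooled vector.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    n = cohort.n_samples
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, N]; got k={k}, N={n}")
    min_train = n - math.ceil(n / k)
    if hp.p > min_train:
        raise ValueError(
            f"p={hp.p} exceeds the smallest training-fold size {min_train}"
        )
    pooled = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    etas: list[np.ndarray] = []
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.arange(n))):
        train = cohort.subset(train_idx)
        test_X = cohort.X[test_idx]
        if model_kind == "rbfn":
            model = fit_rbfn_model(train, hp.p, hp.seed)
        else:
            model = fit_mlaprbfn(train, hp)
            etas.append(model.eta.copy())
        pooled[test_idx] = model.predict(test_X)[:, 0]
        fold_of[test_idx] = fold
    ref = cohort.Y[:, 0]
    return CVResult(
        predictions=pooled,
        reference=ref,
        fold_assignment=fold_of,
        metrics=regression_metrics(pooled, ref),
        agreement=bland_altman(pooled, ref),
        eta_per_fold=etas,
    )
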