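"""Plain RBF network: center selection, width rule, design matrix, readout.

The unsupervised stage picks ``p`` centers by k-means on the standardized
predictors and sets one shared Gaussian width

    sigma = sigma_max / sqrt(2 p),

where ``sigma_max`` is the maximum pairwise Euclidean distance among the
centers.  The supervised stage solves the linear readout ``W`` from the
normal equations of the least-squares problem ``min ||Phi W - Y||_F^2``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans

from .cohort import CohortTable, Scaler, standardize


class NumericalError(RuntimeError):
    """Raised when a linear solve fails (rank deficiency, non-finite result)."""


@dataclasses.dataclass
class RBFBasis:
    """Gaussian basis: ``p`` center vectors and one shared width ``sigma``."""

    centers: np.ndarray  # (p, d)
    sigma: float

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.sigma = float(self.sigma)
        if self.centers.shape[0] < 2:
            raise ValueError("an RBF basis needs at least 2 centers")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def p(self) -> int:
        return self.centers.shape[0]

    @property
    def d(self) -> int:
        return self.centers.shape[1]

    def to_dict(self) -> dict:
        return {"centers": self.centers.tolist(), "sigma": self.sigma}

    @classmethod
    def from_dict(cls, d: dict) -> "RBFBasis":
        return cls(np.asarray(d["centers"]), d["sigma"])


def select_centers(X: np.ndarray, p: int, seed: int) -> np.ndarray:
    """Pick ``p`` centers as k-means centroids (k-means++ init, 10 restarts).

    Deterministic for fixed ``(X, p, seed)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if p > n:
        raise ValueError(f"cannot select p={p} centers from N={n} samples")
    if p < 2:
        raise ValueError("p must be >= 2 (the width rule needs two centers)")
    km = KMeans(n_clusters=p, init="k-means++", n_init=10, random_state=seed)
    km.fit(X)
    return km.cluster_centers_.copy()


def compute_width(centers: np.ndarray) -> float:
    """Shared Gaussian width ``sigma_max / sqrt(2p)`` from the center set.

    ``sigma_max`` is the maximum pairwise Euclidean distance between centers.
    Raises if all centers coincide (degenerate basis, zero width).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    p = centers.shape[0]
    if p < 2:
        raise ValueError("width rule needs at least 2 centers")
    sigma_max = float(pdist(centers).max())
    if sigma_max <= 0:
        raise ValueError("all centers identical: degenerate basis (sigma_max=0)")
    return sigma_max / np.sqrt(2.0 * p)


def make_basis(X: np.ndarray, p: int, seed: int) -> RBFBasis:
    """Convenience: k-means centers + width rule in one step."""
    centers = select_centers(X, p, seed)
    return RBFBasis(centers, compute_width(centers))


def design_matrix(X: np.ndarray, basis: RBFBasis) -> np.ndarray:
    """Gaussian activations ``Phi[i,j] = exp(-||x_i - c_j||^2 / (2 sigma^2))``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != basis.d:
        raise ValueError(
            f"X has {X.shape[1]} columns but basis expects {basis.d}"
        )
    if not basis.sigma > 0:
        raise ValueError("sigma must be positive")
    sq = cdist(X, basis.centers, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * basis.sigma**2))


def fit_rbfn(Phi: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Closed-form readout ``W = (Phi^T Phi)^{-1} Phi^T Y`` via a linear solve.

    The plain baseline adds no ridge; a rank-deficient ``Phi^T Phi`` raises
    :class:`NumericalError` advising a smaller ``p`` (the regularized solver
    is the remedy).
    """
    Phi = np.atleast_2d(np.asarray(Phi, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    A = Phi.T @ Phi
    b = Phi.T @ Y
    try:
        W = scipy.linalg.solve(A, b, assume_a="sym")
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise NumericalError(
            "Phi^T Phi is rank deficient; reduce p, jitter the data, or use "
            "the Laplacian-regularized solver"
        ) from exc
    if not np.all(np.isfinite(W)):
        raise NumericalError(
            "normal-equation solve produced non-finite weights; reduce p or "
            "use the Laplacian-regularized solver"
        )
    return W


def rbf_predict(X_new: np.ndarray, basis: RBFBasis, W: np.ndarray) -> np.ndarray:
    """Predict ``Phi_new W`` for new rows (already on the training scale)."""
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    if W.shape[0] != basis.p:
        raise ValueError(f"W has {W.shape[0]} rows but basis has p={basis.p}")
    return design_matrix(X_new, basis) @ W


@dataclasses.dataclass
class RBFNModel:
    """Fitted plain RBFN: scaler + basis + readout weights."""

    scaler: Scaler
    basis: RBFBasis
    W: np.ndarray
    feature_names: list[str]
    target_names: list[str]

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Predict targets for raw (unstandardized) predictor rows."""
        return rbf_predict(self.scaler.transform(np.atleast_2d(X_raw)),
                           self.basis, self.W)


def fit_rbfn_model(cohort: CohortTable, p: int, seed: int) -> RBFNModel:
    """Standardize, build the basis, and solve the closed-form readout."""
    std = standardize(cohort)
    basis = make_basis(std.X, p, seed)
    Phi = design_matrix(std.X, basis)
    W = fit_rbfn(Phi, std.Y)
    return RBFNModel(std.scaler, basis, W, cohort.feature_names,
                     cohort.target_names)
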