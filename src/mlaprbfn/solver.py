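"""Alternating solver for the multi-Laplacian-regularized RBF network.

The training objective, for design matrix Phi (N x p), targets Y (N x q),
readout W (p x q) and view weights eta on the open probability simplex, is

    J(W, eta) = 1/2 ||Phi W - Y||_F^2
              + lambda1/2 * Tr((Phi W)^T (sum_v eta_v^rho L_v) (Phi W))
              + lambda2/2 * sum_j ||W_j||_2            (L2,1 row norm)

The L2,1 term is handled by iteratively reweighted least squares: the
diagonal matrix G with G_jj = 1/(2 ||W_j||_2) majorizes the row norms, so
for fixed (eta, G) the W-step is a closed-form symmetric linear solve

    (Phi^T Phi + lambda1 Phi^T L* Phi + lambda2 G) W = Phi^T Y,

and for fixed W the eta-step has the closed-form simplex solution

    eta_v  proportional to  h_v^{-1/(rho-1)},   h_v = Tr((Phi W)^T L_v (Phi W)).

One iteration is G-update, W-update, eta-update, L*-refresh; the loop runs a
fixed ``tmax`` times (10 by default).  Prediction for new rows is purely
``Phi_new W`` — the Laplacians never see test rows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings

import numpy as np
import scipy.linalg

from . import graphs as _graphs
from .cohort import CohortTable, Scaler, standardize
from .rbf import NumericalError, RBFBasis, design_matrix, make_basis, rbf_predict

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class Hyperparams:
    """Solver hyperparameters.

    Defaults follow the tuned operating point for the 476-patient clinical
    problem: 140 hidden nodes, 10 alternating iterations, lambda1 = lambda2 =
    2^-3, kernel constant gamma = 1, all four kernel views, rho = 2.
    """

    p: int = 140
    tmax: int = 10
    lambda1: float = 2.0**-3
    lambda2: float = 2.0**-3
    rho: float = 2.0
    gamma: float = 1.0
    kernels: tuple[int, ...] = (1, 2, 3, 4)
    eps_irls: float = 1e-8
    eps_trace: float = 1e-12
    seed: int = 0
    #: optional early stop on relative objective change; off by default
    tol_objective: float | None = None

    def __post_init__(self) -> None:
        self.kernels = tuple(int(k) for k in self.kernels)
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be >= 0")
        if not self.rho > 1:
            raise ValueError("rho must be > 1")
        if self.tmax < 1:
            raise ValueError("tmax must be >= 1")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        for k in self.kernels:
            if k not in _graphs.KERNEL_IDS:
                raise ValueError(f"unknown kernel id {k}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kernels"] = list(self.kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparams":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclasses.dataclass
class SolverState:
    """Trajectory of one solver run."""

    W: np.ndarray
    G: np.ndarray  # (p, p) diagonal IRLS matrix
    eta: np.ndarray
    L_star: np.ndarray
    objective_trace: list[float]
    eta_trace: list[np.ndarray]


def objective(
    Phi: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray,
    graphs: _graphs.ViewGraphs,
    hp: Hyperparams,
) -> float:
    """Evaluate J(W, eta) with the non-squared L2,1 penalty."""
    Phi = np.asarray(Phi, dtype=float)
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if W.ndim == 1:
        W = W[:, None]
    R = Phi @ W - Y
    fit = 0.5 * float(np.sum(R * R))
    F = Phi @ W
    L_star = _graphs.fuse(graphs.L_list, graphs.eta, graphs.rho)
    lap = 0.5 * hp.lambda1 * float(np.trace(F.T @ L_star @ F))
    l21 = 0.5 * hp.lambda2 * float(np.linalg.norm(W, axis=1).sum())
    return fit + lap + l21


def update_G(W: np.ndarray, eps_irls: float = 1e-8) -> np.ndarray:
    """IRLS diagonal: ``G_jj = 1 / (2 max(||W_j||_2, eps_irls))``."""
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    row_norms = np.maximum(np.linalg.norm(W, axis=1), eps_irls)
    return np.diag(1.0 / (2.0 * row_norms))


def update_W(
    Phi: np.ndarray,
    Y: np.ndarray,
    L_star: np.ndarray,
    G: np.ndarray,
    lambda1: float,
    lambda2: float,
) -> np.ndarray:
    """Closed-form W-step: solve ``(Phi^T Phi + l1 Phi^T L* Phi + l2 G) W = Phi^T Y``.

    On a singular system the solve is retried once with ``1e-10 I`` jitter
    (logged); if that also fails a :class:`NumericalError` is raised.
    """
    Phi = np.asarray(Phi, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    PhiT = Phi.T
    A = PhiT @ Phi + lambda1 * (PhiT @ L_star @ Phi) + lambda2 * G
    A = (A + A.T) / 2.0
    b = PhiT @ Y
    try:
        W = scipy.linalg.solve(A, b, assume_a="sym")
        if not np.all(np.isfinite(W)):
            raise scipy.linalg.LinAlgError("non-finite solution")
    except (scipy.linalg.LinAlgError, ValueError):
        logger.warning("W-step system singular; retrying with 1e-10 jitter")
        try:
            W = scipy.linalg.solve(
                A + 1e-10 * np.eye(A.shape[0]), b, assume_a="sym"
            )
        except (scipy.linalg.LinAlgError, ValueError) as exc:
            raise NumericalError("W-step system singular even after jitter") from exc
        if not np.all(np.isfinite(W)):
            raise NumericalError("W-step produced non-finite weights after jitter")
    return W


def update_eta(
    Phi: np.ndarray,
    W: np.ndarray,
    L_list: list[np.ndarray],
    rho: float,
    eps_trace: float = 1e-12,
) -> np.ndarray:
    """Closed-form simplex solution of the eta-subproblem.

    With per-view smoothness traces ``h_v = Tr((Phi W)^T L_v (Phi W))``
    (clamped below at ``eps_trace``; indefinite views can produce
    non-positive traces), the minimizer of ``sum_v eta_v^rho h_v`` on the
    simplex is ``eta_v ∝ h_v^{-1/(rho-1)}``.  The output is renormalized so
    it sums to 1 exactly.
    """
    if not rho > 1:
        raise ValueError("rho must be > 1")
    F = np.asarray(Phi, dtype=float) @ np.asarray(W, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    h = np.array([float(np.trace(F.T @ L @ F)) for L in L_list])
    clamped = h < eps_trace
    if clamped.all():
        warnings.warn(
            "all view traces at the clamp floor; returning uniform eta",
            RuntimeWarning,
        )
        return np.full(len(L_list), 1.0 / len(L_list))
    h = np.maximum(h, eps_trace)
    weights = h ** (-1.0 / (rho - 1.0))
    eta = weights / weights.sum()
    # keep eta strictly inside the simplex even under extreme trace ratios
    # (a ratio beyond float precision would otherwise round a weight to 0/1)
    eta = np.maximum(eta, 1e-15)
    return eta / eta.sum()


@dataclasses.dataclass
class MLapRBFNModel:
    """Fitted multi-Laplacian RBF network.

    Carries everything prediction needs (scaler, basis, readout weights) plus
    the solver trajectory for inspection.  Test-time prediction is
    ``Phi_new W`` only; the graphs are a training-time device.
    """

    scaler: Scaler
    basis: RBFBasis
    W: np.ndarray
    eta: np.ndarray
    hp: Hyperparams
    state: SolverState
    feature_names: list[str]
    target_names: list[str]

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Predict targets for raw (unstandardized) predictor rows."""
        return rbf_predict(self.scaler.transform(np.atleast_2d(X_raw)),
                           self.basis, self.W)

    def to_json(self, path) -> None:
        """Serialize scaler, centers, sigma, W, eta and hyperparams."""
        payload = {
            "format": "mlaprbfn-model-v1",
            "scaler": self.scaler.to_dict(),
            "basis": self.basis.to_dict(),
            "W": self.W.tolist(),
            "eta": self.eta.tolist(),
            "hyperparams": self.hp.to_dict(),
            "feature_names": self.feature_names,
            "target_names": self.target_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MLapRBFNModel":
        with open(path) as fh:
            d = json.load(fh)
        hp = Hyperparams.from_dict(d["hyperparams"])
        W = np.asarray(d["W"], dtype=float)
        eta = np.asarray(d["eta"], dtype=float)
        state = SolverState(W, update_G(W, hp.eps_irls), eta,
                            np.zeros((0, 0)), [], [])
        return cls(
            Scaler.from_dict(d["scaler"]), RBFBasis.from_dict(d["basis"]),
            W, eta, hp, state, d["feature_names"], d["target_names"],
        )


def fit_mlaprbfn(cohort: CohortTable, hp: Hyperparams) -> MLapRBFNModel:
    """Run the full alternating algorithm on a training cohort.

    Pipeline: standardize -> k-means centers -> width rule -> design matrix
    -> V Laplacians on the training rows -> eta = 1/V, W from the plain
    normal equations -> ``tmax`` iterations of {G-step, W-step, eta-step,
    L*-refresh}, recording the objective after every iteration.
    """
    if hp.p > cohort.n_samples:
        raise ValueError(
            f"p={hp.p} exceeds the number of training rows N={cohort.n_samples}"
        )
    std = standardize(cohort)
    basis = make_basis(std.X, hp.p, hp.seed)
    Phi = design_matrix(std.X, basis)
    Y = std.Y

    V = len(hp.kernels)
    view_graphs = _graphs.build_view_graphs(
        std.X, kernels=hp.kernels, gamma=hp.gamma, rho=hp.rho
    )
    L_list = view_graphs.L_list
    eta = np.full(V, 1.0 / V)

    # W^(0): plain normal equations, with jitter fallback on singularity
    A0 = Phi.T @ Phi
    b0 = Phi.T @ Y
    try:
        W = scipy.linalg.solve(A0, b0, assume_a="sym")
        if not np.all(np.isfinite(W)):
            raise scipy.linalg.LinAlgError("non-finite W0")
    except (scipy.linalg.LinAlgError, ValueError):
        logger.warning("Phi^T Phi singular at initialization; adding 1e-10 jitter")
        W = scipy.linalg.solve(
            A0 + 1e-10 * np.eye(A0.shape[0]), b0, assume_a="sym"
        )

    L_star = _graphs.fuse(L_list, eta, hp.rho)
    obj_trace: list[float] = []
    eta_trace: list[np.ndarray] = []

    def current_objective() -> float:
        g = _graphs.ViewGraphs(view_graphs.S_list, L_list, eta,
                               gamma=hp.gamma, rho=hp.rho)
        return objective(Phi, Y, W, g, hp)

    obj_trace.append(current_objective())
    G = update_G(W, hp.eps_irls)
    for t in range(hp.tmax):
        G = update_G(W, hp.eps_irls)
        W = update_W(Phi, Y, L_star, G, hp.lambda1, hp.lambda2)
        eta = update_eta(Phi, W, L_list, hp.rho, hp.eps_trace)
        L_star = _graphs.fuse(L_list, eta, hp.rho)
        J = current_objective()
        obj_trace.append(J)
        eta_trace.append(eta.copy())
        logger.debug("iteration %d: J=%.6g eta=%s", t + 1, J, eta)
        if hp.tol_objective is not None and t > 0:
            prev = obj_trace[-2]
            if abs(prev - J) <= hp.tol_objective * max(abs(prev), 1.0):
                logger.info("early stop at iteration %d", t + 1)
                break

    state = SolverState(W, G, eta, L_star, obj_trace, eta_trace)
    return MLapRBFNModel(std.scaler, basis, W, eta, hp, state,
                         cohort.feature_names, cohort.target_names)
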