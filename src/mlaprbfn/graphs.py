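"""Sample-similarity graphs: four heat kernels, normalized Laplacians, fusion.

Each *view* is one similarity kernel evaluated between all pairs of training
rows.  The four kernels (evaluated on standardized predictors, kernel
constant ``gamma`` defaulting to 1) are

    1. Gaussian      S_ij = exp(-gamma ||x_i - x_j||^2)
    2. cosine        S_ij = x_i.x_j / (|x_i| |x_j|)
    3. polynomial    S_ij = (-gamma x_i.x_j + 0.1)^2
    4. sigmoid       S_ij = tanh(-gamma x_i.x_j + 0.1)

Kernels 3 and 4 are decreasing in the inner product; they are implemented
exactly in this (unusual) orientation.  Each similarity matrix is
symmetrized, turned into a normalized Laplacian
``L = D^{-1/2}(D - S)D^{-1/2}`` with row-sum degrees, and the per-view
Laplacians are fused with simplex-constrained view weights eta as
``L* = sum_v eta_v^rho L_v``.

Kernels 2 and 4 can produce negative similarities on z-scored data; ``S``
itself is never clamped, but the Laplacian uses signed-graph degrees
``D_ii = sum_j |S_ij|`` (see :func:`laplacian`) so that every view Laplacian
is positive semidefinite and the smoothness traces driving the view weights
stay nonnegative.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import squareform, pdist

KERNEL_IDS = (1, 2, 3, 4)

#: Degree clamp applied before D^{-1/2} (indefinite kernels can zero a degree).
EPS_DEG = 1e-8


@dataclasses.dataclass
class ViewGraphs:
    """Per-view similarity matrices, Laplacians and simplex view weights."""

    S_list: list[np.ndarray]
    L_list: list[np.ndarray]
    eta: np.ndarray
    gamma: float = 1.0
    rho: float = 2.0

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float).ravel()
        if len(self.S_list) != len(self.L_list) or len(self.L_list) != self.eta.size:
            raise ValueError("S_list, L_list and eta must have equal length")
        if not self.rho > 1:
            raise ValueError("rho must be > 1")
        if not np.isclose(self.eta.sum(), 1.0):
            raise ValueError("eta must sum to 1")
        if np.any(self.eta <= 0) or np.any(self.eta >= 1):
            raise ValueError("eta must lie on the open simplex (0 < eta_v < 1)")

    @property
    def n_views(self) -> int:
        return len(self.L_list)


def similarity_matrix(X: np.ndarray, kernel_id: int, gamma: float = 1.0) -> np.ndarray:
    """Dense N x N similarity matrix for one of the four kernels.

    The result is symmetrized as ``(S + S^T)/2`` to guard against
    floating-point asymmetry (semantically a no-op for these kernels).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if kernel_id not in KERNEL_IDS:
        raise ValueError(f"kernel_id must be one of {KERNEL_IDS}, got {kernel_id}")
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    if kernel_id == 1:
        S = np.exp(-gamma * squareform(pdist(X, metric="sqeuclidean")))
    else:
        G = X @ X.T
        if kernel_id == 2:
            norms = np.sqrt(np.diag(G))
            bad = np.flatnonzero(norms == 0)
            if bad.size:
                raise ValueError(
                    f"cosine kernel undefined: row {int(bad[0])} has zero norm"
                )
            S = G / np.outer(norms, norms)
        elif kernel_id == 3:
            S = (-gamma * G + 0.1) ** 2
        else:  # kernel_id == 4
            S = np.tanh(-gamma * G + 0.1)
    return (S + S.T) / 2.0


def laplacian(S: np.ndarray, eps_deg: float = EPS_DEG) -> np.ndarray:
    """Normalized Laplacian ``D^{-1/2}(D - S)D^{-1/2}`` of a similarity graph.

    Degrees are the signed-graph row sums ``D_ii = sum_j |S_ij|`` — identical
    to the plain row sum for nonnegative similarities, and the standard
    generalization when a kernel produces mixed-sign entries.  With this
    degree the unnormalized Laplacian satisfies
    ``x^T (D - S) x = 1/2 sum_ij |S_ij| (x_i -+ x_j)^2 >= 0``, so every view
    Laplacian is positive semidefinite and its normalized spectrum lies in
    [0, 2]; a mixed-sign kernel's plain row sum, by contrast, can vanish and
    make the normalization explode.  Degrees are still clamped at
    ``eps_deg`` against fully isolated rows, and the output is
    re-symmetrized after the sandwich product.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[0] == 0:
        raise ValueError("empty similarity matrix")
    if S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    deg = np.abs(S).sum(axis=1)
    deg = np.maximum(deg, eps_deg)
    delta = np.diag(deg) - S
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = inv_sqrt[:, None] * delta * inv_sqrt[None, :]
    return (L + L.T) / 2.0


def fuse_laplacians(graphs: ViewGraphs) -> np.ndarray:
    """Weighted fusion ``L* = sum_v eta_v^rho L_v`` of the view Laplacians."""
    return fuse(graphs.L_list, graphs.eta, graphs.rho)


def fuse(L_list: list[np.ndarray], eta: np.ndarray, rho: float) -> np.ndarray:
    """Fusion on bare lists (used inside the solver loop)."""
    eta = np.asarray(eta, dtype=float).ravel()
    if eta.size != len(L_list):
        raise ValueError(
            f"eta has length {eta.size} but there are {len(L_list)} Laplacians"
        )
    L_star = np.zeros_like(L_list[0])
    for w, L in zip(eta**rho, L_list):
        L_star += w * L
    return L_star


def build_view_graphs(
    X: np.ndarray,
    kernels: tuple[int, ...] = KERNEL_IDS,
    gamma: float = 1.0,
    rho: float = 2.0,
    eta: np.ndarray | None = None,
) -> ViewGraphs:
    """Build all views on the (standardized) training rows.

    ``eta`` defaults to the uniform vector 1/V.
    """
    kernels = tuple(kernels)
    if not kernels:
        raise ValueError("at least one kernel view is required")
    S_list = [similarity_matrix(X, k, gamma) for k in kernels]
    L_list = [laplacian(S) for S in S_list]
    if eta is None:
        eta = np.full(len(kernels), 1.0 / len(kernels))
    return ViewGraphs(S_list, L_list, eta, gamma=gamma, rho=rho)
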