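"""Spectral graph machinery for channel graphs.

Given symmetric nonnegative edge weights W (zero diagonal), this module
builds the normalized Laplacian L = I - D^{-1/2} W D^{-1/2}, the renormalized
first-order propagation operator P = D~^{-1/2} (W + I) D~^{-1/2}, exact
spectral filtering through the eigenbasis of L (the brute-force reference),
Chebyshev-recurrence filtering, and the multichannel graph convolution
P X Theta used by the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import chebyshev as _cheb

from .connectivity import ConnectivityMatrix


@dataclass
class GraphSpec:
    """Weights and the derived spectral operators of one channel graph."""

    W: np.ndarray          # symmetric nonnegative, zero diagonal
    D: np.ndarray          # degree vector, D_ii = sum_j W_ij
    L: np.ndarray          # normalized Laplacian
    P: np.ndarray          # renormalized propagation operator
    lambda_max: float      # largest eigenvalue of L

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


def build_graph_spec(W: np.ndarray | ConnectivityMatrix) -> GraphSpec:
    """Derive Laplacian and propagation operators from edge weights.

    Accepts a raw weight matrix or a :class:`ConnectivityMatrix` (whose
    diagonal is zeroed on entry).  Zero-degree nodes get the D^{-1/2} = 0
    convention in L; in P the renormalization's self-loop keeps them
    well-defined.
    """
    if isinstance(W, ConnectivityMatrix):
        W = W.adjacency()
    W = np.asarray(W, dtype=float).copy()
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("W must be square")
    np.fill_diagonal(W, 0.0)
    if np.max(np.abs(W - W.T)) > 1e-10:
        raise ValueError("W must be symmetric")
    if np.any(W < 0):
        raise ValueError("W must be nonnegative")
    d = W.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_isqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    L = np.eye(n) - d_isqrt[:, None] * W * d_isqrt[None, :]
    L = (L + L.T) / 2
    Wt = W + np.eye(n)
    dt_isqrt = 1.0 / np.sqrt(Wt.sum(axis=1))
    P = dt_isqrt[:, None] * Wt * dt_isqrt[None, :]
    P = (P + P.T) / 2
    lam = float(np.linalg.eigvalsh(L).max())
    return GraphSpec(W=W, D=d, L=L, P=P, lambda_max=lam)


def spectral_filter_oracle(g: GraphSpec, theta: np.ndarray,
                           x: np.ndarray) -> np.ndarray:
    """Exact spectral filtering in the eigenbasis of L (reference path).

    Eigendecomposes L, rescales the spectrum to [-1, 1] via
    lambda~ = 2 lambda / lambda_max - 1, evaluates the degree-(K-1)
    Chebyshev series sum_k theta_k T_k(lambda~) on the eigenvalues, and maps
    back: U f(Lambda~) U^T x.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    x = np.asarray(x, dtype=float)
    if x.shape[0] != g.n_nodes:
        raise ValueError("signal length must equal node count")
    lam, U = np.linalg.eigh(g.L)
    lmax = g.lambda_max if g.lambda_max > 0 else 1.0
    lam_scaled = 2.0 * lam / lmax - 1.0
    fvals = _cheb.chebval(lam_scaled, theta)
    return U @ (fvals[:, None] * (U.T @ x).reshape(g.n_nodes, -1)).reshape(
        x.shape)


def chebyshev_graph_filter(g: GraphSpec, theta: np.ndarray, x: np.ndarray,
                           lambda_max: float | None = None) -> np.ndarray:
    """Chebyshev-recurrence graph filtering, cost O(K |E|).

    Uses T_0 x = x, T_1 x = L~ x, T_k x = 2 L~ T_{k-1} x - T_{k-2} x with
    L~ = 2 L / lambda_max - I.  ``lambda_max`` defaults to the exact value
    stored on the graph; pass 2.0 for the common approximation.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    x = np.asarray(x, dtype=float)
    if x.shape[0] != g.n_nodes:
        raise ValueError("signal length must equal node count")
    lmax = lambda_max if lambda_max is not None else g.lambda_max
    if lmax <= 0:
        lmax = 1.0
    Lt = 2.0 * g.L / lmax - np.eye(g.n_nodes)
    t_prev = x
    out = theta[0] * t_prev
    if len(theta) == 1:
        return out
    t_cur = Lt @ x
    out = out + theta[1] * t_cur
    for k in range(2, len(theta)):
        t_next = 2.0 * (Lt @ t_cur) - t_prev
        out = out + theta[k] * t_next
        t_prev, t_cur = t_cur, t_next
    return out


def first_order_propagation(g: GraphSpec, theta: float,
                            x: np.ndarray) -> np.ndarray:
    """First-order renormalized graph convolution: theta * P x."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != g.n_nodes:
        raise ValueError("signal length must equal node count")
    return theta * (g.P @ x)


def multichannel_graph_conv(g: GraphSpec, X: np.ndarray,
                            Theta: np.ndarray) -> np.ndarray:
    """Multi-feature graph convolution P X Theta.

    ``X`` is (n_nodes, C_in) and ``Theta`` (C_in, C_out); output feature j is
    the sum over input features i of the propagated column i weighted by
    Theta[i, j].
    """
    X = np.asarray(X, dtype=float)
    Theta = np.atleast_2d(np.asarray(Theta, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != g.n_nodes:
        raise ValueError("X must have one row per node")
    if X.shape[1] != Theta.shape[0]:
        raise ValueError("Theta not conformable with X features")
    return g.P @ X @ Theta
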