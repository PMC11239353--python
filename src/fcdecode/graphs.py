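"""Connectivity matrices as graphs: adjacency, normalized Laplacian and the
scaled Chebyshev operator used by the spectral graph-convolutional decoder.

The normalized Laplacian is L = I - D^{-1/2} A D^{-1/2}; its spectrum lies in
[0, 2]. The ChebNet filter works on the rescaled operator
L~ = (2 / lambda_max) L - I whose spectrum lies in [-1, 1], so Chebyshev
polynomials T_k(L~) form a stable filter basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix


class IsolatedGraphError(ValueError):
    """Adjacency is identically zero — no graph structure to build on."""


def to_adjacency(conn: ConnectivityMatrix, mode: str = "abs") -> np.ndarray:
    """Correlation matrix -> nonnegative, zero-diagonal adjacency.

    mode="abs" takes |r| (anticorrelation counts as coupling);
    mode="positive" clips negative correlations to zero.
    """
    if mode not in ("abs", "positive"):
        raise ValueError("mode must be 'abs' or 'positive'")
    a = np.abs(conn.values) if mode == "abs" else np.clip(conn.values, 0.0, None)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    if np.all(a == 0):
        raise IsolatedGraphError("adjacency is all-zero (fully uncorrelated input)")
    return a


@dataclass
class BrainGraph:
    """A weighted ROI graph with its spectral operators and node features."""

    adjacency: np.ndarray
    node_features: np.ndarray | None = None  # (N, F)
    eps_degree: float = 1e-6
    laplacian: np.ndarray = field(init=False)
    scaled_laplacian: np.ndarray = field(init=False)
    lambda_max: float = field(init=False)

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        if a.min() < 0:
            raise ValueError("adjacency weights must be nonnegative")
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 0.0)
        deg = a.sum(axis=1)
        if np.any(deg == 0):
            warnings.warn("zero-degree node: regularizing degree by eps", stacklevel=2)
            deg = deg + self.eps_degree
        d_isqrt = 1.0 / np.sqrt(deg)
        n = a.shape[0]
        lap = np.eye(n) - (d_isqrt[:, None] * a) * d_isqrt[None, :]
        lap = (lap + lap.T) / 2.0
        lam = float(np.linalg.eigvalsh(lap).max())
        lam = max(lam, 1e-12)
        self.adjacency = a
        self.laplacian = lap
        self.lambda_max = lam
        self.scaled_laplacian = (2.0 / lam) * lap - np.eye(n)
        if self.node_features is not None:
            x = np.asarray(self.node_features, dtype=float)
            if x.ndim != 2 or x.shape[0] != n:
                raise ValueError("node_features must be (N, F)")
            self.node_features = x

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def build_graph(adjacency: np.ndarray,
                node_features: np.ndarray | None = None,
                lambda_max_approx: bool = False) -> BrainGraph:
    """Build a BrainGraph; ``lambda_max_approx`` uses the lambda_max ~ 2 shortcut
    instead of the exact symmetric eigensolve (useful for large graphs)."""
    g = BrainGraph(adjacency, node_features)
    if lambda_max_approx:
        n = g.n_nodes
        g.lambda_max = 2.0
        g.scaled_laplacian = g.laplacian - np.eye(n)
    return g


def cheb_basis(graph: BrainGraph, order: int) -> list[np.ndarray]:
    """Chebyshev terms [T_0(L~), ..., T_K(L~)] by the three-term recurrence
    T_k = 2 L~ T_{k-1} - T_{k-2}, T_0 = I, T_1 = L~."""
    if order < 1:
        raise ValueError("Chebyshev order must be >= 1")
    lt = graph.scaled_laplacian
    n = graph.n_nodes
    terms = [np.eye(n), lt.copy()]
    for _ in range(2, order + 1):
        terms.append(2.0 * lt @ terms[-1] - terms[-2])
    return terms


def spectral_filter(graph: BrainGraph, x: np.ndarray,
                    theta: np.ndarray) -> np.ndarray:
    """Apply the order-K Chebyshev filter sum_k theta_k T_k(L~) to signal x."""
    theta = np.asarray(theta, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape[0] != graph.n_nodes:
        raise ValueError("signal length must equal the node count")
    if theta.ndim != 1 or theta.size < 2:
        raise ValueError("theta must hold K+1 >= 2 coefficients")
    lt = graph.scaled_laplacian
    t_prev, t_cur = x, lt @ x
    out = theta[0] * t_prev + theta[1] * t_cur
    for k in range(2, theta.size):
        t_prev, t_cur = t_cur, 2.0 * lt @ t_cur - t_prev
        out = out + theta[k] * t_cur
    return out


def spectral_filter_exact(graph: BrainGraph, x: np.ndarray,
                          theta: np.ndarray) -> np.ndarray:
    """Eigendecomposition reference for ``spectral_filter``: filters in the
    graph Fourier domain as U g(Lambda~) U^T x with g evaluated through the
    same Chebyshev expansion. Used as the independent oracle in tests."""
    theta = np.asarray(theta, dtype=float)
    w, u = np.linalg.eigh(graph.scaled_laplacian)
    # closed-form Chebyshev evaluation T_k(lambda) = cos(k arccos lambda)
    ang = np.arccos(np.clip(w, -1.0, 1.0))
    g = sum(theta[k] * np.cos(k * ang) for k in range(theta.size))
    return u @ (g[:, None] * (u.T @ x)) if x.ndim > 1 else u @ (g * (u.T @ x))
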