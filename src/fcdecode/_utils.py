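"""Shared numerical helpers: PSD projections, seeding, small validators."""

from __future__ import annotations

import hashlib

import numpy as np


def spawn_rng(seed: int, *key: str) -> np.random.Generator:
    """Named substream of a single master seed.

    Each (seed, key...) pair yields an independent ``Generator`` so pipeline
    stages (cohort / init / shuffle / shap ...) can be re-run in isolation
    without perturbing one another's draws. Keys are hashed with SHA-256 so
    streams are stable across processes and platforms.
    """
    digest = hashlib.sha256("/".join(key).encode()).digest()
    spawn_key = tuple(int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4))
    ss = np.random.SeedSequence(int(seed), spawn_key=spawn_key)
    return np.random.default_rng(ss)


def is_symmetric(a: np.ndarray, tol: float = 1e-10) -> bool:
    return a.ndim == 2 and a.shape[0] == a.shape[1] and bool(np.all(np.abs(a - a.T) <= tol))


def check_psd(a: np.ndarray, tol: float = 1e-8) -> bool:
    """True when the symmetric matrix has no eigenvalue below ``-tol``."""
    w = np.linalg.eigvalsh((a + a.T) / 2.0)
    return bool(w.min() >= -tol)


def nearest_correlation(a: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Nearest correlation matrix by Higham's alternating projections.

    Projects onto the PSD cone and the unit-diagonal affine set in turn,
    with Dykstra's correction; converges for any symmetric input.
    """
    y = (a + a.T) / 2.0
    n = y.shape[0]
    ds = np.zeros_like(y)
    x = y.copy()
    for _ in range(max_iter):
        r = y - ds
        w, v = np.linalg.eigh(r)
        x = (v * np.clip(w, 0.0, None)) @ v.T
        ds = x - r
        y_prev = y
        y = x.copy()
        np.fill_diagonal(y, 1.0)
        if np.linalg.norm(y - y_prev, ord="fro") < tol * max(1.0, np.linalg.norm(y, ord="fro")):
            break
    np.fill_diagonal(y, 1.0)
    # final PSD safeguard
    w, v = np.linalg.eigh((y + y.T) / 2.0)
    if w.min() < 0:
        y = (v * np.clip(w, 1e-12, None)) @ v.T
        d = np.sqrt(np.diag(y))
        y = y / np.outer(d, d)
        np.fill_diagonal(y, 1.0)
    return (y + y.T) / 2.0


def block_correlation(n_a: int, n_b: int, within_a: float, within_b: float,
                      between: float) -> np.ndarray:
    """Two-block compound-symmetric correlation matrix (projected to PSD)."""
    n = n_a + n_b
    m = np.full((n, n), between, dtype=float)
    m[:n_a, :n_a] = within_a
    m[n_a:, n_a:] = within_b
    np.fill_diagonal(m, 1.0)
    if not check_psd(m):
        m = nearest_correlation(m)
    return m


def sample_wishart_correlation(rng: np.random.Generator, sigma: np.ndarray,
                               df: int) -> np.ndarray:
    """Random correlation matrix centred (approximately) on ``sigma``.

    Draws ``df`` latent normal vectors with covariance ``sigma`` and returns
    the correlation of their scatter matrix; larger ``df`` means a tighter
    concentration around ``sigma``.
    """
    n = sigma.shape[0]
    if df < n + 1:
        raise ValueError(f"wishart df must be >= n+1 = {n + 1}, got {df}")
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(n))
    z = rng.standard_normal((df, n)) @ chol.T
    s = z.T @ z / df
    d = np.sqrt(np.diag(s))
    c = s / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def fisher_z(r: np.ndarray | float, clip: float = 1.0 - 1e-7) -> np.ndarray | float:
    return np.arctanh(np.clip(r, -clip, clip))
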