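"""Random-walk node embeddings (node2vec and walklets) for small ROI graphs.

Both methods generate biased/plain random walks on the weighted graph and
train a skip-gram model with negative sampling (SGNS) on the walk corpus.
node2vec biases transitions with return parameter p and in-out parameter q;
walklets trains one sub-embedding per skip scale (pairs at exact hop
distance k) and concatenates the scales. Written for graphs of tens of
nodes, where a numpy SGNS is entirely adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import spawn_rng


@dataclass
class EmbeddingParams:
    dimensions: int = 16
    walk_length: int = 20
    walks_per_node: int = 50
    window_size: int = 5
    p: float = 1.0  # node2vec return parameter
    q: float = 1.0  # node2vec in-out parameter
    scales: tuple[int, ...] = (1, 2, 3)  # walklets skip scales
    epochs: int = 3
    negative: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.dimensions <= 0:
            raise ValueError("embedding dimension must be positive")


def _random_walks(adj: np.ndarray, params: EmbeddingParams,
                  rng: np.random.Generator) -> np.ndarray:
    """node2vec second-order biased walks; (n_walks, walk_length) node ids."""
    n = adj.shape[0]
    neighbors = [np.where(adj[i] > 0)[0] for i in range(n)]
    weights = [adj[i, neighbors[i]] for i in range(n)]
    walks = []
    for start in range(n):
        for _ in range(params.walks_per_node):
            walk = [start]
            while len(walk) < params.walk_length:
                cur = walk[-1]
                nbrs = neighbors[cur]
                if nbrs.size == 0:
                    break
                w = weights[cur].astype(float).copy()
                if len(walk) > 1 and (params.p != 1.0 or params.q != 1.0):
                    prev = walk[-2]
                    for idx, nxt in enumerate(nbrs):
                        if nxt == prev:
                            w[idx] /= params.p
                        elif adj[prev, nxt] == 0:
                            w[idx] /= params.q
                w = w / w.sum()
                walk.append(int(rng.choice(nbrs, p=w)))
            walks.append(walk)
    length = min(len(w) for w in walks)
    return np.array([w[:length] for w in walks], dtype=int)


def _sgns(pairs: np.ndarray, n_nodes: int, dim: int, params: EmbeddingParams,
          rng: np.random.Generator) -> np.ndarray:
    """Skip-gram with negative sampling on (center, context) pairs."""
    w_in = (rng.random((n_nodes, dim)) - 0.5) / dim
    w_out = np.zeros((n_nodes, dim))
    lr = params.learning_rate
    for _ in range(params.epochs):
        order = rng.permutation(len(pairs))
        for center, context in pairs[order]:
            targets = np.concatenate(([context],
                                      rng.integers(0, n_nodes, params.negative)))
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            v = w_in[center]
            u = w_out[targets]
            scores = 1.0 / (1.0 + np.exp(-np.clip(u @ v, -30, 30)))
            g = (scores - labels) * lr
            w_in[center] = v - g @ u
            w_out[targets] = u - np.outer(g, v)
    return w_in


def _walk_pairs(walks: np.ndarray, window: int) -> np.ndarray:
    pairs = []
    for walk in walks:
        for i, center in enumerate(walk):
            lo, hi = max(0, i - window), min(len(walk), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((center, walk[j]))
    return np.array(pairs, dtype=int)


def _scale_pairs(walks: np.ndarray, scale: int) -> np.ndarray:
    """Walklets corpus at skip scale k: pairs at exact hop distance k."""
    pairs = []
    for walk in walks:
        for i in range(len(walk) - scale):
            pairs.append((walk[i], walk[i + scale]))
            pairs.append((walk[i + scale], walk[i]))
    return np.array(pairs, dtype=int)


def embed_nodes(adjacency: np.ndarray, method: str = "node2vec",
                params: EmbeddingParams | None = None) -> np.ndarray:
    """One embedding vector per node; deterministic under ``params.seed``."""
    params = params or EmbeddingParams()
    adj = np.asarray(adjacency, dtype=float)
    n = adj.shape[0]
    if n == 1 or not np.any(adj > 0):
        dim = (params.dimensions if method == "node2vec"
               else params.dimensions * len(params.scales))
        return np.zeros((n, dim))
    rng = spawn_rng(params.seed, "embedding", method)
    walks = _random_walks(adj, params, rng)
    if method == "node2vec":
        pairs = _walk_pairs(walks, params.window_size)
        return _sgns(pairs, n, params.dimensions, params, rng)
    if method == "walklets":
        parts = []
        for scale in params.scales:
            pairs = _scale_pairs(walks, scale)
            parts.append(_sgns(pairs, n, params.dimensions, params, rng))
        return np.concatenate(parts, axis=1)
    raise ValueError("method must be 'node2vec' or 'walklets'")
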