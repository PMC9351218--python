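"""Topological protein representations via biased random walks + skip-gram.

This is the node2vec procedure: for every node, ``r`` second-order random
walks of length ``l`` are simulated.  A walk that just moved from node ``t``
to node ``v`` chooses the next node ``x`` among the neighbours of ``v`` with
unnormalized probability ``alpha_pq(t, x) * w(v, x)`` where::

    alpha_pq(t, x) = 1/p  if d(t, x) = 0   (return to t)
                     1    if d(t, x) = 1   (x also neighbours t)
                     1/q  if d(t, x) = 2   (x moves outward)

The walk corpus is then fed to a skip-gram model with negative sampling
(SGNS), trained by mini-batched SGD, yielding one dense vector per node.

Defaults follow common practice for PPI embedding: walk length 20, 10 walks
per node, embedding dimension 64, context window 10, ``p = q = 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WalkParams",
    "transition_bias",
    "next_step_distribution",
    "generate_walks",
    "train_skipgram",
    "embed_network",
]


@dataclass(frozen=True)
class WalkParams:
    """Parameters of the second-order random walk."""

    walk_length: int = 20
    num_walks: int = 10
    p: float = 1.0
    q: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.num_walks < 1:
            raise ValueError("num_walks must be >= 1")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


def transition_bias(d_tx: int, p: float, q: float) -> float:
    """Second-order bias ``alpha_pq`` as a function of the distance d(t, x)."""
    if d_tx == 0:
        return 1.0 / p
    if d_tx == 1:
        return 1.0
    if d_tx == 2:
        return 1.0 / q
    raise ValueError(f"d_tx must be in {{0, 1, 2}}, got {d_tx}")


def next_step_distribution(
    graph: nx.Graph, prev, cur, params: WalkParams
) -> tuple[list, np.ndarray]:
    """Transition distribution over the neighbours of ``cur``.

    Returns the neighbour list (sorted for determinism) and the matching
    probability vector.  On the first step (``prev is None``) the
    distribution is uniform over neighbours.
    """
    neighbors = sorted(graph.neighbors(cur))
    if not neighbors:
        raise ValueError(f"node {cur!r} has no neighbors; walk cannot proceed")
    if prev is None:
        probs = np.full(len(neighbors), 1.0 / len(neighbors))
        return neighbors, probs
    weights = np.empty(len(neighbors))
    for i, x in enumerate(neighbors):
        if x == prev:
            d = 0
        elif graph.has_edge(prev, x):
            d = 1
        else:
            d = 2
        weights[i] = transition_bias(d, params.p, params.q) * graph[cur][x].get("weight", 1.0)
    probs = weights / weights.sum()
    return neighbors, probs


def _indexed_adjacency(graph: nx.Graph) -> tuple[list, dict, list[np.ndarray]]:
    """Integer-indexed sorted adjacency arrays for fast walking."""
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    adj = [
        np.array(sorted(index[m] for m in graph.neighbors(n)), dtype=np.int64)
        for n in nodes
    ]
    return nodes, index, adj


def generate_walks(graph: nx.Graph, params: WalkParams) -> list[list]:
    """Simulate ``num_walks`` biased walks of length ``walk_length`` per node.

    Isolated nodes yield length-1 walks.  Reproducible under ``params.seed``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes, _, adj = _indexed_adjacency(graph)
    rng = np.random.default_rng(params.seed)
    n = len(nodes)
    simple = params.p == 1.0 and params.q == 1.0
    inv_p, inv_q = 1.0 / params.p, 1.0 / params.q
    walks: list[list] = []
    order = np.arange(n)
    for _ in range(params.num_walks):
        rng.shuffle(order)
        for start in order:
            walk = [start]
            cur = start
            prev = -1
            while len(walk) < params.walk_length:
                nbrs = adj[cur]
                if nbrs.size == 0:
                    break
                if simple or prev < 0:
                    nxt = nbrs[rng.integers(nbrs.size)]
                else:
                    # d=0 where x == prev; d=1 where x adjacent to prev; else d=2
                    w = np.where(np.isin(nbrs, adj[prev], assume_unique=True), 1.0, inv_q)
                    loc = np.searchsorted(nbrs, prev)
                    if loc < nbrs.size and nbrs[loc] == prev:
                        w[loc] = inv_p
                    w /= w.sum()
                    nxt = rng.choice(nbrs, p=w)
                prev, cur = cur, int(nxt)
                walk.append(cur)
            walks.append([nodes[i] for i in walk])
    return walks


def train_skipgram(
    corpus: list[list],
    dim: int = 64,
    window: int = 10,
    seed: int = 0,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
) -> dict:
    """Train skip-gram with negative sampling on a walk corpus.

    Sequential SGD over (center, context) pairs, word2vec style: for every
    token the effective window is drawn uniformly from ``1..window`` (the
    reduced-window trick), ``negative`` noise nodes per pair are drawn from
    the unigram distribution raised to the 3/4 power, and the step size
    decays linearly from ``alpha`` to ``min_alpha``.  The inner update loop
    is JIT-compiled (numba) and single-threaded, so training is
    deterministic for a fixed seed.

    Returns a mapping node -> ``dim``-vector for every node in the corpus.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if dim < 1 or window < 1:
        raise ValueError("dim and window must be >= 1")
    vocab = sorted({node for walk in corpus for node in walk})
    index = {n: i for i, n in enumerate(vocab)}
    V = len(vocab)
    rng = np.random.default_rng(seed)

    sentences = [np.array([index[n] for n in walk], dtype=np.int64) for walk in corpus]
    flat = np.concatenate(sentences)
    counts = np.bincount(flat, minlength=V).astype(float)
    noise_cdf = np.cumsum(counts**0.75)
    noise_cdf /= noise_cdf[-1]

    w_in = rng.uniform(-0.5 / dim, 0.5 / dim, size=(V, dim)).astype(np.float32)
    w_out = np.zeros((V, dim), dtype=np.float32)

    # Build (center, context) pairs for one epoch, vectorized per offset.
    def epoch_pairs() -> tuple[np.ndarray, np.ndarray]:
        reduced = rng.integers(1, window + 1, size=flat.size)
        # sentence id per token, to forbid pairs across walk boundaries
        sent_id = np.repeat(np.arange(len(sentences)), [s.size for s in sentences])
        centers, contexts = [], []
        for d in range(1, window + 1):
            same = sent_id[:-d] == sent_id[d:]
            left = same & (reduced[:-d] >= d)  # center i, context i+d
            right = same & (reduced[d:] >= d)  # center i+d, context i
            idx = np.nonzero(left)[0]
            centers.append(idx)
            contexts.append(idx + d)
            idx = np.nonzero(right)[0]
            centers.append(idx + d)
            contexts.append(idx)
        c = flat[np.concatenate(centers)]
        o = flat[np.concatenate(contexts)]
        perm = rng.permutation(c.size)
        return c[perm], o[perm]

    # linear learning-rate schedule over the expected total pair count
    mean_red = (window + 1) / 2.0
    total = max(1, int(epochs * flat.size * 2 * mean_red))
    done = 0
    chunk = 200_000
    for _ in range(epochs):
        c_all, o_all = epoch_pairs()
        for s in range(0, c_all.size, chunk):
            c = c_all[s : s + chunk]
            o = o_all[s : s + chunk]
            lr = max(min_alpha, alpha * (1.0 - done / total))
            neg = np.searchsorted(
                noise_cdf, rng.random((c.size, negative))
            ).astype(np.int64)
            _sgns_updates(w_in, w_out, c, o, neg, np.float32(lr))
            done += c.size
    return {node: w_in[index[node]].astype(float) for node in vocab}


def _sgns_updates(w_in, w_out, centers, contexts, negatives, lr):  # pragma: no cover
    """Sequential SGNS updates; JIT-compiled on first use."""
    global _sgns_updates
    from numba import njit

    @njit(cache=True, fastmath=False)
    def kernel(w_in, w_out, centers, contexts, negatives, lr):
        n_pairs, n_neg = negatives.shape
        dim = w_in.shape[1]
        grad = np.empty(dim, dtype=np.float32)
        for i in range(n_pairs):
            v = w_in[centers[i]]
            grad[:] = 0.0
            for k in range(-1, n_neg):
                target = contexts[i] if k < 0 else negatives[i, k]
                label = 1.0 if k < 0 else 0.0
                u = w_out[target]
                dot = 0.0
                for d in range(dim):
                    dot += v[d] * u[d]
                if dot > 8.0:
                    f = 1.0
                elif dot < -8.0:
                    f = 0.0
                else:
                    f = 1.0 / (1.0 + np.exp(-dot))
                g = np.float32((f - label) * lr)
                for d in range(dim):
                    grad[d] += g * u[d]
                    u[d] -= g * v[d]
            for d in range(dim):
                v[d] -= grad[d]

    _sgns_updates = kernel
    return kernel(w_in, w_out, centers, contexts, negatives, lr)


def embed_network(
    graph: nx.Graph,
    params: WalkParams | None = None,
    dim: int = 64,
    window: int = 10,
) -> dict:
    """Walks + skip-gram; every graph node gets a vector.

    Isolated nodes never appear in any context and receive a zero vector
    (logged), preserving alignment with the other feature blocks.
    """
    params = params or WalkParams()
    walks = generate_walks(graph, params)
    trainable = [w for w in walks if len(w) >= 2]
    embedding = train_skipgram(trainable, dim=dim, window=window, seed=params.seed)
    missing = [n for n in graph.nodes if n not in embedding]
    if missing:
        logger.warning("%d isolated node(s) received zero embeddings", len(missing))
        for n in missing:
            embedding[n] = np.zeros(dim)
    return embedding
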