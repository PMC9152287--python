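"""Second-order biased random walks (node2vec-style).

A walk at node ``curr`` that arrived from ``prev`` scores each neighbor
``x`` of ``curr`` as ``w(curr, x) * alpha`` with

* ``alpha = 1/p``  if ``x == prev``          (return),
* ``alpha = 1``    if ``x`` is adjacent to ``prev`` (stay close, BFS-like),
* ``alpha = 1/q``  otherwise                 (move outward, DFS-like),

then samples proportionally. ``p > 1`` discourages immediate backtracking;
``q < 1`` favors outward, depth-first-like exploration. With ``p = q = 1``
the walk reduces to the plain weight-proportional (DeepWalk) random walk.
Edge weights always scale transition probabilities, so the weighted
similarity graph biases walks toward functionally similar miRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graphs import AdjacencyView

logger = logging.getLogger(__name__)


@dataclass
class WalkConfig:
    """Walk generation parameters.

    ``p`` (return) and ``q`` (in-out) are dimensionless bias parameters;
    defaults follow the package-wide convention p=10, q=0.5 with 10 walks of
    length 80 per node.
    """

    p: float = 10.0
    q: float = 0.5
    num_walks: int = 10
    walk_length: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.num_walks < 1:
            raise ValueError("num_walks must be >= 1")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")


@dataclass
class WalkCorpus:
    """Collection of node-index walks plus the id vocabulary they index."""

    node_ids: list[str]
    walks: list[np.ndarray] = field(repr=False)

    def __len__(self) -> int:
        return len(self.walks)

    def as_id_walks(self) -> list[list[str]]:
        return [[self.node_ids[i] for i in walk] for walk in self.walks]


def _second_order_scores(
    graph: AdjacencyView, prev: int, curr: int, p: float, q: float
) -> np.ndarray:
    """Unnormalized transition scores over ``graph.neighbors[curr]``."""
    nbrs = graph.neighbors[curr]
    w = graph.weights[curr]
    prev_nbrs = graph.neighbors[prev]
    # alpha defaults to 1/q; overridden to 1 for common neighbors of prev,
    # and to 1/p for the return edge.
    alpha = np.full(len(nbrs), 1.0 / q)
    if len(prev_nbrs):
        pos = np.searchsorted(prev_nbrs, nbrs)
        pos[pos == len(prev_nbrs)] = len(prev_nbrs) - 1
        alpha[prev_nbrs[pos] == nbrs] = 1.0
    alpha[nbrs == prev] = 1.0 / p
    return w * alpha


def transition_distribution(
    graph: AdjacencyView, prev: str | int | None, curr: str | int, cfg: WalkConfig
) -> dict[str, float]:
    """Normalized transition probabilities from ``curr`` given ``prev``.

    ``prev=None`` gives the first-step distribution (plain weight-
    proportional). Returns an empty mapping for an isolated ``curr``,
    signalling the caller to end the walk. The returned probabilities sum
    to 1 within 1e-12.
    """
    ci = graph.index_of(curr) if isinstance(curr, str) else int(curr)
    nbrs = graph.neighbors[ci]
    if len(nbrs) == 0:
        return {}
    if prev is None:
        scores = graph.weights[ci].copy()
    else:
        pi = graph.index_of(prev) if isinstance(prev, str) else int(prev)
        scores = _second_order_scores(graph, pi, ci, cfg.p, cfg.q)
    probs = scores / scores.sum()
    return {graph.node_ids[n]: float(pr) for n, pr in zip(nbrs, probs)}


def _sample(scores: np.ndarray, rng: np.random.Generator) -> int:
    """Index sampled proportionally to non-negative scores (cumsum inversion)."""
    cum = np.cumsum(scores)
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))


def generate_walks(graph: AdjacencyView, cfg: WalkConfig) -> WalkCorpus:
    """Generate ``num_walks`` biased walks of ``walk_length`` nodes per node.

    The first step from each start uses weight-proportional probabilities
    (there is no previous node yet); later steps apply the second-order
    bias. Isolated start nodes produce no walks (logged once). Node order
    is shuffled per pass with the seeded generator, so the corpus is
    reproducible bit-for-bit given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    starts = np.array(
        [i for i in range(graph.n_nodes) if len(graph.neighbors[i]) > 0], dtype=np.int64
    )
    n_isolated = graph.n_nodes - len(starts)
    if n_isolated:
        logger.info("%d isolated nodes produce no walks", n_isolated)
    walks: list[np.ndarray] = []
    for _ in range(cfg.num_walks):
        order = rng.permutation(starts)
        for start in order:
            walk = np.empty(cfg.walk_length, dtype=np.int64)
            walk[0] = start
            nbrs = graph.neighbors[start]
            curr = int(nbrs[_sample(graph.weights[start], rng)])
            walk[1] = curr
            prev = int(start)
            length = 2
            for t in range(2, cfg.walk_length):
                nbrs = graph.neighbors[curr]
                if len(nbrs) == 0:  # dead end: isolated continuation
                    break
                scores = _second_order_scores(graph, prev, curr, cfg.p, cfg.q)
                nxt = int(nbrs[_sample(scores, rng)])
                walk[t] = nxt
                prev, curr = curr, nxt
                length = t + 1
            walks.append(walk[:length])
    return WalkCorpus(node_ids=list(graph.node_ids), walks=walks)
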