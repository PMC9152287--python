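"""Node embedding estimator and per-miRNA feature fusion.

:class:`Node2Vec` wraps walk generation plus skip-gram training as an
estimator (``fit`` on a network, fitted ``embedding_``). With ``p=1, q=1``
it degenerates to the unbiased DeepWalk scheme. :func:`fuse_features`
concatenates the similarity-network and interaction-network embeddings
into one feature row per miRNA (default 512 + 512 = 1024 columns),
zero-padding the block of any network the miRNA is missing from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .graphs import AdjacencyView, BipartiteNetwork, SimilarityNetwork, normalize_id
from .skipgram import EmbeddingMatrix, SkipGramConfig, train_skipgram
from .walks import WalkConfig, generate_walks

logger = logging.getLogger(__name__)


class Node2Vec(BaseEstimator):
    """Biased random-walk + skip-gram graph embedder.

    Parameters
    ----------
    p, q:
        Return and in-out walk-bias parameters. Defaults p=10, q=0.5
        (breadth-limiting, outward-exploring); p=q=1 gives DeepWalk.
    dim:
        Embedding dimension per network (default 512).
    num_walks, walk_length, window, negatives, epochs, learning_rate:
        Walk-corpus and skip-gram training sizes; defaults are the
        reference node2vec/word2vec values.
    random_state:
        Seeds both walk generation and skip-gram training.
    """

    def __init__(
        self,
        p: float = 10.0,
        q: float = 0.5,
        dim: int = 512,
        num_walks: int = 10,
        walk_length: int = 80,
        window: int = 10,
        negatives: int = 5,
        epochs: int = 5,
        learning_rate: float = 0.025,
        batch_pairs: int = 1024,
        random_state: int = 0,
    ):
        self.p = p
        self.q = q
        self.dim = dim
        self.num_walks = num_walks
        self.walk_length = walk_length
        self.window = window
        self.negatives = negatives
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_pairs = batch_pairs
        self.random_state = random_state

    def fit(self, X: SimilarityNetwork | BipartiteNetwork | AdjacencyView, y=None):
        """Embed every node of the network ``X``."""
        if isinstance(X, SimilarityNetwork):
            graph = AdjacencyView.from_similarity(X)
        elif isinstance(X, BipartiteNetwork):
            graph = AdjacencyView.from_bipartite(X)
        else:
            graph = X
        walk_cfg = WalkConfig(
            p=self.p,
            q=self.q,
            num_walks=self.num_walks,
            walk_length=self.walk_length,
            seed=self.random_state,
        )
        sg_cfg = SkipGramConfig(
            dim=self.dim,
            window=self.window,
            negatives=self.negatives,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            batch_pairs=self.batch_pairs,
            seed=self.random_state,
        )
        corpus = generate_walks(graph, walk_cfg)
        self.embedding_ = train_skipgram(corpus, sg_cfg)
        self.node_ids_ = self.embedding_.node_ids
        return self

    def fit_transform(self, X, y=None) -> EmbeddingMatrix:
        return self.fit(X).embedding_


@dataclass
class FeatureTable:
    """Fused per-miRNA feature rows.

    ``features`` has one 2*d-wide row per miRNA: the similarity-network
    block followed by the interaction-network block. ``presence[i]`` is
    ``(in_similarity, in_interaction)``; a missing block is exactly zero.
    """

    mirna_ids: list[str]
    features: np.ndarray = field(repr=False)
    presence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.features.shape[0] != len(self.mirna_ids):
            raise ValueError("feature row count must match mirna_ids")

    @property
    def width(self) -> int:
        return self.features.shape[1]

    @property
    def block_width(self) -> int:
        return self.features.shape[1] // 2

    def row_of(self, mirna: str) -> int:
        if not hasattr(self, "_index"):
            self._index = {normalize_id(m): i for i, m in enumerate(self.mirna_ids)}
        return self._index[normalize_id(mirna)]

    def mask_block(self, source: str) -> "FeatureTable":
        """Zero one network's block: ``source`` in {'similarity_only',
        'interaction_only', 'both'} names the block(s) to KEEP."""
        if source == "both":
            return self
        feats = self.features.copy()
        d = self.block_width
        if source == "similarity_only":
            feats[:, d:] = 0.0
        elif source == "interaction_only":
            feats[:, :d] = 0.0
        else:
            raise ValueError(f"unknown feature source: {source!r}")
        return FeatureTable(list(self.mirna_ids), feats, self.presence.copy())


def fuse_features(
    emb_sim: EmbeddingMatrix | None,
    emb_int: EmbeddingMatrix | None,
    mirna_universe: list[str],
) -> FeatureTable:
    """Concatenate per-network embeddings into per-miRNA feature rows.

    ``mirna_universe`` fixes the (deterministic) row order and restricts
    the interaction embedding to miRNA nodes — gene vectors are discarded.
    A miRNA present in only one network gets zeros in the other network's
    block; a miRNA absent from both is excluded with a warning.
    """
    if emb_sim is None and emb_int is None:
        raise ValueError("at least one embedding is required")
    dims = [e.dim for e in (emb_sim, emb_int) if e is not None]
    if len(dims) == 2 and dims[0] != dims[1]:
        raise ValueError(f"per-network dimensions differ: {dims[0]} vs {dims[1]}")
    d = dims[0]

    sim_lookup = (
        {normalize_id(n): v for n, v in zip(emb_sim.node_ids, emb_sim.vectors)}
        if emb_sim is not None
        else {}
    )
    int_lookup = (
        {normalize_id(n): v for n, v in zip(emb_int.node_ids, emb_int.vectors)}
        if emb_int is not None
        else {}
    )

    kept: list[str] = []
    rows: list[np.ndarray] = []
    presence: list[tuple[bool, bool]] = []
    n_dropped = 0
    for mirna in mirna_universe:
        key = normalize_id(mirna)
        in_sim, in_int = key in sim_lookup, key in int_lookup
        if not in_sim and not in_int:
            n_dropped += 1
            continue
        row = np.zeros(2 * d)
        if in_sim:
            row[:d] = sim_lookup[key]
        if in_int:
            row[d:] = int_lookup[key]
        kept.append(mirna)
        rows.append(row)
        presence.append((in_sim, in_int))
    if n_dropped:
        logger.warning("%d miRNAs absent from both networks were excluded", n_dropped)
    if not kept:
        raise ValueError("no miRNA from the universe appears in any network")
    return FeatureTable(
        mirna_ids=kept,
        features=np.vstack(rows),
        presence=np.array(presence, dtype=bool),
    )


def mirna_universe(
    sim: SimilarityNetwork | None, interactions: BipartiteNetwork | None
) -> list[str]:
    """Union of miRNA ids across networks, similarity order first, then
    interaction-only miRNAs in their input order (deterministic)."""
    seen: dict[str, str] = {}
    if sim is not None:
        for n in sim.node_ids:
            seen.setdefault(normalize_id(n), n)
    if interactions is not None:
        for n in interactions.mirna_ids:
            seen.setdefault(normalize_id(n), n)
    return list(seen.values())
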