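"""Skip-gram with negative sampling over random-walk corpora.

Walks are treated as sentences: every ordered pair of nodes co-occurring
within a window is a (center, context) training example. The exact
objective maximizes, per node ``u`` and walk-neighborhood ``N_S(u)``,
``sum log P(v | f(u))`` with the softmax

    P(v | f(u)) = exp(f(u)^T f(v)) / sum_n exp(f(u)^T f(n)),

whose per-pair negative-sampling surrogate

    -log sigmoid(u . v_o) - sum_k log sigmoid(-u . v_{n_k})

is what training optimizes (the softmax normalization over the whole
vocabulary is replaced by ``k`` noise samples drawn from the unigram^0.75
distribution). Optimization is plain SGD with a linearly decaying rate,
word2vec-style: input vectors initialized uniformly in [-0.5/d, 0.5/d],
context vectors at zero. The exact softmax is kept as a separate oracle
(:func:`exact_softmax_loss`) used only for small-graph verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, log_expit

from .walks import WalkCorpus


@dataclass
class SkipGramConfig:
    dim: int = 512
    window: int = 10
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    batch_pairs: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.negatives < 0:
            raise ValueError("negatives must be >= 0")


@dataclass
class EmbeddingMatrix:
    """Per-node embedding vectors; row order matches ``node_ids``."""

    node_ids: list[str]
    vectors: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.node_ids):
            raise ValueError("vectors row count must match node_ids")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite values")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def lookup(self) -> dict[str, np.ndarray]:
        return {n: self.vectors[i] for i, n in enumerate(self.node_ids)}


def extract_pairs(corpus: WalkCorpus, window: int) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) index pairs within ``window`` positions, both
    directions, vectorized per offset."""
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for walk in corpus.walks:
        L = len(walk)
        for k in range(1, min(window, L - 1) + 1):
            a, b = walk[:-k], walk[k:]
            centers.append(a)
            contexts.append(b)
            centers.append(b)
            contexts.append(a)
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def sgns_pair_loss_grad(
    u: np.ndarray, v_pos: np.ndarray, v_negs: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss and analytic gradients for one (center, context, negatives) example.

    Returns ``(loss, dL/du, dL/dv_pos, dL/dv_negs)``. Shared with the
    batched trainer's algebra; exposed for gradient verification.
    """
    s_pos = float(u @ v_pos)
    s_neg = v_negs @ u
    loss = -float(log_expit(s_pos)) - float(np.sum(log_expit(-s_neg)))
    g_pos = expit(s_pos) - 1.0
    g_neg = expit(s_neg)
    du = g_pos * v_pos + g_neg @ v_negs
    dv_pos = g_pos * u
    dv_negs = g_neg[:, None] * u[None, :]
    return loss, du, dv_pos, dv_negs


def _noise_cdf(counts: np.ndarray) -> np.ndarray:
    weights = counts.astype(float) ** 0.75
    total = weights.sum()
    if total == 0:
        raise ValueError("empty corpus: no nodes to sample negatives from")
    return np.cumsum(weights / total)


def train_skipgram(corpus: WalkCorpus, cfg: SkipGramConfig) -> EmbeddingMatrix:
    """Train embeddings on a walk corpus; deterministic given the seed.

    The vocabulary is the corpus's node-id list (graph order); nodes that
    never occur in a walk keep their initial vectors and are never drawn
    as noise.
    """
    if len(corpus.walks) == 0:
        raise ValueError("corpus is empty")
    rng = np.random.default_rng(cfg.seed)
    V, d = len(corpus.node_ids), cfg.dim
    w_in = rng.uniform(-0.5 / d, 0.5 / d, size=(V, d))
    w_out = np.zeros((V, d))

    centers, contexts = extract_pairs(corpus, cfg.window)
    counts = np.bincount(np.concatenate([w for w in corpus.walks]), minlength=V)
    noise_cdf = _noise_cdf(counts)

    n_pairs = len(centers)
    total_updates = cfg.epochs * n_pairs
    done = 0
    # Batches accumulate pair gradients at fixed parameters, so a batch
    # must stay a small fraction of an epoch or nodes repeated many times
    # within it take oversized steps and diverge on small corpora.
    B = max(1, min(cfg.batch_pairs, n_pairs // 50))
    K = cfg.negatives
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, B):
            idx = order[lo : lo + B]
            c, o = centers[idx], contexts[idx]
            b = len(idx)
            lr = cfg.learning_rate * max(1.0 - done / total_updates, 1e-4)
            U = w_in[c]
            Vo = w_out[o]
            g_pos = expit(np.einsum("bd,bd->b", U, Vo)) - 1.0
            dU = g_pos[:, None] * Vo
            np.add.at(w_out, o, -lr * g_pos[:, None] * U)
            if K > 0:
                negs = np.searchsorted(noise_cdf, rng.random((b, K)), side="right")
                Vn = w_out[negs]
                g_neg = expit(np.einsum("bd,bkd->bk", U, Vn))
                dU += np.einsum("bk,bkd->bd", g_neg, Vn)
                np.add.at(
                    w_out,
                    negs.ravel(),
                    (-lr * g_neg[..., None] * U[:, None, :]).reshape(-1, d),
                )
            np.add.at(w_in, c, -lr * dU)
            done += b
    return EmbeddingMatrix(node_ids=list(corpus.node_ids), vectors=w_in)


def softmax_conditional(vectors: np.ndarray, u_idx: int) -> np.ndarray:
    """Exact P(. | f(u)) over the vocabulary under the softmax model."""
    scores = vectors @ vectors[u_idx]
    scores -= scores.max()
    e = np.exp(scores)
    return e / e.sum()


def exact_softmax_loss(vectors: np.ndarray, corpus: WalkCorpus, window: int) -> float:
    """Exact negative log-likelihood of all windowed co-occurrence pairs.

    Small-vocabulary oracle for the objective that negative sampling
    approximates; O(V^2) per distinct center, so only for toy graphs.
    """
    from scipy.special import logsumexp

    centers, contexts = extract_pairs(corpus, window)
    loss = 0.0
    for u in np.unique(centers):
        mask = centers == u
        scores = vectors @ vectors[int(u)]
        logp = scores - logsumexp(scores)
        loss -= float(logp[contexts[mask]].sum())
    return loss


def write_word2vec(emb: EmbeddingMatrix, path: str | Path) -> None:
    """Write in word2vec text format: header 'N d', then 'id v1 ... vd'."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(emb.node_ids)} {emb.dim}\n")
        for node, vec in zip(emb.node_ids, emb.vectors):
            fh.write(node + " " + " ".join(f"{x:.17g}" for x in vec) + "\n")


def read_word2vec(path: str | Path) -> EmbeddingMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        n, d = int(header[0]), int(header[1])
        node_ids: list[str] = []
        vectors = np.empty((n, d))
        for i in range(n):
            fields = fh.readline().rstrip("\n").split(" ")
            node_ids.append(fields[0])
            vectors[i] = [float(x) for x in fields[1 : d + 1]]
    return EmbeddingMatrix(node_ids=node_ids, vectors=vectors)
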