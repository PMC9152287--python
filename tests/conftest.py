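"""Shared fixtures: small graphs, the synthetic benchmark, and a memoized
experiment runner so pipeline results are computed once per condition."""

from __future__ import annotations

import numpy as np
import pytest

import mirdisc as md
from mirdisc.graphs import AdjacencyView

# Benchmark-scale embedding/training sizes used by the heavier pipeline
# tests (library defaults stay at the full-scale values).
EMBED_PARAMS = dict(dim=32, num_walks=4, walk_length=40, window=5, epochs=3)
ENCODER_PARAMS = dict(epochs=15, patience=4, batch_size=64)


def embed_dataset(sim, bip, seed: int) -> md.FeatureTable:
    emb_sim = md.Node2Vec(random_state=seed, **EMBED_PARAMS).fit_transform(sim)
    emb_int = md.Node2Vec(random_state=seed + 1, **EMBED_PARAMS).fit_transform(bip)
    return md.fuse_features(emb_sim, emb_int, md.mirna_universe(sim, bip))


@pytest.fixture(scope="session")
def benchmark_dataset():
    return md.generate_dataset(md.default_benchmark())


@pytest.fixture(scope="session")
def benchmark_features(benchmark_dataset):
    sim, bip, labels = benchmark_dataset
    return embed_dataset(sim, bip, seed=1), labels


@pytest.fixture(scope="session")
def experiment_cache():
    """Memoized run_experiment keyed by (dataset tag, condition)."""
    cache: dict = {}

    def run(tag, features, labels, **kw):
        key = (tag, tuple(sorted(kw.items())))
        if key not in cache:
            cfg = md.ExperimentConfig(encoder_params=dict(ENCODER_PARAMS), **kw)
            cache[key] = md.run_experiment(features, labels, cfg)
        return cache[key]

    return run


@pytest.fixture
def small_adjacency():
    """4-node graph: prev-curr, curr-a, curr-b, prev-a (b not adjacent to prev)."""
    W = np.zeros((4, 4))
    for i, j in [(0, 1), (1, 2), (1, 3), (0, 2)]:
        W[i, j] = W[j, i] = 1.0
    net = md.SimilarityNetwork(["prev", "curr", "a", "b"], W)
    return AdjacencyView.from_similarity(net)


def brute_force_roc_auc(y, scores):
    """All-pairs Mann-Whitney count: (#{pos>neg} + 0.5 #{ties}) / (P*N)."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def hand_average_precision(y, scores):
    """AP = sum_k (R_k - R_{k-1}) P_k over descending score thresholds."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    yy = y[order]
    P = yy.sum()
    tp, ap, prev_r = 0, 0.0, 0.0
    for k, lab in enumerate(yy, start=1):
        tp += lab
        r = tp / P
        ap += (r - prev_r) * (tp / k)
        prev_r = r
    return ap
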