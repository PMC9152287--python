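"""Synthetic datasets with the structure the method assumes.

The guilt-by-association premise is that disease miRNAs form a
functional-similarity community and regulate overlapping target genes.
The generator plants exactly that: a block of elevated similarity among
the positive miRNAs over a low-similarity background, plus a shared gene
pool that positives preferentially target. Noise is generated on the
upper triangle and mirrored, so emitted matrices are exactly symmetric.

The default benchmark mimics the real resources' scale: ~500 miRNAs with
~100 positives (the similarity matrix side), a few thousand genes, and a
fraction of miRNAs present in only one network so zero-padding is
exercised. It does not attempt to match real degree distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .graphs import (
    BipartiteNetwork,
    ConfigurationError,
    LabelSet,
    SimilarityNetwork,
    write_edges,
    write_labels,
    write_similarity,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; similarity values are on the same [0, 1] scale the
    walker consumes.

    ``share_prob`` is the probability that a positive miRNA's target is
    drawn from the shared pool (setting it to ``shared_target_pool /
    n_gene`` removes the interaction signal; setting ``sim_within ==
    sim_background`` removes the similarity signal).
    """

    n_mirna: int = 500
    n_gene: int = 2000
    n_pos: int = 100
    sim_within: float = 0.6
    sim_background: float = 0.15
    sim_noise: float = 0.05
    targets_per_mirna: int = 40
    shared_target_pool: int = 200
    share_prob: float = 0.7
    missing_frac: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 <= self.sim_background <= self.sim_within <= 1):
            raise ValueError("need 0 <= sim_background <= sim_within <= 1")
        if self.n_pos >= self.n_mirna:
            raise ValueError("n_pos must be smaller than n_mirna")
        if not 0 <= self.share_prob <= 1:
            raise ValueError("share_prob must be in [0, 1]")
        if self.targets_per_mirna > self.n_gene:
            raise ConfigurationError("targets_per_mirna cannot exceed n_gene")
        if self.shared_target_pool > self.n_gene:
            raise ConfigurationError("shared_target_pool cannot exceed n_gene")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must be in [0, 1)")


def default_benchmark() -> SyntheticConfig:
    """The standard fixture: 500 miRNAs, 100 positives, planted block +
    shared-target signal, 10% of miRNAs present in only one network."""
    return SyntheticConfig()


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[SimilarityNetwork, BipartiteNetwork, LabelSet]:
    """Emit the three resources; fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    mirnas = [f"hsa-miR-synth-{i + 1}" for i in range(cfg.n_mirna)]
    genes = [f"G{i + 1:06d}" for i in range(cfg.n_gene)]
    pos_idx = np.sort(rng.choice(cfg.n_mirna, size=cfg.n_pos, replace=False))
    positives = {mirnas[i] for i in pos_idx}

    # similarity: block means + mirrored upper-triangle noise, clipped, unit diag
    n = cfg.n_mirna
    sim = np.full((n, n), cfg.sim_background)
    sim[np.ix_(pos_idx, pos_idx)] = cfg.sim_within
    noise = rng.normal(0.0, cfg.sim_noise, size=(n, n))
    upper = np.triu(noise, k=1)
    sim = sim + upper + upper.T
    sim = np.clip(sim, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)

    # targets: positives draw from the shared pool with share_prob
    pool = np.arange(cfg.shared_target_pool)
    edges: set[tuple[str, str]] = set()
    is_pos = np.zeros(n, dtype=bool)
    is_pos[pos_idx] = True
    for i, mirna in enumerate(mirnas):
        if is_pos[i]:
            n_shared = int(rng.binomial(cfg.targets_per_mirna, cfg.share_prob))
            n_shared = min(n_shared, cfg.shared_target_pool)
            shared = rng.choice(pool, size=n_shared, replace=False)
            rest_pool = np.setdiff1d(np.arange(cfg.n_gene), shared, assume_unique=False)
            rest = rng.choice(rest_pool, size=cfg.targets_per_mirna - n_shared, replace=False)
            targets = np.concatenate([shared, rest])
        else:
            targets = rng.choice(cfg.n_gene, size=cfg.targets_per_mirna, replace=False)
        for g in targets:
            edges.add((mirna, genes[g]))

    # remove missing_frac of miRNAs from exactly one network each
    n_missing = int(round(cfg.missing_frac * n))
    missing = rng.choice(n, size=n_missing, replace=False)
    drop_from_sim = rng.random(n_missing) < 0.5
    sim_keep = np.ones(n, dtype=bool)
    bip_drop: set[str] = set()
    for j, i in enumerate(missing):
        if drop_from_sim[j]:
            sim_keep[i] = False
        else:
            bip_drop.add(mirnas[i])

    keep_idx = np.flatnonzero(sim_keep)
    sim_net = SimilarityNetwork(
        node_ids=[mirnas[i] for i in keep_idx],
        weights=sim[np.ix_(keep_idx, keep_idx)],
    )
    kept_edges = {(m, g) for m, g in edges if m not in bip_drop}
    mirna_order = [m for m in mirnas if m not in bip_drop]
    gene_order = sorted({g for _, g in kept_edges})
    bip_net = BipartiteNetwork(mirna_ids=mirna_order, gene_ids=gene_order, edges=kept_edges)
    label_set = LabelSet(positives=positives, universe=set(mirnas))
    return sim_net, bip_net, label_set


def write_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the three input files the readers consume; byte-identical for
    identical configs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_net, bip_net, label_set = generate_dataset(cfg)
    paths = {
        "similarity": out / "similarity.tsv",
        "interactions": out / "interactions.tsv",
        "labels": out / "positives.txt",
    }
    write_similarity(sim_net, paths["similarity"])
    write_edges(bip_net, paths["interactions"])
    write_labels(label_set.positives, paths["labels"])
    return paths


def null_config(base: SyntheticConfig | None = None) -> SyntheticConfig:
    """Signal-free variant of ``base``: flat similarity and background-rate
    target sharing, for permutation-style sanity checks."""
    base = base or default_benchmark()
    return replace(
        base,
        sim_within=base.sim_background,
        share_prob=base.shared_target_pool / base.n_gene,
    )
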