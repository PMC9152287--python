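"""Network containers and readers for the three tabular inputs.

The prediction task consumes three resources:

* a symmetric miRNA functional-similarity matrix (MISIM-style), read into a
  :class:`SimilarityNetwork` whose edge weights bias the random walk;
* a miRNA->mRNA interaction edge list (mirTarBase-style), read into a
  :class:`BipartiteNetwork` that is walked as a single homogeneous
  unweighted undirected graph;
* a list of disease-associated miRNA identifiers (HMDD-style), read into a
  :class:`LabelSet` of positives inside the universe of known miRNAs.

Identifiers are matched across resources case-insensitively after trimming
whitespace; no precursor/mature (-5p/-3p) mapping is attempted.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-9


class FormatError(ValueError):
    """Raised when an input file violates its declared tabular shape."""


class ConfigurationError(ValueError):
    """Raised when inputs are well-formed but the requested run is impossible."""


def normalize_id(raw: str) -> str:
    """Canonical matching key for an identifier: trimmed, case-folded."""
    return raw.strip().casefold()


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


@dataclass
class SimilarityNetwork:
    """Weighted undirected miRNA graph given by a symmetric similarity matrix.

    Parameters
    ----------
    node_ids:
        Ordered miRNA identifiers (input order; downstream runs are
        reproducible because this order is deterministic).
    weights:
        ``(n, n)`` symmetric matrix of similarity scores in ``[0, 1]``.
        The diagonal (self-similarity) is ignored for walks: no self-loops.
    """

    node_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise FormatError(
                f"similarity matrix is {self.weights.shape}, expected ({n}, {n})"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("similarity matrix contains non-finite entries")
        if np.any(self.weights < 0):
            raise ValueError("similarity matrix contains negative entries")
        asym = np.abs(self.weights - self.weights.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            logger.warning(
                "similarity matrix asymmetric (max |A - A.T| = %.3g); symmetrizing by averaging",
                asym,
            )
            self.weights = (self.weights + self.weights.T) / 2.0

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def walkable_edges(self, threshold: float = 0.0) -> int:
        """Number of off-diagonal edges with weight above ``threshold``."""
        w = self.weights.copy()
        np.fill_diagonal(w, 0.0)
        return int(np.count_nonzero(np.triu(w) > threshold))


@dataclass
class BipartiteNetwork:
    """Unweighted miRNA-gene interaction graph.

    Stored as a bipartite edge set but embedded as a single homogeneous
    unweighted undirected graph (node types are ignored during walks; only
    miRNA vectors are kept downstream).
    """

    mirna_ids: list[str]
    gene_ids: list[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        mirnas = set(self.mirna_ids)
        genes = set(self.gene_ids)
        for m, g in self.edges:
            if m not in mirnas or g not in genes:
                raise ValueError(f"edge ({m}, {g}) references an unknown node")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def degree(self, mirna: str) -> int:
        return sum(1 for m, _ in self.edges if m == mirna)


@dataclass
class LabelSet:
    """Positive (disease-associated) miRNAs within the known universe."""

    positives: set[str]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.positives <= self.universe:
            raise ValueError("positives must be a subset of the universe")

    @property
    def unlabeled(self) -> set[str]:
        return self.universe - self.positives


def load_similarity_matrix(
    path: str | Path, delimiter: str | None = None
) -> SimilarityNetwork:
    """Read a similarity matrix with a header row and a label column.

    The header ids and the first-column ids must agree (same order, matched
    case-insensitively). Asymmetry beyond ``1e-9`` is repaired by averaging
    with a logged warning; negative or non-numeric entries raise.
    """
    if delimiter is None:
        delimiter = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"similarity matrix is {df.shape[0]}x{df.shape[1]}, not square")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if [normalize_id(r) for r in rows] != [normalize_id(c) for c in cols]:
        raise FormatError("row labels do not match column labels")
    try:
        weights = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric entry in similarity matrix: {exc}") from exc
    return SimilarityNetwork(node_ids=[r.strip() for r in rows], weights=weights)


def write_similarity(net: SimilarityNetwork, path: str | Path, delimiter: str = "\t") -> None:
    """Write the matrix in the same header + label-column layout it is read from."""
    df = pd.DataFrame(net.weights, index=net.node_ids, columns=net.node_ids)
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def load_interaction_edges(path: str | Path) -> BipartiteNetwork:
    """Read a two-column miRNA<TAB>gene edge list; '#' lines are comments.

    Duplicate interactions are collapsed; distinct miRNA/gene counts are
    logged. A data line with a field count other than two raises a
    :class:`FormatError` carrying the offending line number.
    """
    mirna_order: dict[str, str] = {}
    gene_order: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()
    n_lines = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 fields, found {len(fields)}"
                )
            n_lines += 1
            m_raw, g_raw = fields[0].strip(), fields[1].strip()
            m = mirna_order.setdefault(normalize_id(m_raw), m_raw)
            g = gene_order.setdefault(normalize_id(g_raw), g_raw)
            edges.add((m, g))
    net = BipartiteNetwork(
        mirna_ids=list(mirna_order.values()),
        gene_ids=list(gene_order.values()),
        edges=edges,
    )
    logger.info(
        "read %d interaction lines: %d unique edges, %d distinct miRNAs, %d distinct genes",
        n_lines, len(edges), net.n_mirnas, net.n_genes,
    )
    return net


def write_edges(net: BipartiteNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m, g in sorted(net.edges):
            fh.write(f"{m}\t{g}\n")


def load_labels(path: str | Path, universe: Iterable[str]) -> LabelSet:
    """Read one positive miRNA id per line and intersect with the universe.

    Ids absent from the universe are dropped with a warning carrying the
    count; duplicates are collapsed. An empty positive set after the
    intersection raises a :class:`ConfigurationError`.
    """
    key_to_canonical = {normalize_id(u): u for u in universe}
    positives: set[str] = set()
    dropped = 0
    with _open_text(path) as fh:
        for line in fh:
            raw = line.strip()
            if not raw or raw.startswith("#"):
                continue
            key = normalize_id(raw)
            if key in key_to_canonical:
                positives.add(key_to_canonical[key])
            else:
                dropped += 1
    if dropped:
        logger.warning("%d label ids not found in the miRNA universe; dropped", dropped)
    if not positives:
        raise ConfigurationError("no positive miRNA remains after intersecting with the universe")
    return LabelSet(positives=positives, universe=set(key_to_canonical.values()))


def write_labels(labels: Sequence[str] | set[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in sorted(labels):
            fh.write(f"{m}\n")


@dataclass
class AdjacencyView:
    """Flat array adjacency used by the random walker.

    ``neighbors[i]`` holds the (sorted) neighbor indices of node ``i`` and
    ``weights[i]`` the matching edge weights. Built once per graph; the
    second-order walk bias needs O(log deg) adjacency checks against the
    previous node, served by ``np.searchsorted`` on the sorted arrays.
    """

    node_ids: list[str]
    neighbors: list[np.ndarray] = field(repr=False)
    weights: list[np.ndarray] = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        if not hasattr(self, "_index"):
            self._index = {normalize_id(n): i for i, n in enumerate(self.node_ids)}
        return self._index[normalize_id(node_id)]

    def has_edge(self, i: int, j: int) -> bool:
        nb = self.neighbors[i]
        pos = np.searchsorted(nb, j)
        return pos < len(nb) and nb[pos] == j

    @classmethod
    def from_similarity(
        cls, net: SimilarityNetwork, threshold: float = 0.0
    ) -> "AdjacencyView":
        """Dense similarity graph; zero-weight pairs carry zero transition
        probability so they are simply absent. ``threshold`` optionally prunes
        weak edges (off by default: weights only bias the walk)."""
        w = net.weights.copy()
        np.fill_diagonal(w, 0.0)
        neighbors, weights = [], []
        for i in range(net.n_nodes):
            nb = np.flatnonzero(w[i] > threshold)
            neighbors.append(nb.astype(np.int64))
            weights.append(w[i, nb].astype(float))
        return cls(node_ids=list(net.node_ids), neighbors=neighbors, weights=weights)

    @classmethod
    def from_bipartite(cls, net: BipartiteNetwork) -> "AdjacencyView":
        """Homogeneous unweighted view: miRNA nodes first, then gene nodes."""
        node_ids = list(net.mirna_ids) + list(net.gene_ids)
        index = {normalize_id(n): i for i, n in enumerate(node_ids)}
        adj: list[list[int]] = [[] for _ in node_ids]
        for m, g in net.edges:
            mi, gi = index[normalize_id(m)], index[normalize_id(g)]
            adj[mi].append(gi)
            adj[gi].append(mi)
        neighbors = [np.array(sorted(a), dtype=np.int64) for a in adj]
        weights = [np.ones(len(a), dtype=float) for a in adj]
        return cls(node_ids=node_ids, neighbors=neighbors, weights=weights)
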