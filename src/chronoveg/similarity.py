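"""Bray-Curtis similarity, UPGMA clustering, cophenetic fit, branch support.

Similarity between two abundance vectors is the quantitative Sorensen form

    BC(x, y) = 2 * sum_i min(x_i, y_i) / (sum x + sum y)

computed here on pooled per-site densities. The UPGMA dendrogram is built on
the distance view 1 - BC with unweighted average linkage: the distance
between two clusters is the arithmetic mean of all cross-pair leaf
distances, which admits the size-weighted Lance-Williams update used below.
Tree fit is summarized by the cophenetic correlation (Pearson r between
original and tree-implied distances), and node stability by a species-level
bootstrap: columns of the abundance matrix are resampled with replacement,
the tree is rebuilt, and each internal node is scored by the percentage of
replicate trees containing the same leaf bipartition.

UPGMA is implemented in-package to pin the tie-breaking rule (ties on the
minimum distance are resolved toward the lexicographically smallest label
pair); agreement with an independent average-linkage implementation is part
of the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .inventory import AbundanceMatrix

logger = logging.getLogger(__name__)


def bray_curtis(x, y) -> float:
    """Bray-Curtis similarity in [0, 1] between two abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise DomainError("abundances must be non-negative")
    if x.sum() <= 0 or y.sum() <= 0:
        raise DomainError("Bray-Curtis undefined for an all-zero vector")
    return float(2.0 * np.minimum(x, y).sum() / (x.sum() + y.sum()))


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity with unit diagonal over site labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise DomainError("similarity matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise DomainError("similarity matrix must be symmetric")
        self.values = v

    @property
    def distance(self) -> np.ndarray:
        """Distance view 1 - similarity with an exactly zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def similarity_matrix(abund: AbundanceMatrix) -> SimilarityMatrix:
    """Pairwise Bray-Curtis similarity over the pooled site rows."""
    n = len(abund.site_labels)
    if n < 2:
        raise DomainError("need at least two sites for a similarity matrix")
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = bray_curtis(abund.values[i], abund.values[j])
    return SimilarityMatrix(labels=list(abund.site_labels), values=values)


@dataclass
class Dendrogram:
    """Binary UPGMA merge tree over site labels.

    ``merges`` lists (left_leafset, right_leafset, height) in merge order;
    leaf sets are frozensets of labels and heights are on the distance
    scale. ``support`` maps internal-node leaf sets to bootstrap percentages
    (leaves are 100 by convention); ``cophenetic_r`` is filled by
    :func:`cophenetic_correlation`.
    """

    labels: list[str]
    merges: list[tuple[frozenset, frozenset, float]]
    support: dict[frozenset, float] = field(default_factory=dict)
    cophenetic_r: float | None = None

    @property
    def clades(self) -> list[frozenset]:
        """Leaf sets of internal nodes, smallest to largest."""
        return [a | b for a, b, _ in self.merges]

    def cophenetic_matrix(self) -> np.ndarray:
        """Tree-implied distances: pair (i, j) gets the height of the merge
        that first places i and j in one cluster."""
        n = len(self.labels)
        idx = {lab: i for i, lab in enumerate(self.labels)}
        c = np.zeros((n, n))
        for a, b, h in self.merges:
            for la in a:
                for lb in b:
                    c[idx[la], idx[lb]] = c[idx[lb], idx[la]] = h
        return c

    def to_newick(self, *, with_support: bool = True) -> str:
        """Newick string with merge-height branch lengths; internal nodes
        carry bootstrap support as labels when available."""
        node_height: dict[frozenset, float] = {frozenset([l]): 0.0 for l in self.labels}
        node_str: dict[frozenset, str] = {
            frozenset([l]): l.replace(" ", "_") for l in self.labels
        }
        for a, b, h in self.merges:
            merged = a | b
            parts = []
            for child in (a, b):
                # branch length: parent height minus child height (heights
                # are merge distances; leaves sit at 0)
                parts.append(f"{node_str[child]}:{(h - node_height[child]) / 2:.6g}")
            label = ""
            if with_support and merged in self.support:
                label = f"{self.support[merged]:.0f}"
            node_str[merged] = f"({','.join(sorted(parts))}){label}"
            node_height[merged] = h
        root = frozenset(self.labels)
        return node_str[root] + ";"


def _lex_key(cluster: frozenset) -> tuple:
    return tuple(sorted(cluster))


def upgma(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a symmetric distance matrix.

    At each step the closest pair of clusters merges at its current
    distance; the distance from the merged cluster to any other is the
    size-weighted mean (n_a * d_a + n_b * d_b) / (n_a + n_b), i.e., the
    unweighted arithmetic mean over all cross leaf pairs. Equal minimum
    distances are resolved toward the lexicographically smallest label pair.
    """
    d = np.asarray(dist, dtype=float)
    n = len(labels)
    if n < 2:
        raise DomainError("need at least two labels")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise DomainError("distance matrix must be square and symmetric")

    clusters: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dd = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[frozenset, frozenset, float]] = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for (i, j), v in dd.items():
            key = (v, min(_lex_key(clusters[i]), _lex_key(clusters[j])),
                   max(_lex_key(clusters[i]), _lex_key(clusters[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = dd[(i, j)]
        a, b = clusters[i], clusters[j]
        merges.append((a, b, h))
        new = next_id
        next_id += 1
        del dd[(i, j)]
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dd.pop((min(i, k), max(i, k)))
            djk = dd.pop((min(j, k), max(j, k)))
            dd[(min(new, k), max(new, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        clusters[new] = a | b
        sizes[new] = sizes[i] + sizes[j]
        for k in (i, j):
            del clusters[k], sizes[k]
    return Dendrogram(labels=list(labels), merges=merges)


def cophenetic_correlation(tree: Dendrogram, dist: np.ndarray) -> float:
    """Pearson r between original and cophenetic distances over all pairs.

    Reported as a magnitude (tree distances and input distances are
    positively oriented by construction). Requires at least three labels.
    """
    n = len(tree.labels)
    if n < 3:
        raise DomainError("cophenetic correlation undefined for fewer than 3 labels")
    c = tree.cophenetic_matrix()
    iu = np.triu_indices(n, 1)
    x, y = np.asarray(dist)[iu], c[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    tree.cophenetic_r = abs(r)
    return abs(r)


def branch_support(
    abund: AbundanceMatrix, n_reps: int = 9999, seed: int | None = None
) -> dict[frozenset, float]:
    """Bootstrap node support from species-column resampling.

    Each replicate draws species columns with replacement, rebuilds the
    Bray-Curtis + UPGMA tree, and checks which original internal-node leaf
    bipartitions recur; support is the recurrence percentage. Replicates
    leaving any site with an all-zero vector are redrawn (and counted in the
    log). Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise DomainError("need at least one replicate")
    rng = np.random.default_rng(seed)
    base = upgma(similarity_matrix(abund).distance, abund.site_labels)
    clades = base.clades
    hits = {c: 0 for c in clades}
    n_species = len(abund.species_names)
    redraws = 0
    for _ in range(n_reps):
        while True:
            cols = rng.integers(0, n_species, size=n_species)
            vals = abund.values[:, cols]
            if (vals.sum(axis=1) > 0).all():
                break
            redraws += 1
        rep = AbundanceMatrix(
            site_labels=list(abund.site_labels),
            species_names=[abund.species_names[c] for c in cols],
            values=vals,
        )
        rep_tree = upgma(similarity_matrix(rep).distance, rep.site_labels)
        rep_clades = set(rep_tree.clades)
        for c in clades:
            if c in rep_clades:
                hits[c] += 1
    if redraws:
        logger.info("redrew %d degenerate bootstrap replicates", redraws)
    support = {c: 100.0 * hits[c] / n_reps for c in clades}
    base.support = support
    return support
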