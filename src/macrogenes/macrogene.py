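"""Macrogene construction: protein-embedding clustering and gene weights.

A *macrogene* is a learned group of intra- and inter-species genes.  The
space is initialized by k-means clustering of the stacked protein embeddings;
each centroid becomes a macrogene, and every gene is connected to every
macrogene with a strictly positive weight that decays with the gene's rank
distance to the centroid:

    W[g, m] = 2 * (ln(1 / rd[m, g] + 1))**2

where ``rd[m, g] = 1`` for the gene nearest to macrogene ``m``.  The factor
2 puts the largest weight near 1 (2 * ln(2)^2 ≈ 0.961).  Logs are natural.

A cell's macrogene expression aggregates its counts through the species'
weight block:  e_c = ReLU(LayerNorm(W_s^T log(X_c + 1))).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .config import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "MacrogeneModel",
    "cluster_protein_embeddings",
    "rank_distances",
    "weight_from_rank",
    "initialize_weights",
    "macrogene_expression",
    "top_genes",
    "species_specific_fraction",
]


@dataclass
class MacrogeneModel:
    """Centroids, gene-to-macrogene weights and the gene row index."""

    centroids: np.ndarray       # N_M × p
    weights: np.ndarray         # |G| × N_M, strictly positive
    rank_distance: np.ndarray   # |G| × N_M, each column a permutation of 1..|G|
    gene_index: list            # row -> (species_id, gene_id)

    def __post_init__(self):
        self.gene_index = [(str(s), str(g)) for s, g in self.gene_index]
        if self.weights.shape[0] != len(self.gene_index):
            raise ValueError("one weight row per gene is required")
        if (self.weights < 0).any():
            raise ValueError("macrogene weights must be nonnegative")

    @property
    def n_macrogenes(self) -> int:
        return self.weights.shape[1]

    @property
    def species_ids(self) -> list:
        seen = dict.fromkeys(s for s, _ in self.gene_index)
        return list(seen)

    def species_slice(self, species_id: str) -> slice:
        rows = [i for i, (s, _) in enumerate(self.gene_index) if s == species_id]
        if not rows:
            raise KeyError(f"species {species_id!r} has no genes in the weight matrix")
        start, stop = rows[0], rows[-1] + 1
        if rows != list(range(start, stop)):  # rows are contiguous by construction
            raise ValueError(f"gene rows for species {species_id!r} are not contiguous")
        return slice(start, stop)

    def species_block(self, species_id: str) -> np.ndarray:
        """The |G_s| × N_M weight block for one species."""
        return self.weights[self.species_slice(species_id)]

    def with_weights(self, weights: np.ndarray) -> "MacrogeneModel":
        return MacrogeneModel(self.centroids, np.asarray(weights, dtype=float),
                              self.rank_distance, self.gene_index)


def cluster_protein_embeddings(P: np.ndarray, n_macrogenes: int, seed: int) -> np.ndarray:
    """Seeded k-means over gene protein embeddings; returns the centroids.

    Lloyd iterations with k-means++ initialization, max 300 iterations,
    relative tolerance 1e-4 on the within-cluster sum of squares.
    """
    P = np.asarray(P, dtype=np.float64)
    if not np.isfinite(P).all():
        raise ValueError("protein embeddings contain non-finite entries")
    if n_macrogenes > P.shape[0]:
        raise ConfigurationError(
            f"num_macrogenes={n_macrogenes} exceeds the number of genes ({P.shape[0]})"
        )
    km = KMeans(
        n_clusters=n_macrogenes,
        init="k-means++",
        n_init=1,
        max_iter=300,
        tol=1e-4,
        random_state=int(seed) % (2**31),
    ).fit(P)
    logger.info("k-means objective (within-cluster sum of squares): %.6g", km.inertia_)
    return km.cluster_centers_.astype(np.float64)


def rank_distances(P: np.ndarray, centroids: np.ndarray, gene_ids: list) -> np.ndarray:
    """Per-macrogene Euclidean-distance ranks of all genes (1 = nearest).

    Distance ties are broken by gene-id lexicographic order, so each column
    of the result is a deterministic permutation of 1..|G|.
    """
    P = np.asarray(P, dtype=np.float64)
    d2 = ((P[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2) if P.shape[0] * centroids.shape[0] < 2_000_000 else None
    if d2 is None:
        # memory-lean expansion for large problems
        d2 = (P**2).sum(1)[:, None] - 2 * P @ centroids.T + (centroids**2).sum(1)[None, :]
    gene_order = np.argsort(np.array(gene_ids, dtype=object), kind="stable")
    lex_rank = np.empty(len(gene_ids), dtype=int)
    lex_rank[gene_order] = np.arange(len(gene_ids))

    rd = np.empty(d2.shape, dtype=np.int64)
    for m in range(centroids.shape[0]):
        order = np.lexsort((lex_rank, d2[:, m]))
        rd[order, m] = np.arange(1, len(gene_ids) + 1)
    return rd


def weight_from_rank(rd) -> np.ndarray:
    """The initialization map rd → 2·(ln(1/rd + 1))²; strictly positive.

    Evaluated as log1p(1/rd) so the map stays strictly decreasing even at
    very large ranks where 1/rd underflows the naive form's precision.
    """
    rd = np.asarray(rd, dtype=np.float64)
    return 2.0 * np.log1p(1.0 / rd) ** 2


def initialize_weights(P: np.ndarray, centroids: np.ndarray,
                       gene_index: list) -> MacrogeneModel:
    """Build the initial :class:`MacrogeneModel` from embeddings and centroids."""
    gene_ids = [f"{s}::{g}" for s, g in gene_index]  # species-qualified, unique
    rd = rank_distances(P, centroids, gene_ids)
    return MacrogeneModel(
        centroids=np.asarray(centroids, dtype=np.float64),
        weights=weight_from_rank(rd),
        rank_distance=rd,
        gene_index=gene_index,
    )


def macrogene_expression(
    X: np.ndarray,
    W_s: np.ndarray,
    gamma: np.ndarray | None = None,
    beta: np.ndarray | None = None,
    eps: float = 1e-5,
) -> np.ndarray:
    """Aggregate raw counts into macrogene expression values.

    e = ReLU(LayerNorm(log1p(X) @ W_s)) with learnable affine LayerNorm
    parameters (defaults gamma=1, beta=0).  Rows of ``X`` are cells; output
    entries are always >= 0 so genes contribute positively or not at all.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != W_s.shape[0]:
        raise ValueError(f"cell has {X.shape[1]} genes but the species block has {W_s.shape[0]} rows")
    h = np.log1p(X) @ W_s
    mu = h.mean(axis=1, keepdims=True)
    var = h.var(axis=1, keepdims=True)
    h = (h - mu) / np.sqrt(var + eps)
    if gamma is not None:
        h = h * np.asarray(gamma)
    if beta is not None:
        h = h + np.asarray(beta)
    return np.maximum(h, 0.0)


def top_genes(model: MacrogeneModel, macrogene_id: int, per_species_k: int) -> dict:
    """Highest-weighted genes of one macrogene, ranked per species.

    Ties are broken by gene-id lexicographic order.  Used to interpret (and
    name) macrogenes.
    """
    if not 0 <= macrogene_id < model.n_macrogenes:
        raise KeyError(f"unknown macrogene id {macrogene_id}")
    if per_species_k < 1:
        raise ConfigurationError("per_species_k must be >= 1")
    col = model.weights[:, macrogene_id]
    out: dict[str, list] = {}
    for sid in model.species_ids:
        sl = model.species_slice(sid)
        entries = [(model.gene_index[i][1], col[i]) for i in range(sl.start, sl.stop)]
        entries.sort(key=lambda t: (-t[1], t[0]))
        out[sid] = entries[:per_species_k]
    return out


def species_specific_fraction(model: MacrogeneModel, macrogene_ids,
                              threshold: float = 0.5) -> float:
    """Fraction of the listed macrogenes whose above-threshold weights all
    belong to genes of a single species.

    A macrogene with no weight above the threshold is not counted as
    single-species (it contributes 0).
    """
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    macrogene_ids = list(macrogene_ids)
    if not macrogene_ids:
        raise ValueError("macrogene_ids must be nonempty")
    species = np.array([s for s, _ in model.gene_index], dtype=object)
    single = 0
    for m in macrogene_ids:
        above = model.weights[:, m] > threshold
        hit_species = set(species[above])
        if len(hit_species) == 1:
            single += 1
    return single / len(macrogene_ids)
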