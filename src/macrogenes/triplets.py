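"""Weakly supervised triplet metric learning across species.

Fine-tuning aligns species in the latent space using only *within-species*
annotations — labels are never compared across species.  Per epoch:

1. recompute evaluation-mode embeddings for all cells;
2. mine candidate anchor/positive pairs per (species, annotation) group via
   mutual cross-species 1-nearest neighbors under cosine distance, with the
   label back-check: anchor x (species s1) selects its nearest cross-species
   neighbor y; y's nearest neighbor x' back in s1 must share x's annotation;
3. pool the verified positives per group and match every anchor candidate
   with a seeded-uniform positive from a different species;
4. draw one negative per pair, uniform over cells whose label differs from
   both the anchor's and the positive's labels;
5. keep semihard triplets, D(a,p) < D(a,n) < D(a,p) + margin (strict);
6. minimize the mean triplet margin loss over the surviving triplets,
   updating encoder parameters only — the gene-to-macrogene weights and the
   decoder are frozen.

Distances are cosine distances, D = 1 - cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from . import nn
from .datatypes import SpeciesDataset
from .model import CellEmbeddingSet, ZinbAutoencoder

logger = logging.getLogger(__name__)

__all__ = [
    "TripletBatch",
    "cosine_distance_matrix",
    "mutual_nn_candidates",
    "mine_positive_pairs",
    "select_negatives",
    "semihard_filter",
    "triplet_loss",
    "finetune",
]


@dataclass
class TripletBatch:
    """(anchor, positive, negative) cell indices into a CellEmbeddingSet."""

    anchors: np.ndarray
    positives: np.ndarray
    negatives: np.ndarray
    margin: float = 0.2

    def __len__(self) -> int:
        return len(self.anchors)

    def subset(self, keep: np.ndarray) -> "TripletBatch":
        return TripletBatch(self.anchors[keep], self.positives[keep],
                            self.negatives[keep], self.margin)


def _normalize_rows(Z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return Z / norms


def cosine_distance_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances 1 - cos(a, b)."""
    return 1.0 - _normalize_rows(A) @ _normalize_rows(B).T


def mutual_nn_candidates(E: CellEmbeddingSet) -> dict:
    """Deterministic mutual-NN discovery, grouped by (species, annotation).

    Returns ``{(species, label): (anchor_candidates, verified_pairs)}`` where
    ``anchor_candidates`` is every cell of the group and ``verified_pairs``
    is the list of (x, y) passing the cross-species mutual-1-NN label
    back-check.  Nearest-neighbor ties break to the lowest cell index.
    """
    species_ids = list(dict.fromkeys(E.species))
    if len(species_ids) < 2:
        logger.warning("mutual-NN mining requires >= 2 species; returning no candidates")
        return {}
    Zn = _normalize_rows(E.embeddings)
    idx_of = {s: np.flatnonzero(E.species == s) for s in species_ids}

    # nearest cross-species neighbor of every cell, and nearest same-species
    # neighbor of every cell *from the perspective of another species' cell*
    out: dict = {}
    nn_cross = np.empty(E.n_cells, dtype=int)
    for s in species_ids:
        own = idx_of[s]
        others = np.flatnonzero(E.species != s)
        sim = Zn[own] @ Zn[others].T
        nn_cross[own] = others[np.argmax(sim, axis=1)]  # argmax: first max wins ties

    for s in species_ids:
        own = idx_of[s]
        for lab in dict.fromkeys(E.labels[own]):
            group = own[E.labels[own] == lab]
            pairs = []
            for x in group:
                y = nn_cross[x]
                # y's nearest neighbor back in species s
                sim_back = Zn[own] @ Zn[y]
                x_prime = own[np.argmax(sim_back)]
                if E.labels[x_prime] == lab:
                    pairs.append((int(x), int(y)))
            out[(s, lab)] = (group.copy(), pairs)
    return out


def mine_positive_pairs(E: CellEmbeddingSet, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Anchor/positive index arrays from pooled mutual-NN candidates.

    Within each (species, annotation) group, every anchor candidate is
    matched with a seeded-uniform verified positive candidate from a
    different species; groups with no verified candidate yield no pairs.
    """
    anchors, positives = [], []
    for (s, _lab), (group, pairs) in mutual_nn_candidates(E).items():
        if not pairs:
            continue
        pool = np.array(sorted({y for _, y in pairs}), dtype=int)
        pool = pool[E.species[pool] != s]  # cross-species by construction; keep explicit
        if pool.size == 0:
            continue
        choice = rng.integers(0, pool.size, size=len(group))
        anchors.extend(int(a) for a in group)
        positives.extend(int(p) for p in pool[choice])
    return np.array(anchors, dtype=int), np.array(positives, dtype=int)


def select_negatives(anchors: np.ndarray, positives: np.ndarray, labels: np.ndarray,
                     rng: np.random.Generator, margin: float = 0.2) -> TripletBatch:
    """One negative per pair, uniform over cells whose label differs from both
    the anchor's and the positive's labels; pairs without any eligible
    negative are dropped with a warning."""
    labels = np.asarray(labels, dtype=object)
    keep_a, keep_p, negs = [], [], []
    dropped = 0
    for a, p in zip(anchors, positives):
        eligible = np.flatnonzero((labels != labels[a]) & (labels != labels[p]))
        if eligible.size == 0:
            dropped += 1
            continue
        negs.append(int(eligible[rng.integers(0, eligible.size)]))
        keep_a.append(int(a))
        keep_p.append(int(p))
    if dropped:
        logger.warning("dropped %d pair(s) with no eligible negative", dropped)
    return TripletBatch(np.array(keep_a, dtype=int), np.array(keep_p, dtype=int),
                        np.array(negs, dtype=int), margin)


def semihard_filter(batch: TripletBatch, E: CellEmbeddingSet,
                    margin: float | None = None) -> TripletBatch:
    """Keep exactly the triplets with D(a,p) < D(a,n) < D(a,p) + margin (strict)."""
    m = batch.margin if margin is None else margin
    if len(batch) == 0:
        return batch
    Zn = _normalize_rows(E.embeddings)
    d_ap = 1.0 - np.einsum("ij,ij->i", Zn[batch.anchors], Zn[batch.positives])
    d_an = 1.0 - np.einsum("ij,ij->i", Zn[batch.anchors], Zn[batch.negatives])
    keep = (d_ap < d_an) & (d_an < d_ap + m)
    return batch.subset(np.flatnonzero(keep))


def triplet_loss(z_a: Tensor, z_p: Tensor, z_n: Tensor, margin: float) -> Tensor:
    """Mean triplet margin loss max(D(a,p) - D(a,n) + m, 0) on cosine distance.

    Inputs are row-aligned 2-D tensors of embeddings; zero rows are rejected
    (cosine distance undefined).
    """
    for z in (z_a, z_p, z_n):
        if (np.linalg.norm(z.data, axis=-1) == 0).any():
            raise ValueError("triplet loss is undefined for zero embedding vectors")
    d_ap = 1.0 - nn.cosine_rows(z_a, z_p)
    d_an = 1.0 - nn.cosine_rows(z_a, z_n)
    return (d_ap - d_an + margin).relu().mean()


def finetune(model: ZinbAutoencoder, datasets: list[SpeciesDataset],
             rng: np.random.Generator | None = None) -> tuple[CellEmbeddingSet, list]:
    """Metric-learning fine-tuning loop (see module docstring).

    Stops early (with a warning) after three consecutive epochs with zero
    surviving triplets.  Returns the final embeddings and per-epoch stats.
    """
    cfg = model.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % 2**31, 59]))
    opt = nn.Adam(model.encoder_parameters(), lr=cfg.finetune_learning_rate)

    offsets, start = {}, 0
    for ds in datasets:
        offsets[ds.species_id] = (start, ds)
        start += ds.n_cells

    history = []
    empty_streak = 0
    for epoch in range(cfg.finetune_epochs):
        E = model.embed_datasets(datasets)
        anchors, positives = mine_positive_pairs(E, rng)
        if anchors.size:
            batch = select_negatives(anchors, positives, E.labels, rng, cfg.margin)
            batch = semihard_filter(batch, E)
        else:
            batch = TripletBatch(np.empty(0, int), np.empty(0, int), np.empty(0, int), cfg.margin)
        history.append({"epoch": epoch, "mined": int(anchors.size), "semihard": len(batch)})
        logger.info("finetune epoch %d: %d mined, %d semihard", epoch, anchors.size, len(batch))
        if len(batch) == 0:
            empty_streak += 1
            if empty_streak >= 3:
                logger.warning("no semihard triplets for 3 consecutive epochs; stopping early")
                break
            continue
        empty_streak = 0
        for _ in range(cfg.triplet_steps_per_epoch):
            # forward every species' cells with grad, then gather triplet rows
            chunks = [model.embed(ds.counts, ds.species_id) for ds in datasets]
            from .autograd import concat as _concat
            Z = _concat(chunks, axis=0)
            loss = triplet_loss(Z[batch.anchors], Z[batch.positives],
                                Z[batch.negatives], cfg.margin)
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model.embed_datasets(datasets), history
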