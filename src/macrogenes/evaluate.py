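"""Scoring of cross-species integrations.

Three evaluations:

* **label transfer** — a multinomial logistic classifier is fit on one
  species' embeddings and annotations and scored on another species, where a
  prediction is correct iff the predicted reference label maps to the true
  query label under a predetermined cross-species cell-type mapping.  The
  attainable ceiling is the fraction of query cells whose label is mapped at
  all.
* **neighbor composition** — for each query cell type, the distribution of
  reference cell types among the k nearest cross-species neighbors (cosine
  distance).
* **homology recapture** — the fraction of macrogenes whose per-species
  top-k weighted genes contain at least one known homolog pair, against a
  matched random null (k genes sampled uniformly without replacement per
  species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support

from .datatypes import CellTypeMapping, HomologPairTable
from .macrogene import MacrogeneModel
from .model import CellEmbeddingSet
from .triplets import cosine_distance_matrix

__all__ = ["TransferReport", "RecaptureCurve", "label_transfer_score",
           "neighbor_composition", "homology_recapture_curve"]


@dataclass
class TransferReport:
    accuracies: list
    median_accuracy: float
    ceiling: float
    per_class: pd.DataFrame

    def __post_init__(self):
        if not 0 <= self.median_accuracy <= self.ceiling + 1e-12 <= 1 + 1e-12:
            raise ValueError("accuracy must lie in [0, ceiling] and ceiling in [0, 1]")


@dataclass
class RecaptureCurve:
    k_values: np.ndarray
    observed: np.ndarray
    null: np.ndarray

    def __post_init__(self):
        for name, curve in (("observed", self.observed), ("null", self.null)):
            if ((curve < -1e-12) | (curve > 1 + 1e-12)).any():
                raise ValueError(f"{name} proportions must lie in [0, 1]")
            if (np.diff(curve) < -1e-12).any():
                raise ValueError(f"{name} curve must be non-decreasing in k")


def label_transfer_score(E: CellEmbeddingSet, train_species, test_species,
                         mapping: CellTypeMapping, runs: int = 1, seed: int = 0,
                         mode: str = "classifier_seed") -> TransferReport:
    """Median cross-species label-transfer accuracy over seeded classifier runs.

    ``mode="classifier_seed"`` refits the (stochastically solved) classifier
    with a different random state per run; ``mode="subsample"`` additionally
    bootstraps the training set.  Test-species labels are only ever used for
    scoring, never for fitting.
    """
    if len(mapping) == 0:
        raise ValueError("the cell-type mapping is empty")
    train_idx = np.flatnonzero(E.species == train_species)
    test_idx = np.flatnonzero(E.species == test_species)
    if train_idx.size == 0 or test_idx.size == 0:
        raise ValueError("both species must be present in the embedding set")

    X_train = E.embeddings[train_idx]
    y_train = E.labels[train_idx].astype(str)
    X_test = E.embeddings[test_idx]
    y_test = E.labels[test_idx].astype(str)

    mapped = mapping.mapped_query_labels()
    ceiling = float(np.mean([lab in mapped for lab in y_test]))

    rng = np.random.default_rng(seed)
    accuracies = []
    last_pred = None
    for _ in range(max(1, runs)):
        run_seed = int(rng.integers(0, 2**31 - 1))
        Xt, yt = X_train, y_train
        if mode == "subsample":
            boot = np.random.default_rng(run_seed).integers(0, len(yt), size=len(yt))
            Xt, yt = Xt[boot], yt[boot]
        clf = LogisticRegression(C=1.0, solver="saga", max_iter=500,
                                 tol=1e-3, random_state=run_seed)
        clf.fit(Xt, yt)
        pred = clf.predict(X_test)
        correct = np.array([mapping.is_correct(p, t) for p, t in zip(pred, y_test)])
        accuracies.append(float(correct.mean()))
        last_pred = pred

    # per-class metrics on query labels with a unique inverse under the mapping
    inverse: dict[str, list] = {}
    for ref, queries in mapping.mapping.items():
        for q in queries:
            inverse.setdefault(q, []).append(ref)
    unique_q = {q: refs[0] for q, refs in inverse.items() if len(refs) == 1}
    sel = np.array([t in unique_q for t in y_test])
    if sel.any():
        y_true_ref = np.array([unique_q[t] for t in y_test[sel]])
        prec, rec, f1, support = precision_recall_fscore_support(
            y_true_ref, last_pred[sel], labels=sorted(set(y_true_ref)), zero_division=0)
        per_class = pd.DataFrame({
            "reference_label": sorted(set(y_true_ref)),
            "precision": prec, "recall": rec, "f1": f1, "support": support,
        })
    else:
        per_class = pd.DataFrame(columns=["reference_label", "precision", "recall", "f1", "support"])

    return TransferReport(accuracies=accuracies,
                          median_accuracy=float(np.median(accuracies)),
                          ceiling=ceiling, per_class=per_class)


def neighbor_composition(E: CellEmbeddingSet, query_species, ref_species,
                         k: int = 1) -> pd.DataFrame:
    """Reference cell-type frequencies among each query type's k nearest
    cross-species neighbors; rows normalized to 1."""
    q_idx = np.flatnonzero(E.species == query_species)
    r_idx = np.flatnonzero(E.species == ref_species)
    if q_idx.size == 0 or r_idx.size == 0:
        raise ValueError("both species must be present")
    if k > r_idx.size:
        import logging
        logging.getLogger(__name__).warning(
            "k=%d exceeds the reference size %d; capping", k, r_idx.size)
        k = r_idx.size

    D = cosine_distance_matrix(E.embeddings[q_idx], E.embeddings[r_idx])
    nn_k = np.argsort(D, axis=1, kind="stable")[:, :k]
    ref_labels = E.labels[r_idx]
    q_types = sorted(set(E.labels[q_idx].astype(str)))
    r_types = sorted(set(ref_labels.astype(str)))
    table = pd.DataFrame(0.0, index=q_types, columns=r_types)
    for i, q in enumerate(q_idx):
        for j in nn_k[i]:
            table.loc[str(E.labels[q]), str(ref_labels[j])] += 1.0
    return table.div(table.sum(axis=1), axis=0)


def _top_k_gene_lists(model: MacrogeneModel, species_id, k_max: int):
    """Per macrogene: genes of one species ranked by descending weight,
    ties broken lexicographically; returns an (N_M, k_max) id array."""
    sl = model.species_slice(species_id)
    genes = np.array([g for _, g in model.gene_index[sl.start:sl.stop]], dtype=object)
    W = model.weights[sl]
    lex = np.argsort(genes, kind="stable")
    lex_rank = np.empty(len(genes), dtype=int)
    lex_rank[lex] = np.arange(len(genes))
    out = np.empty((model.n_macrogenes, k_max), dtype=object)
    for m in range(model.n_macrogenes):
        order = np.lexsort((lex_rank, -W[:, m]))
        out[m] = genes[order[:k_max]]
    return out, genes


def homology_recapture_curve(model: MacrogeneModel, pairs: HomologPairTable,
                             species_a, species_b, k_range, null_reps: int = 100,
                             seed: int = 0) -> RecaptureCurve:
    """Observed and null homology-recapture proportions per top-k.

    Observed: a macrogene is a hit at k iff some (top-k gene of species a,
    top-k gene of species b) combination is a known homolog pair.  Null: per
    macrogene and replicate, k genes are drawn uniformly without replacement
    from each species' gene set (prefixes of one permutation per replicate,
    so the null curve is monotone by construction); the mean over replicates
    is reported.
    """
    k_range = np.asarray(sorted(k_range), dtype=int)
    n_a = model.species_slice(species_a)
    n_b = model.species_slice(species_b)
    max_k = min(n_a.stop - n_a.start, n_b.stop - n_b.start)
    if k_range.min() < 1 or k_range.max() > max_k:
        raise ValueError(f"k_range must lie within [1, {max_k}] (min species gene count)")
    tops_a, genes_a = _top_k_gene_lists(model, species_a, int(k_range.max()))
    tops_b, genes_b = _top_k_gene_lists(model, species_b, int(k_range.max()))

    def hit(a_list, b_list) -> bool:
        return any((a, b) in pairs for a in a_list for b in b_list)

    n_m = model.n_macrogenes
    observed = np.array([
        np.mean([hit(tops_a[m, :k], tops_b[m, :k]) for m in range(n_m)])
        for k in k_range
    ])

    rng = np.random.default_rng(seed)
    null_hits = np.zeros(len(k_range))
    for _ in range(null_reps):
        for m in range(n_m):
            perm_a = genes_a[rng.permutation(len(genes_a))[: k_range.max()]]
            perm_b = genes_b[rng.permutation(len(genes_b))[: k_range.max()]]
            for ki, k in enumerate(k_range):
                if hit(perm_a[:k], perm_b[:k]):
                    null_hits[ki:] += 1  # nested prefixes: a hit at k is a hit at k' > k
                    break
    null = null_hits / (null_reps * n_m)
    return RecaptureCurve(k_values=k_range, observed=observed, null=null)
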