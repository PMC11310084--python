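"""Core data containers: per-species count datasets, protein-embedding tables,
homolog-pair tables and cross-species cell-type mappings.

All containers validate their invariants on construction so downstream code
can assume well-formed inputs.  Counts are dense ``int64`` arrays — the
package targets desk-scale problems; sparse inputs are densified on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesDataset",
    "ProteinEmbeddingTable",
    "HomologPairTable",
    "CellTypeMapping",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        dupes = dupes[dupes > 1].index.tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dupes}")


@dataclass
class SpeciesDataset:
    """Raw counts and within-species cell annotations for one species.

    ``counts`` is cells × genes with nonnegative integer entries.  Labels are
    the species' own annotation (cell types or cluster ids); they are never
    matched across species by the model.
    """

    species_id: str
    counts: np.ndarray
    gene_ids: list[str]
    cell_labels: np.ndarray
    cell_ids: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if np.issubdtype(self.counts.dtype, np.floating):
            frac = self.counts != np.floor(self.counts)
            if frac.any():
                r, c = np.argwhere(frac)[0]
                raise ValidationError(
                    f"counts contain fractional values (e.g. {self.counts[r, c]!r} "
                    f"at cell {r}, gene {c}); raw integer counts are required"
                )
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            r, c = np.argwhere(self.counts < 0)[0]
            raise ValidationError(f"negative count {self.counts[r, c]} at cell {r}, gene {c}")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        _check_unique(self.gene_ids, f"gene ids in species {self.species_id!r}")
        _check_unique(self.cell_ids, f"cell ids in species {self.species_id!r}")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        self.cell_labels = np.asarray(self.cell_labels, dtype=object)
        if len(self.cell_labels) != self.n_cells:
            raise ValidationError("one label per cell is required")
        if any(lab is None or (isinstance(lab, float) and np.isnan(lab)) for lab in self.cell_labels):
            raise ValidationError("missing cell labels are not allowed")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, keep_idx: np.ndarray) -> "SpeciesDataset":
        keep_idx = np.asarray(keep_idx, dtype=int)
        return SpeciesDataset(
            species_id=self.species_id,
            counts=self.counts[:, keep_idx],
            gene_ids=[self.gene_ids[i] for i in keep_idx],
            cell_labels=self.cell_labels.copy(),
            cell_ids=list(self.cell_ids),
        )


@dataclass
class ProteinEmbeddingTable:
    """Per-gene protein embeddings (isoform-averaged) for one species."""

    species_id: str
    gene_ids: list[str]
    vectors: np.ndarray  # genes × p

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValidationError("embedding vectors must form a 2-D matrix")
        _check_unique(self.gene_ids, f"embedding gene ids in species {self.species_id!r}")
        if len(self.gene_ids) != self.vectors.shape[0]:
            raise ValidationError("one vector per gene id is required")
        if not np.isfinite(self.vectors).all():
            raise ValidationError("protein embeddings contain non-finite entries")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def p(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def vector(self, gene_id: str) -> np.ndarray:
        return self.vectors[self._index[gene_id]]


@dataclass
class HomologPairTable:
    """Cross-species homolog gene pairs (e.g. parsed BLASTP hits).

    Lookup is symmetric: ``("a", "b") in table`` iff ``("b", "a") in table``.
    """

    pairs: set = field(default_factory=set)

    def __post_init__(self):
        self.pairs = {(str(a), str(b)) for a, b in self.pairs}
        self._sym = self.pairs | {(b, a) for a, b in self.pairs}

    def __contains__(self, pair) -> bool:
        a, b = pair
        return (str(a), str(b)) in self._sym

    def __len__(self) -> int:
        return len(self.pairs)

    def validate_against(self, genes_a: set, genes_b: set) -> None:
        for a, b in self.pairs:
            ok = (a in genes_a and b in genes_b) or (a in genes_b and b in genes_a)
            if not ok:
                raise ValidationError(f"homolog pair ({a!r}, {b!r}) references unknown genes")


@dataclass
class CellTypeMapping:
    """Reference-species label → set of query-species labels considered correct."""

    mapping: dict

    def __post_init__(self):
        self.mapping = {str(k): {str(v) for v in vs} for k, vs in self.mapping.items()}

    def mapped_query_labels(self) -> set:
        out = set()
        for vs in self.mapping.values():
            out |= vs
        return out

    def is_correct(self, predicted_ref_label: str, true_query_label: str) -> bool:
        return str(true_query_label) in self.mapping.get(str(predicted_ref_label), set())

    def __len__(self) -> int:
        return len(self.mapping)
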