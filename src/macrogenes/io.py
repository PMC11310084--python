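"""Readers and writers for the package's on-disk interfaces.

Containers:

* per-species counts + labels: ``.h5ad`` (AnnData; raw counts in ``X`` or a
  named layer, labels in ``obs``),
* protein embeddings: TSV with one row per *protein* (``gene_id`` then *p*
  floats; rows sharing a gene id are isoform-averaged), or an HDF5 file with
  datasets ``gene_ids`` and ``vectors``,
* homolog pairs: 2-column TSV (BLASTP-tabular ``qseqid``/``sseqid`` compatible),
* cell-type mapping: 2-column TSV (reference label, query label).
"""

from __future__ import annotations

import logging

import anndata as ad
import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import ConfigurationError
from .datatypes import (
    CellTypeMapping,
    HomologPairTable,
    ProteinEmbeddingTable,
    SpeciesDataset,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_species_dataset",
    "save_species_dataset",
    "load_protein_embeddings",
    "save_protein_embeddings",
    "load_homolog_pairs",
    "load_cell_type_mapping",
    "normalized_dispersion",
    "select_hvgs",
    "align_genes",
]


# --------------------------------------------------------------------------
# species datasets (h5ad)
# --------------------------------------------------------------------------

def load_species_dataset(path, label_column: str, species_id: str | None = None,
                         layer: str | None = None) -> SpeciesDataset:
    """Read a validated :class:`SpeciesDataset` from an h5ad file.

    Raw counts are taken from ``X`` (or ``layers[layer]``); matrices with
    fractional or negative entries are rejected.
    """
    adata = ad.read_h5ad(path)
    if label_column not in adata.obs.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found in cell metadata "
            f"(available: {list(adata.obs.columns)})"
        )
    X = adata.layers[layer] if layer is not None else adata.X
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X)
    if species_id is None:
        species_id = adata.uns.get("species_id", str(path))
    return SpeciesDataset(
        species_id=str(species_id),
        counts=X,
        gene_ids=list(adata.var_names),
        cell_labels=adata.obs[label_column].astype(str).to_numpy(),
        cell_ids=list(adata.obs_names),
    )


def save_species_dataset(dataset: SpeciesDataset, path, label_column: str = "cell_type") -> None:
    adata = ad.AnnData(
        X=dataset.counts.astype(np.int64),
        obs=pd.DataFrame({label_column: pd.Categorical(dataset.cell_labels.astype(str))},
                         index=dataset.cell_ids),
        var=pd.DataFrame(index=dataset.gene_ids),
    )
    adata.uns["species_id"] = dataset.species_id
    adata.write_h5ad(path)


# --------------------------------------------------------------------------
# protein embeddings
# --------------------------------------------------------------------------

def load_protein_embeddings(path, species_id: str) -> ProteinEmbeddingTable:
    """Load per-gene protein embeddings.

    TSV input holds one row per protein; a gene's vector is the arithmetic
    mean of its protein rows, so genes with several isoforms are averaged and
    genes with no protein rows are simply absent from the table.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as fh:
            gene_ids = [g.decode() if isinstance(g, bytes) else str(g) for g in fh["gene_ids"][:]]
            vectors = fh["vectors"][:]
        return ProteinEmbeddingTable(species_id=species_id, gene_ids=gene_ids, vectors=vectors)

    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected a gene id column plus embedding columns")
    values = df.iloc[:, 1:]
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValidationError(f"{path}: non-finite embedding entries")
    grouped = values.groupby(df.iloc[:, 0].astype(str), sort=True).mean()
    return ProteinEmbeddingTable(
        species_id=species_id,
        gene_ids=[str(g) for g in grouped.index],
        vectors=grouped.to_numpy(dtype=np.float64),
    )


def save_protein_embeddings(table: ProteinEmbeddingTable, path) -> None:
    df = pd.DataFrame(table.vectors, index=table.gene_ids)
    df.to_csv(path, sep="\t", header=False)


# --------------------------------------------------------------------------
# homolog pairs and cell-type mapping (2-column TSVs)
# --------------------------------------------------------------------------

def load_homolog_pairs(path) -> HomologPairTable:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], comment="#")
    return HomologPairTable(pairs={(str(a), str(b)) for a, b in df.itertuples(index=False)})


def load_cell_type_mapping(path) -> CellTypeMapping:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], comment="#")
    mapping: dict[str, set] = {}
    for ref, query in df.itertuples(index=False):
        mapping.setdefault(str(ref), set()).add(str(query))
    return CellTypeMapping(mapping=mapping)


# --------------------------------------------------------------------------
# gene alignment across species
# --------------------------------------------------------------------------

def normalized_dispersion(counts: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Seurat-style normalized dispersion of each gene on log1p counts.

    Per gene, dispersion = var/mean of log1p counts; genes are binned into
    ``n_bins`` equal-frequency bins by mean expression and the dispersion is
    z-scored within each bin.  Genes with zero mean get ``-inf`` (never
    selected).
    """
    logx = np.log1p(np.asarray(counts, dtype=np.float64))
    mean = logx.mean(axis=0)
    var = logx.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)

    out = np.full(mean.shape, -np.inf)
    ok = np.isfinite(disp)
    if not ok.any():
        return out
    n_bins = min(n_bins, max(1, ok.sum()))
    ranks = pd.Series(mean[ok]).rank(method="first").to_numpy()
    bins = np.ceil(ranks / (ok.sum() / n_bins)).astype(int) - 1
    d = disp[ok]
    z = np.empty_like(d)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = d[sel].mean(), d[sel].std()
        z[sel] = 0.0 if sd == 0 else (d[sel] - mu) / sd
    out[ok] = z
    return out


def select_hvgs(dataset: SpeciesDataset, n: int) -> SpeciesDataset:
    """Keep the ``n`` genes with the highest normalized dispersion.

    Ties are broken by gene-id lexicographic order so selection is
    deterministic; gene order within the dataset is preserved.
    """
    if n >= dataset.n_genes:
        return dataset
    score = normalized_dispersion(dataset.counts)
    order = sorted(range(dataset.n_genes), key=lambda i: (-score[i], dataset.gene_ids[i]))
    keep = np.sort(np.array(order[:n]))
    return dataset.subset_genes(keep)


def align_genes(
    datasets: list[SpeciesDataset],
    tables: list[ProteinEmbeddingTable],
    hvg_per_species: int | str = "all",
) -> tuple[list[SpeciesDataset], np.ndarray, list[tuple[str, str]]]:
    """Harmonize each species with its embedding table and stack embeddings.

    Per species: optional HVG selection, then genes lacking a protein
    embedding are dropped (with a warning).  Returns the filtered datasets,
    the stacked embedding matrix ``P`` whose rows follow the concatenated
    per-species gene order, and that row index as ``(species_id, gene_id)``
    pairs.
    """
    if len(datasets) != len(tables):
        raise ValidationError("one embedding table per dataset is required")
    by_species = {t.species_id: t for t in tables}

    filtered: list[SpeciesDataset] = []
    rows: list[np.ndarray] = []
    gene_index: list[tuple[str, str]] = []
    for ds in datasets:
        if ds.species_id not in by_species:
            raise ValidationError(f"no embedding table for species {ds.species_id!r}")
        table = by_species[ds.species_id]
        if hvg_per_species != "all":
            ds = select_hvgs(ds, int(hvg_per_species))
        have = [i for i, g in enumerate(ds.gene_ids) if g in table]
        missing = ds.n_genes - len(have)
        if not have:
            raise ValidationError(
                f"species {ds.species_id!r}: no genes overlap its embedding table"
            )
        if missing:
            logger.warning(
                "species %s: dropping %d gene(s) without a protein embedding",
                ds.species_id, missing,
            )
            ds = ds.subset_genes(np.array(have))
        filtered.append(ds)
        rows.append(np.stack([table.vector(g) for g in ds.gene_ids]))
        gene_index.extend((ds.species_id, g) for g in ds.gene_ids)

    p_dims = {r.shape[1] for r in rows}
    if len(p_dims) != 1:
        raise ValidationError(f"embedding dimensions differ across species: {sorted(p_dims)}")
    return filtered, np.vstack(rows), gene_index
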