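"""Differential expression on macrogene values.

The test is a Wilcoxon rank-sum (Mann-Whitney) test per macrogene between a
target cell group and the rest (or a specific other group), pooling cells
from all species — macrogene values are species-comparable by construction.
For macrogene m and target group t:

    U_m = R_m - |c in t| (|c in t| + 1) / 2

where R_m is the rank sum (midranks for ties) of group-t cells.  P-values
come from the normal approximation with tie correction and an optional
continuity correction; Benjamini-Hochberg adjustment is reported alongside
the raw p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import SpeciesDataset
from .macrogene import MacrogeneModel, top_genes
from .model import ZinbAutoencoder

__all__ = ["macrogene_values", "wilcoxon_de", "name_macrogene", "cross_species_de"]


def macrogene_values(datasets: list[SpeciesDataset], model: ZinbAutoencoder):
    """Evaluation-mode macrogene expression for every cell (trained weights)."""
    return model.macrogene_values(datasets)


def _rank_sum_stats(values: np.ndarray, in_group: np.ndarray,
                    continuity: bool = True, tie_correction: bool = True):
    """Vectorized U, rank sum, z and two-sided p per column of `values`."""
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    n = values.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")

    ranks = stats.rankdata(values, method="average", axis=0)
    R = ranks[in_group].sum(axis=0)
    U = R - n1 * (n1 + 1) / 2.0

    mean_u = n1 * n2 / 2.0
    if tie_correction:
        tie_term = np.empty(values.shape[1])
        for j in range(values.shape[1]):
            _, counts = np.unique(values[:, j], return_counts=True)
            tie_term[j] = (counts**3 - counts).sum()
    else:
        tie_term = np.zeros(values.shape[1])
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    with np.errstate(divide="ignore", invalid="ignore"):
        shift = U - mean_u
        if continuity:
            shift = shift - 0.5 * np.sign(shift)
        z = shift / np.sqrt(var_u)
    constant = var_u <= 0
    z = np.where(constant, 0.0, z)
    p = np.where(constant, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return U, R, z, p, constant, n1, n2


def wilcoxon_de(values: np.ndarray, labels: np.ndarray, target, versus="rest",
                continuity: bool = True, tie_correction: bool = True) -> pd.DataFrame:
    """Rank-sum differential expression of each macrogene for group `target`.

    `versus` is ``"rest"`` or a specific group label.  Rows are sorted by
    ascending adjusted p-value, then descending |z| (effect).  Macrogenes
    constant across all tested cells get p = 1 and ``constant=True``.
    """
    labels = np.asarray(labels, dtype=object)
    in_target = labels == target
    if versus == "rest":
        keep = np.ones(len(labels), dtype=bool)
    else:
        keep = in_target | (labels == versus)
    values = np.atleast_2d(values)[keep]
    in_group = in_target[keep]
    if in_group.sum() == 0:
        raise ValueError(f"target group {target!r} is empty")
    if (~in_group).sum() == 0:
        raise ValueError("comparison group is empty")

    U, R, z, p, constant, n1, n2 = _rank_sum_stats(values, in_group, continuity, tie_correction)
    p_adj = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame({
        "macrogene": np.arange(values.shape[1]),
        "U": U,
        "rank_sum": R,
        "z": z,
        "p": p,
        "p_adj": np.maximum(p_adj, p),
        "direction": np.where(U > n1 * n2 / 2.0, "up", np.where(U < n1 * n2 / 2.0, "down", "none")),
        "constant": constant,
        "n_group": n1,
        "n_rest": n2,
    })
    return df.sort_values(["p_adj", "p", "z"],
                          key=lambda s: -s.abs() if s.name == "z" else s,
                          kind="stable").reset_index(drop=True)


def name_macrogene(model: MacrogeneModel, macrogene_id: int, per_species_k: int = 5) -> dict:
    """Interpretable label for a macrogene: the gene id with the maximum
    weight (ties break lexicographically), plus per-species top gene lists."""
    col = model.weights[:, macrogene_id]
    genes = [g for _, g in model.gene_index]
    best = min(range(len(genes)), key=lambda i: (-col[i], genes[i]))
    return {
        "name": genes[best],
        "top_genes": top_genes(model, macrogene_id, per_species_k),
    }


def cross_species_de(values: np.ndarray, labels: np.ndarray, species: np.ndarray,
                     cell_type, species_a, species_b, **kwargs) -> pd.DataFrame:
    """Macrogene DE between two species within one conserved cell type."""
    labels = np.asarray(labels, dtype=object)
    species = np.asarray(species, dtype=object)
    for s in (species_a, species_b):
        if not ((labels == cell_type) & (species == s)).any():
            raise ValueError(f"cell type {cell_type!r} is absent in species {s!r}")
    keep = (labels == cell_type) & ((species == species_a) | (species == species_b))
    return wilcoxon_de(np.atleast_2d(values)[keep], species[keep], species_a,
                       versus=species_b, **kwargs)
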