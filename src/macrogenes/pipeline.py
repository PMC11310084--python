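"""End-to-end orchestration: gene alignment → macrogene initialization →
ZINB-autoencoder pretraining → triplet fine-tuning."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import TrainingConfig
from .datatypes import ProteinEmbeddingTable, SpeciesDataset
from .io import align_genes
from .macrogene import MacrogeneModel, cluster_protein_embeddings, initialize_weights
from .model import CellEmbeddingSet, ZinbAutoencoder, pretrain
from .triplets import finetune

logger = logging.getLogger(__name__)

__all__ = ["IntegrationResult", "run_integration"]


@dataclass
class IntegrationResult:
    datasets: list                     # gene-filtered inputs actually used
    protein_embeddings: np.ndarray     # stacked P
    initial_macrogenes: MacrogeneModel
    trained_macrogenes: MacrogeneModel  # same centroids/rd, pretrained weights
    model: ZinbAutoencoder
    pretrain_embeddings: CellEmbeddingSet
    final_embeddings: CellEmbeddingSet
    pretrain_history: list
    finetune_history: list


def run_integration(datasets: list[SpeciesDataset], tables: list[ProteinEmbeddingTable],
                    config: TrainingConfig, skip_finetune: bool = False) -> IntegrationResult:
    """Run the full two-stage integration with a single seed.

    With a fixed ``config.seed`` the result is bit-reproducible: k-means,
    parameter initialization, minibatch order, dropout, the similarity-loss
    permutations and all triplet sampling derive from it.
    """
    filtered, P, gene_index = align_genes(datasets, tables, config.hvg_per_species)
    logger.info("aligned %d species, %d genes total", len(filtered), len(gene_index))

    centroids = cluster_protein_embeddings(P, config.num_macrogenes, config.seed)
    macrogenes = initialize_weights(P, centroids, gene_index)

    model = ZinbAutoencoder(macrogenes, config)
    pretrain_history = pretrain(model, filtered, P)
    pretrain_embeddings = model.embed_datasets(filtered)

    if skip_finetune:
        final_embeddings, finetune_history = pretrain_embeddings, []
    else:
        final_embeddings, finetune_history = finetune(model, filtered)

    return IntegrationResult(
        datasets=filtered,
        protein_embeddings=P,
        initial_macrogenes=macrogenes,
        trained_macrogenes=macrogenes.with_weights(model.weights),
        model=model,
        pretrain_embeddings=pretrain_embeddings,
        final_embeddings=final_embeddings,
        pretrain_history=pretrain_history,
        finetune_history=finetune_history,
    )
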