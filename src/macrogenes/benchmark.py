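"""The package's standard synthetic benchmark.

Conditions: 3 species, 5 shared + 1 species-unique cell type each, 2000
cells and 300 genes per species, 200 homolog triples (the
:class:`~macrogenes.simulate.SyntheticConfig` defaults).  Model capacity is
scaled to the 900-gene problem: 128 macrogenes, latent dimension 32, hidden
width 128, weight-encoder width 64.  Epoch counts are chosen for convergence
at this scale (see docs/methods.md).

``run_benchmark`` executes the full pipeline once and scores it; it is the
basis of both the acceptance tests and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .config import TrainingConfig
from .de import wilcoxon_de
from .evaluate import (homology_recapture_curve, label_transfer_score,
                       neighbor_composition)
from .macrogene import species_specific_fraction
from .pipeline import IntegrationResult, run_integration
from .simulate import SyntheticConfig, generate_benchmark

__all__ = ["benchmark_config", "run_benchmark"]


def benchmark_config(seed: int, **overrides) -> TrainingConfig:
    defaults = dict(
        num_macrogenes=128,
        hvg_per_species="all",
        latent_dim=32,
        hidden_dim=128,
        weight_encoder_dim=64,
        pretrain_epochs=12,
        finetune_epochs=10,
        triplet_steps_per_epoch=5,
        batch_size=256,
        seed=seed,
    )
    defaults.update(overrides)
    return TrainingConfig(**defaults)


def run_benchmark(seed: int, synthetic_config: SyntheticConfig | None = None,
                  full_scores: bool = True, **config_overrides) -> dict:
    """Generate the benchmark, integrate it, and score the result.

    Returns a dict with the integration result, the truth, and the scores:
    label-transfer accuracy (fine-tuned and pretrain-only) with its ceiling,
    the homology-recapture curve, the species-specific macrogene fraction,
    and the neighbor composition of the species-unique types.
    """
    truth, datasets, tables, mapping = generate_benchmark(seed, synthetic_config)
    config = benchmark_config(seed, **config_overrides)
    result: IntegrationResult = run_integration(datasets, tables, config)

    train_s, test_s = truth.species[0], truth.species[1]
    transfer = label_transfer_score(result.final_embeddings, train_s, test_s,
                                    mapping, runs=1, seed=seed)
    transfer_pre = label_transfer_score(result.pretrain_embeddings, train_s, test_s,
                                        mapping, runs=1, seed=seed)

    if not full_scores:
        return {
            "truth": truth,
            "mapping": mapping,
            "result": result,
            "accuracy": transfer.median_accuracy,
            "accuracy_pretrain_only": transfer_pre.median_accuracy,
            "ceiling": transfer.ceiling,
            "n_cells": sum(ds.n_cells for ds in result.datasets),
        }

    pairs = truth.homolog_pair_table(train_s, test_s)
    recapture = homology_recapture_curve(result.trained_macrogenes, pairs,
                                         train_s, test_s, k_range=[1, 2, 5, 10],
                                         null_reps=50, seed=seed)

    # species-specific macrogene fraction over pooled top-20 DE lists
    values, _species, labels = result.model.macrogene_values(result.datasets)
    top20: list[int] = []
    for cell_type in dict.fromkeys(labels):
        table = wilcoxon_de(values, labels, cell_type)
        top20.extend(table["macrogene"].head(20).tolist())
    specific_fraction = species_specific_fraction(result.trained_macrogenes, top20)

    # cross-species neighbor composition of the query species' unique type
    composition = neighbor_composition(result.final_embeddings, test_s, train_s, k=1)
    unique_rows = [t for t in composition.index if "unique" in t]
    unique_max = float(composition.loc[unique_rows].max(axis=1).max()) if unique_rows else float("nan")

    return {
        "truth": truth,
        "mapping": mapping,
        "result": result,
        "accuracy": transfer.median_accuracy,
        "accuracy_pretrain_only": transfer_pre.median_accuracy,
        "ceiling": transfer.ceiling,
        "recapture": recapture,
        "species_specific_fraction": specific_fraction,
        "unique_type_max_composition": unique_max,
        "n_cells": sum(ds.n_cells for ds in result.datasets),
    }
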