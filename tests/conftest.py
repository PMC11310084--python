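import numpy as np
import pytest

import macrogenes as mg


SMALL = mg.SyntheticConfig(
    cells_per_species=150,
    genes_per_species=60,
    n_homolog_groups=40,
    n_shared_types=3,
    n_modules=8,
    embedding_dim=16,
)


def small_training_config(seed=0, **overrides):
    defaults = dict(
        num_macrogenes=20,
        hvg_per_species="all",
        latent_dim=8,
        hidden_dim=32,
        weight_encoder_dim=16,
        pretrain_epochs=4,
        finetune_epochs=4,
        triplet_steps_per_epoch=3,
        batch_size=64,
        seed=seed,
    )
    defaults.update(overrides)
    return mg.TrainingConfig(**defaults)


@pytest.fixture(scope="session")
def small_world():
    """A small 3-species synthetic world: truth, datasets, embeddings, mapping."""
    return mg.generate_benchmark(11, SMALL)


@pytest.fixture(scope="session")
def small_result(small_world):
    """One full integration run on the small world, shared across tests."""
    _, datasets, tables, _ = small_world
    return mg.run_integration(datasets, tables, small_training_config(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
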