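"""Training configuration.

Every hyperparameter of the pipeline lives here so that a single YAML file
(or CLI flags overriding it) fully determines a run.  With a fixed ``seed``
the whole pipeline is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

__all__ = ["TrainingConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    pass


@dataclass
class TrainingConfig:
    # macrogene space
    num_macrogenes: int = 2000
    hvg_per_species: int | str = 8000  # or "all"

    # model capacity
    latent_dim: int = 256          # k: cell embedding dimension
    hidden_dim: int = 512          # encoder / decoder hidden width
    weight_encoder_dim: int = 256  # n: output of the macrogene-weight encoder Q
    dropout: float = 0.1
    layernorm_eps: float = 1e-5
    species_conditional: bool = False

    # objectives
    tau: float = 1.0     # weight of the protein-similarity regularizer
    margin: float = 0.2  # triplet margin

    # optimization
    pretrain_epochs: int = 50
    finetune_epochs: int = 30
    learning_rate: float = 1e-3
    finetune_learning_rate: float = 1e-4
    triplet_steps_per_epoch: int = 5
    batch_size: int = 256

    seed: int = 0

    def __post_init__(self):
        if self.num_macrogenes < 2:
            raise ConfigurationError("num_macrogenes must be >= 2")
        if self.margin <= 0:
            raise ConfigurationError("margin must be > 0")
        if self.tau < 0:
            raise ConfigurationError("tau must be >= 0")
        if not (0 <= self.dropout < 1):
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.hvg_per_species != "all" and int(self.hvg_per_species) < 1:
            raise ConfigurationError('hvg_per_species must be a positive int or "all"')

    @classmethod
    def from_yaml(cls, path, **overrides) -> "TrainingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
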