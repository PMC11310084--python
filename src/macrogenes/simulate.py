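"""Synthetic multi-species single-cell data with known ground truth.

The generator emulates the statistical structure the integration method
assumes: several species with disjoint gene identifier sets, a shared set of
latent cell types driving ZINB-distributed counts through gene programs
("modules"), and per-gene protein embeddings in which homologous genes
across species lie near each other.

Counts use the negative-binomial-as-gamma-Poisson construction plus a
Bernoulli zero-inflation mask, so the generator is mutually consistent with
the model's ZINB likelihood.  Library sizes are lognormal
(mean log 2000, sigma 0.3) to create realistic depth variation.

Defaults define the package's standard benchmark: 3 species, 5 shared plus 1
species-unique cell type each, 2000 cells and 300 genes per species, 200
homolog groups spanning all species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .datatypes import (CellTypeMapping, HomologPairTable,
                        ProteinEmbeddingTable, SpeciesDataset)

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_truth",
           "generate_counts", "generate_protein_embeddings",
           "generate_benchmark", "benchmark_mapping"]


@dataclass
class SyntheticConfig:
    n_species: int = 3
    genes_per_species: int = 300
    n_homolog_groups: int = 200      # bijective groups spanning every species
    n_modules: int = 10              # latent gene programs
    n_shared_types: int = 5
    n_unique_types_per_species: int = 1
    cells_per_species: int = 2000

    # ZINB noise model
    inverse_dispersion: float = 2.0  # theta
    zero_inflation: float = 0.05     # pi
    library_log_mean: float = float(np.log(2000.0))
    library_log_sigma: float = 0.3

    # expression programs
    modules_per_type: int = 3
    active_loading: float = 1.0
    baseline_loading: float = 0.05

    # protein-embedding geometry
    embedding_dim: int = 64
    module_scale: float = 8.0        # module base vector scale
    module_noise: float = 1.0        # within-module gene scatter
    homolog_noise: float = 0.1       # within-homolog-group scatter

    def __post_init__(self):
        if self.n_species < 2 or self.n_shared_types < 2 or self.n_modules < 2:
            raise ValueError("need >= 2 species, >= 2 cell types and >= 2 modules")
        if self.n_homolog_groups > self.genes_per_species:
            raise ValueError("more homolog groups requested than genes per species")
        if self.embedding_dim < 2 or self.homolog_noise < 0:
            raise ValueError("embedding_dim >= 2 and homolog_noise >= 0 required")


@dataclass
class SyntheticTruth:
    """Everything needed to generate counts/embeddings and to score results."""

    config: SyntheticConfig
    species: list
    gene_ids: dict            # species -> list of gene ids
    homolog_groups: list      # each: {species: gene_id}, bijective where defined
    gene_module: dict         # (species, gene) -> module index
    gene_scale: dict          # (species, gene) -> positive expression scale
    cell_types: dict          # species -> list of type names present
    type_loadings: dict       # type name -> module loading vector (>= 0)
    seed: int

    def homolog_pair_table(self, species_a, species_b) -> HomologPairTable:
        pairs = {(grp[species_a], grp[species_b])
                 for grp in self.homolog_groups
                 if species_a in grp and species_b in grp}
        return HomologPairTable(pairs=pairs)

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "species": self.species,
            "gene_ids": self.gene_ids,
            "homolog_groups": self.homolog_groups,
            "gene_module": {f"{s}::{g}": m for (s, g), m in self.gene_module.items()},
            "gene_scale": {f"{s}::{g}": v for (s, g), v in self.gene_scale.items()},
            "cell_types": self.cell_types,
            "type_loadings": {t: list(v) for t, v in self.type_loadings.items()},
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def generate_truth(config: SyntheticConfig, seed: int) -> SyntheticTruth:
    """Assign genes to modules and homolog groups, and types to loadings.

    Homologous genes share a module; a configurable number of cell types is
    unique to each species, emulating species-specific cell types.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 101]))
    cfg = config
    species = [f"species_{i}" for i in range(cfg.n_species)]
    gene_ids = {s: [f"{s}_g{j:04d}" for j in range(cfg.genes_per_species)] for s in species}

    # the first n_homolog_groups gene slots of every species form the groups
    homolog_groups = [{s: gene_ids[s][j] for s in species}
                      for j in range(cfg.n_homolog_groups)]

    gene_module: dict = {}
    group_module = rng.integers(0, cfg.n_modules, size=cfg.n_homolog_groups)
    for j, grp in enumerate(homolog_groups):
        for s, g in grp.items():
            gene_module[(s, g)] = int(group_module[j])
    for s in species:
        for g in gene_ids[s][cfg.n_homolog_groups:]:
            gene_module[(s, g)] = int(rng.integers(0, cfg.n_modules))

    gene_scale = {key: float(np.exp(rng.normal(0.0, 0.5)))
                  for key in gene_module}

    shared = [f"type_{t}" for t in range(cfg.n_shared_types)]
    cell_types = {}
    type_loadings: dict = {}
    all_types = list(shared)
    for s in species:
        uniques = [f"{s}_unique_{u}" for u in range(cfg.n_unique_types_per_species)]
        cell_types[s] = shared + uniques
        all_types.extend(uniques)
    used_signatures: set = set()
    for t in all_types:
        # distinct module signature per type so every type is identifiable
        for _ in range(1000):
            active = tuple(sorted(rng.choice(cfg.n_modules, size=cfg.modules_per_type,
                                             replace=False).tolist()))
            if active not in used_signatures:
                used_signatures.add(active)
                break
        else:
            raise ValueError("not enough distinct module combinations for the requested types")
        loading = np.full(cfg.n_modules, cfg.baseline_loading)
        loading[list(active)] = cfg.active_loading
        type_loadings[t] = loading

    return SyntheticTruth(config=cfg, species=species, gene_ids=gene_ids,
                          homolog_groups=homolog_groups, gene_module=gene_module,
                          gene_scale=gene_scale, cell_types=cell_types,
                          type_loadings=type_loadings, seed=int(seed))


def generate_counts(truth: SyntheticTruth, seed: int | None = None) -> list:
    """ZINB counts per species: type loadings → per-gene means → gamma-Poisson
    draws with the truth's inverse dispersion, then a zero-inflation mask."""
    cfg = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([(truth.seed if seed is None else int(seed)) % 2**31, 211]))
    datasets = []
    for s in truth.species:
        genes = truth.gene_ids[s]
        scale = np.array([truth.gene_scale[(s, g)] for g in genes])
        modules = np.array([truth.gene_module[(s, g)] for g in genes])
        types = truth.cell_types[s]
        labels = np.array(types, dtype=object)[rng.integers(0, len(types), size=cfg.cells_per_species)]
        library = np.exp(rng.normal(cfg.library_log_mean, cfg.library_log_sigma,
                                    size=cfg.cells_per_species))

        loadings = np.stack([truth.type_loadings[t] for t in labels])  # cells × modules
        rate = loadings[:, modules] * scale[None, :]                   # cells × genes
        mu = rate / rate.sum(axis=1, keepdims=True) * library[:, None]

        theta = cfg.inverse_dispersion
        lam = rng.gamma(shape=theta, scale=mu / theta)
        counts = rng.poisson(lam)
        if cfg.zero_inflation > 0:
            counts[rng.random(counts.shape) < cfg.zero_inflation] = 0
        datasets.append(SpeciesDataset(
            species_id=s,
            counts=counts.astype(np.int64),
            gene_ids=genes,
            cell_labels=labels,
            cell_ids=[f"{s}_c{i:05d}" for i in range(cfg.cells_per_species)],
        ))
    return datasets


def generate_protein_embeddings(truth: SyntheticTruth, p: int | None = None,
                                homolog_noise: float | None = None,
                                seed: int | None = None) -> list:
    """Module-structured gene "protein embeddings".

    Each module has a base vector; each homolog group (and each unique gene)
    gets its own offset within the module; homologous genes share that offset
    up to a small `homolog_noise` perturbation, so a homolog's nearest
    cross-species neighbor is its partner at default noise.
    """
    cfg = truth.config
    p = cfg.embedding_dim if p is None else int(p)
    hnoise = cfg.homolog_noise if homolog_noise is None else float(homolog_noise)
    rng = np.random.default_rng(np.random.SeedSequence([(truth.seed if seed is None else int(seed)) % 2**31, 307]))

    module_base = rng.normal(0.0, cfg.module_scale, size=(cfg.n_modules, p))
    group_offset = rng.normal(0.0, cfg.module_noise, size=(len(truth.homolog_groups), p))

    tables = []
    for s in truth.species:
        vectors = np.empty((len(truth.gene_ids[s]), p))
        for i, g in enumerate(truth.gene_ids[s]):
            m = truth.gene_module[(s, g)]
            if i < len(truth.homolog_groups):
                base = module_base[m] + group_offset[i]
                vectors[i] = base + rng.normal(0.0, hnoise, size=p)
            else:
                vectors[i] = module_base[m] + rng.normal(0.0, cfg.module_noise, size=p)
        tables.append(ProteinEmbeddingTable(species_id=s,
                                            gene_ids=list(truth.gene_ids[s]),
                                            vectors=vectors))
    return tables


def benchmark_mapping(truth: SyntheticTruth) -> CellTypeMapping:
    """Identity mapping over the shared cell types (unique types unmapped)."""
    shared = [t for t in truth.type_loadings if t.startswith("type_")]
    return CellTypeMapping(mapping={t: {t} for t in shared})


def generate_benchmark(seed: int, config: SyntheticConfig | None = None):
    """The default synthetic benchmark: truth, datasets, embeddings, mapping."""
    cfg = config or SyntheticConfig()
    truth = generate_truth(cfg, seed)
    datasets = generate_counts(truth)
    tables = generate_protein_embeddings(truth)
    return truth, datasets, tables, benchmark_mapping(truth)
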