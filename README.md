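# macrogenes

Cross-species integration of single-cell RNA-seq data through
**macrogenes** — a shared feature space learned from protein-language-model
embeddings of each species' genes.

Different species have different genes, so most integration methods restrict
the data to one-to-one orthologs and throw the rest away. This package
instead connects every gene `g` of every species to a set of learned
macrogenes `m` through strictly positive weights `W[g, m]`, initialized by
k-means clustering of the genes' protein embeddings:

    W[g, m] = 2 · (ln(1 / rd[m, g] + 1))²

with `rd[m, g]` the rank of gene g's Euclidean distance to centroid m
(rank 1 = nearest). Cells are embedded in two stages:

1. **ZINB autoencoder pretraining.** A cell's macrogene expression
   `e_c = ReLU(LayerNorm(W_sᵀ log(X_c + 1)))` is encoded to a latent
   `z_c = f(e_c)` and decoded into per-gene zero-inflated negative binomial
   parameters (`μ`, zero-inflation logits `O`, inverse dispersion `θ`),
   with means softmax-scaled to preserve each cell's library size. The loss
   adds a regularizer keeping the weight rows' cosine structure aligned with
   the protein embeddings' cosine structure; τ = 1.
2. **Triplet metric learning.** Anchors and positives are mined as mutual
   cross-species 1-nearest neighbors (cosine) with a within-species label
   back-check, negatives drawn from cells with a different label than both,
   triplets filtered to the semihard window
   `D(a,p) < D(a,n) < D(a,p) + m` (margin m = 0.2), and the triplet margin
   loss is minimized over the encoder only — weights and decoder stay
   frozen. Only within-species annotations are used, never cross-species.

On top of the embeddings the package provides macrogene differential
expression (Wilcoxon rank-sum on macrogene values, pooled across species,
BH-adjusted), macrogene naming/interpretation by top-weighted genes,
cross-species label-transfer scoring, neighbor-composition analysis,
homology-recapture curves against a random null, and a synthetic
multi-species generator with full ground truth. See `docs/methods.md` for
the model details and design choices.

Who it is for: computational biologists integrating scRNA-seq atlases across
species (precomputed protein embeddings in hand), and method developers who
need a fully testable, deterministic desk-scale implementation.

## Worked example

```python
import macrogenes as mg

# a small synthetic world: 2 species, 120 genes each, 80 homolog pairs
world = mg.SyntheticConfig(n_species=2, cells_per_species=800,
                           genes_per_species=120, n_homolog_groups=80,
                           n_shared_types=4, embedding_dim=32)
truth, datasets, tables, mapping = mg.generate_benchmark(seed=0, config=world)

config = mg.TrainingConfig(num_macrogenes=48, hvg_per_species="all",
                           latent_dim=16, hidden_dim=64, weight_encoder_dim=32,
                           pretrain_epochs=15, finetune_epochs=10, seed=0)
result = mg.run_integration(datasets, tables, config)

report = mg.label_transfer_score(result.final_embeddings, "species_0",
                                 "species_1", mapping, runs=1, seed=0)
print(f"label transfer accuracy: {report.median_accuracy:.3f} "
      f"(ceiling {report.ceiling:.3f})")

pairs = truth.homolog_pair_table("species_0", "species_1")
curve = mg.homology_recapture_curve(result.trained_macrogenes, pairs,
                                    "species_0", "species_1",
                                    k_range=[1, 5], null_reps=50, seed=0)
print(f"homology recapture at top-1: {curve.observed[0]:.2f} "
      f"(random null {curve.null[0]:.4f})")

values, species, labels = mg.macrogene_values(result.datasets, result.model)
table = mg.wilcoxon_de(values, labels, "type_0")
top = int(table.loc[0, "macrogene"])
name = mg.name_macrogene(result.trained_macrogenes, top)["name"]
print(f"top marker macrogene for type_0: #{top} ({name}), "
      f"adjusted p = {table.loc[0, 'p_adj']:.2e}")
```

Output (about 4 s on one CPU):

```
label transfer accuracy: 0.756 (ceiling 0.818)
homology recapture at top-1: 0.83 (random null 0.0050)
top marker macrogene for type_0: #15 (species_0_g0060), adjusted p = 1.02e-115
```

Reading the numbers: a logistic classifier trained on species_0's annotated
embeddings predicts species_1's cell types at 0.756 accuracy, against a
ceiling of 0.818 (the fraction of species_1 cells whose type exists in the
cross-species mapping at all — species-unique types cannot be predicted).
83% of macrogenes hold a known homolog pair within their single
top-weighted gene per species; randomly chosen genes would do so 0.5% of
the time. The top type_0 marker macrogene is named after its
highest-weighted gene.

## Command line

The same pipeline is available as a CLI over files (h5ad counts, TSV
embeddings/homologs/mappings, YAML config):

```sh
macrogenes simulate --seed 0 --out data/
macrogenes train --data data/species_0.h5ad --data data/species_1.h5ad \
    --embeddings data/species_0_embeddings.tsv \
    --embeddings data/species_1_embeddings.tsv \
    --config config.yaml --out run/
macrogenes de --data data/species_0.h5ad --checkpoint run/checkpoint.h5 \
    --groupby-value type_0 --out de.tsv
macrogenes eval transfer --data run/species_0_integrated.h5ad \
    --data run/species_1_integrated.h5ad \
    --train-species species_0 --test-species species_1 \
    --mapping data/cell_type_mapping.tsv --out transfer.json
```

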