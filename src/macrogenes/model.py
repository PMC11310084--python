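"""The two-stage cell-embedding model.

Stage one pretrains an autoencoder over the macrogene space with a
zero-inflated negative binomial (ZINB) reconstruction loss plus a
protein-similarity regularizer on the gene-to-macrogene weights.  Stage two
(:mod:`macrogenes.triplets`) fine-tunes the encoder with a triplet metric
objective.

Architecture (widths configurable):

* aggregation:  e = ReLU(LayerNorm(log1p(X) @ W_s)) with W = softplus(free
  parameter), so the gene-to-macrogene weights stay strictly positive and
  differentiable while being updated during pretraining;
* encoder f: two blocks of Linear -> ReLU -> LayerNorm -> Dropout,
  N_M -> hidden -> k;
* decoder: shared trunk D_S (k -> hidden, same block structure), mean head
  D_mu (hidden -> N_M, same block) projected through the species weight
  block and softmax-scaled to the cell's library size, zero-inflation logit
  head D_O (hidden -> |G|, linear), and a free per-gene inverse-dispersion
  parameter theta (softplus-positive, shared across cells);
* weight encoder Q: one block N_M -> n applied to rows of W for the
  similarity regularizer.

The species one-hot conditional is available behind
``config.species_conditional`` and off (a constant decoder input) by default.
"""

from __future__ import annotations

import json
import logging

import h5py
import numpy as np

from .autograd import Tensor, concat, logaddexp
from . import nn
from .config import TrainingConfig
from .datatypes import SpeciesDataset
from .macrogene import MacrogeneModel

logger = logging.getLogger(__name__)

__all__ = ["ZinbAutoencoder", "zinb_nll", "similarity_loss", "pretrain",
           "CellEmbeddingSet", "save_checkpoint", "load_checkpoint"]

_MU_EPS = 1e-8


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def zinb_nll(x, mu, theta, logits) -> Tensor:
    """Negative log likelihood of counts under a ZINB mixture, summed over genes.

    The mixture puts probability ``pi = sigmoid(logits)`` on a point mass at
    zero and ``1 - pi`` on a negative binomial with mean ``mu`` and inverse
    dispersion ``theta`` (the marginal of the Poisson-gamma construction).
    Evaluated entirely in log space:

        log P(0) = logaddexp(logits, log NB(0)) - softplus(logits)
        log P(x>0) = -softplus(logits) + log NB(x)

    ``x`` is a constant array; ``mu``, ``theta``, ``logits`` may carry grads.
    """
    x_data = np.asarray(x.data if isinstance(x, Tensor) else x, dtype=np.float64)
    if (x_data < 0).any() or (x_data != np.floor(x_data)).any():
        raise ValueError("counts must be nonnegative integers")
    mu = mu if isinstance(mu, Tensor) else Tensor(mu)
    theta = theta if isinstance(theta, Tensor) else Tensor(theta)
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    if not (np.isfinite(mu.data).all() and np.isfinite(theta.data).all()
            and np.isfinite(logits.data).all()):
        raise ValueError("ZINB parameters must be finite")

    x_t = Tensor(x_data)
    log_theta_mu = (theta + mu + _MU_EPS).log()
    log_nb_zero = theta * ((theta + _MU_EPS).log() - log_theta_mu)
    log_nb = (
        (x_t + theta).lgamma() - theta.lgamma() - Tensor(_lgamma_const(x_data + 1.0))
        + log_nb_zero
        + x_t * ((mu + _MU_EPS).log() - log_theta_mu)
    )
    sp = logits.softplus()
    log_p_zero = logaddexp(logits, log_nb_zero) - sp
    log_p_pos = log_nb - sp
    zero_mask = Tensor((x_data == 0).astype(np.float64))
    log_p = zero_mask * log_p_zero + (1.0 - zero_mask) * log_p_pos
    return -log_p.sum(axis=-1)


def _lgamma_const(v: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln
    return gammaln(v)


def similarity_loss(B: Tensor, P: np.ndarray, permutation: np.ndarray) -> Tensor:
    """Mean squared difference between weight-space and protein-space
    row-to-shuffled-row cosine similarities.

    ``B`` are the Q-encoded macrogene weight rows (one per gene), ``P`` the
    protein embeddings in the same row order, and ``permutation`` a seeded
    permutation of gene rows applied identically to both.  Rows with zero
    norm get cosine 0.
    """
    perm = np.asarray(permutation, dtype=int)
    sim_b = nn.cosine_rows(B, B[perm])
    sim_p = nn.cosine_rows(Tensor(P), Tensor(P[perm, :]))
    diff = sim_b - sim_p
    return (diff**2).mean()


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class CellEmbeddingSet:
    """Per-cell latent embeddings with species and within-species labels."""

    def __init__(self, embeddings: np.ndarray, species: np.ndarray,
                 labels: np.ndarray, cell_ids: list):
        self.embeddings = np.asarray(embeddings, dtype=np.float64)
        self.species = np.asarray(species, dtype=object)
        self.labels = np.asarray(labels, dtype=object)
        self.cell_ids = list(cell_ids)
        if not np.isfinite(self.embeddings).all():
            raise ValueError("embeddings contain non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.embeddings.shape[0]

    @property
    def k(self) -> int:
        return self.embeddings.shape[1]


class ZinbAutoencoder:
    """Autoencoder over the macrogene space (see module docstring)."""

    def __init__(self, macrogene_model: MacrogeneModel, config: TrainingConfig,
                 species_ids: list | None = None):
        self.config = config
        self.gene_index = list(macrogene_model.gene_index)
        self.species_ids = species_ids or macrogene_model.species_ids
        self.species_slices = {s: macrogene_model.species_slice(s) for s in self.species_ids}
        self.n_genes = len(self.gene_index)
        self.n_macrogenes = macrogene_model.n_macrogenes

        m, k, h, n = self.n_macrogenes, config.latent_dim, config.hidden_dim, config.weight_encoder_dim
        dec_in = k + (len(self.species_ids) if config.species_conditional else 0)

        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, 17]))
        P = nn.Parameter
        w0 = np.clip(macrogene_model.weights, 1e-10, None)
        self.params: dict[str, Tensor] = {
            "W_free": P(nn.inverse_softplus(w0)),
            "agg_gamma": P(np.ones(m)), "agg_beta": P(np.zeros(m)),
            "enc1_W": P(nn.he_init(rng, m, h)), "enc1_b": P(np.zeros(h)),
            "enc1_gamma": P(np.ones(h)), "enc1_beta": P(np.zeros(h)),
            "enc2_W": P(nn.he_init(rng, h, k)), "enc2_b": P(np.zeros(k)),
            "enc2_gamma": P(np.ones(k)), "enc2_beta": P(np.zeros(k)),
            "ds_W": P(nn.he_init(rng, dec_in, h)), "ds_b": P(np.zeros(h)),
            "ds_gamma": P(np.ones(h)), "ds_beta": P(np.zeros(h)),
            "dmu_W": P(nn.he_init(rng, h, m)), "dmu_b": P(np.zeros(m)),
            "dmu_gamma": P(np.ones(m)), "dmu_beta": P(np.zeros(m)),
            "do_W": P(nn.he_init(rng, h, self.n_genes)), "do_b": P(np.zeros(self.n_genes)),
            "theta_free": P(np.full(self.n_genes, nn.inverse_softplus(1.0))),
            "q_W": P(nn.he_init(rng, m, n)), "q_b": P(np.zeros(n)),
            "q_gamma": P(np.ones(n)), "q_beta": P(np.zeros(n)),
        }
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, 29]))
        self.training = False

    # -- parameter groups ---------------------------------------------------

    def parameters(self) -> list:
        return list(self.params.values())

    def encoder_parameters(self) -> list:
        """Parameters updated during metric-learning fine-tuning: the encoder
        stack and the aggregation LayerNorm affine — never W or the decoder."""
        names = ["agg_gamma", "agg_beta",
                 "enc1_W", "enc1_b", "enc1_gamma", "enc1_beta",
                 "enc2_W", "enc2_b", "enc2_gamma", "enc2_beta"]
        return [self.params[n] for n in names]

    @property
    def weights(self) -> np.ndarray:
        """The current (pretrained) gene-to-macrogene weight matrix."""
        return np.logaddexp(0.0, self.params["W_free"].data)

    def weights_tensor(self) -> Tensor:
        return self.params["W_free"].softplus()

    # -- forward pieces -----------------------------------------------------

    def _block(self, x: Tensor, prefix: str) -> Tensor:
        p = self.params
        h = nn.linear(x, p[f"{prefix}_W"], p[f"{prefix}_b"]).relu()
        h = nn.layer_norm(h, p[f"{prefix}_gamma"], p[f"{prefix}_beta"], self.config.layernorm_eps)
        return nn.dropout(h, self.config.dropout, self._dropout_rng, self.training)

    def aggregate(self, X: np.ndarray, species: str, W: Tensor | None = None) -> Tensor:
        """Macrogene expression e = ReLU(LayerNorm(log1p(X) @ W_s))."""
        if species not in self.species_slices:
            raise KeyError(f"species {species!r} was not seen at model construction")
        W = self.weights_tensor() if W is None else W
        W_s = W[self.species_slices[species]]
        logx = Tensor(np.log1p(np.atleast_2d(np.asarray(X, dtype=np.float64))))
        h = logx @ W_s
        h = nn.layer_norm(h, self.params["agg_gamma"], self.params["agg_beta"],
                          self.config.layernorm_eps)
        return h.relu()

    def encode(self, e: Tensor) -> Tensor:
        """z = f(e): two dense blocks mapping macrogene space to the latent."""
        return self._block(self._block(e, "enc1"), "enc2")

    def embed(self, X: np.ndarray, species: str) -> Tensor:
        return self.encode(self.aggregate(X, species))

    def decode(self, z: Tensor, species: str, total_count: np.ndarray,
               W: Tensor | None = None):
        """ZINB parameters for one species' cells.

        Returns (mu, logits, theta_s).  mu rows sum to the cell's library
        size exactly (softmax times the total); a zero-library cell gets an
        all-zero mean without any division.
        """
        sl = self.species_slices[species]
        if self.config.species_conditional:
            onehot = np.zeros((z.shape[0], len(self.species_ids)))
            onehot[:, self.species_ids.index(species)] = 1.0
            z = concat([z, Tensor(onehot)], axis=1)
        hs = self._block(z, "ds")
        dmu = self._block(hs, "dmu")
        W = self.weights_tensor() if W is None else W
        logits_mu = dmu @ W[sl].T
        rho = nn.softmax_rows(logits_mu)
        total = np.asarray(total_count, dtype=np.float64).reshape(-1, 1)
        mu = rho * Tensor(total)
        O = nn.linear(hs, self.params["do_W"], self.params["do_b"])[:, sl]
        theta_s = self.params["theta_free"].softplus()[sl]
        return mu, O, theta_s

    def reconstruction_nll(self, X: np.ndarray, species: str,
                           W: Tensor | None = None) -> Tensor:
        """Per-cell ZINB negative log likelihood (vector over cells)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        e = self.aggregate(X, species, W=W)
        z = self.encode(e)
        mu, O, theta_s = self.decode(z, species, X.sum(axis=1), W=W)
        return zinb_nll(X, mu, theta_s, O)

    def encode_weights(self, W: Tensor | None = None) -> Tensor:
        """B = Q(W): encode each gene's macrogene-weight row."""
        W = self.weights_tensor() if W is None else W
        return self._block(W, "q")

    # -- evaluation-mode conveniences ----------------------------------------

    def embed_datasets(self, datasets: list[SpeciesDataset]) -> CellEmbeddingSet:
        """Deterministic (no-dropout) latent embeddings for all cells."""
        was_training, self.training = self.training, False
        try:
            chunks, species, labels, ids = [], [], [], []
            for ds in datasets:
                chunks.append(self.embed(ds.counts, ds.species_id).data)
                species.extend([ds.species_id] * ds.n_cells)
                labels.extend(ds.cell_labels)
                ids.extend(ds.cell_ids)
        finally:
            self.training = was_training
        return CellEmbeddingSet(np.vstack(chunks), np.array(species, dtype=object),
                                np.array(labels, dtype=object), ids)

    def macrogene_values(self, datasets: list[SpeciesDataset]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Evaluation-mode macrogene expression for all cells.

        Returns (values C_total × N_M, species per cell, labels per cell).
        """
        was_training, self.training = self.training, False
        try:
            vals = [self.aggregate(ds.counts, ds.species_id).data for ds in datasets]
        finally:
            self.training = was_training
        species = np.concatenate([[ds.species_id] * ds.n_cells for ds in datasets])
        labels = np.concatenate([ds.cell_labels for ds in datasets])
        return np.vstack(vals), species.astype(object), labels.astype(object)


# --------------------------------------------------------------------------
# pretraining
# --------------------------------------------------------------------------

def pretrain(model: ZinbAutoencoder, datasets: list[SpeciesDataset], P: np.ndarray,
             rng: np.random.Generator | None = None) -> list:
    """Minimize tau * L_similarity + mean ZINB NLL by seeded minibatch Adam.

    Minibatches mix cells from all species (grouped per species inside each
    batch for the species-specific forward).  One fresh gene permutation is
    drawn per optimization step for the similarity regularizer.  Returns the
    per-epoch mean training loss.
    """
    cfg = model.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % 2**31, 41]))
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    cell_species = np.concatenate([np.full(ds.n_cells, i) for i, ds in enumerate(datasets)])
    cell_row = np.concatenate([np.arange(ds.n_cells) for ds in datasets])
    n_total = len(cell_species)
    history = []
    model.training = True
    try:
        for epoch in range(cfg.pretrain_epochs):
            order = rng.permutation(n_total)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n_total, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                W = model.weights_tensor()
                nll_terms = []
                for i, ds in enumerate(datasets):
                    rows = cell_row[batch[cell_species[batch] == i]]
                    if rows.size == 0:
                        continue
                    nll_terms.append(model.reconstruction_nll(ds.counts[rows], ds.species_id, W=W).sum())
                rc = nll_terms[0]
                for t in nll_terms[1:]:
                    rc = rc + t
                loss = rc * (1.0 / len(batch))
                if cfg.tau > 0:
                    perm = rng.permutation(model.n_genes)
                    loss = loss + cfg.tau * similarity_loss(model.encode_weights(W), P, perm)
                else:
                    # keep the generator stream identical across tau settings
                    rng.permutation(model.n_genes)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"pretraining diverged (non-finite loss at epoch {epoch})"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            history.append(epoch_loss / n_batches)
            logger.info("pretrain epoch %d/%d: loss %.4f", epoch + 1, cfg.pretrain_epochs, history[-1])
    finally:
        model.training = False
    return history


def evaluate_loss(model: ZinbAutoencoder, datasets: list[SpeciesDataset], P: np.ndarray,
                  permutation: np.ndarray | None = None) -> float:
    """Full-data evaluation-mode pretraining loss (no dropout, no updates)."""
    was_training, model.training = model.training, False
    try:
        W = model.weights_tensor()
        total, n = 0.0, 0
        for ds in datasets:
            total += float(model.reconstruction_nll(ds.counts, ds.species_id, W=W).sum().data)
            n += ds.n_cells
        loss = total / n
        if model.config.tau > 0:
            perm = permutation if permutation is not None else np.arange(model.n_genes)
            loss += model.config.tau * float(similarity_loss(model.encode_weights(W), P, perm).data)
    finally:
        model.training = was_training
    return loss


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(model: ZinbAutoencoder, path) -> None:
    """Write named parameter arrays, the config snapshot and the gene index."""
    with h5py.File(path, "w") as fh:
        g = fh.create_group("params")
        for name, p in model.params.items():
            g.create_dataset(name, data=p.data)
        fh.attrs["config"] = json.dumps(model.config.to_dict())
        fh.attrs["species_ids"] = json.dumps(model.species_ids)
        fh.create_dataset("gene_species", data=np.array([s for s, _ in model.gene_index], dtype="S"))
        fh.create_dataset("gene_ids", data=np.array([g_ for _, g_ in model.gene_index], dtype="S"))


def load_checkpoint(path) -> ZinbAutoencoder:
    with h5py.File(path, "r") as fh:
        cfg = TrainingConfig(**json.loads(fh.attrs["config"]))
        species_ids = json.loads(fh.attrs["species_ids"])
        gene_index = [(s.decode(), g.decode())
                      for s, g in zip(fh["gene_species"][:], fh["gene_ids"][:])]
        param_data = {name: fh["params"][name][:] for name in fh["params"]}
    n_m = param_data["agg_gamma"].shape[0]
    shell = MacrogeneModel(
        centroids=np.zeros((n_m, 1)),
        weights=np.logaddexp(0.0, param_data["W_free"]),
        rank_distance=np.ones((len(gene_index), n_m), dtype=int),
        gene_index=gene_index,
    )
    model = ZinbAutoencoder(shell, cfg, species_ids=species_ids)
    for name, data in param_data.items():
        model.params[name].data = data
    return model
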