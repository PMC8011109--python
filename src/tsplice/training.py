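"""Training of the tissue-specific splicing network.

The objective is the masked Kullback–Leibler divergence between measured and
predicted inclusion levels, treating Ψ as the probability that a transcript
includes the exon:

    Loss = 1/(T·E) Σ_t Σ_e γ_e,t [ Ψ log(Ψ/Ψ̂) + (1−Ψ) log((1−Ψ)/(1−Ψ̂)) ]

with γ_e,t = 1 where Ψ_e,t is observed and 0 otherwise. The denominator is
the full T·E product even when entries are masked. Predictions enter as
Ψ̂ = σ(net output + logit(Ψ̄_e)), so the network only has to learn deviations
from the tissue average. Measured Ψ is clipped to [1e-5, 1−1e-5].

Several independently initialized networks are combined by forward ensemble
selection: models are sorted by validation loss and greedily added to a
running average (on the Δ_tissue logit scale) while the ensemble's validation
loss strictly improves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data_model import EncodedExon, PsiMatrix, clip_psi, encode, extract_regions, logit, sigmoid
from .network import TSpliceConfig, TSpliceNet, build_network

__all__ = [
    "TrainConfig",
    "SpliceDataset",
    "Ensemble",
    "masked_kl_loss",
    "fit",
    "select_ensemble",
    "train_ensemble",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    n_restarts: int = 20

    def __post_init__(self):
        for name in ("batch_size", "max_epochs", "patience", "n_restarts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class SpliceDataset:
    """Training tuples: one-hot inputs, Ψ targets, observation mask, Ψ̄.

    ``x``: (N, 2, 400, 4) float32; ``psi``: (N, T) with NaN at masked
    entries; ``mask``: (N, T) bool; ``psi_bar``: (N,) per-exon tissue-average
    Ψ on the natural scale.
    """

    x: np.ndarray
    psi: np.ndarray
    mask: np.ndarray
    psi_bar: np.ndarray

    def __post_init__(self):
        n = self.x.shape[0]
        if not (self.psi.shape[0] == self.mask.shape[0] == self.psi_bar.shape[0] == n):
            raise ValueError("dataset arrays disagree on the number of exons")

    def __len__(self):
        return self.x.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.psi.shape[1]

    def subset(self, idx) -> "SpliceDataset":
        idx = np.asarray(idx, dtype=np.intp)
        return SpliceDataset(self.x[idx], self.psi[idx], self.mask[idx], self.psi_bar[idx])

    @classmethod
    def from_psi_matrix(cls, exons, genome, psi: PsiMatrix) -> "SpliceDataset":
        """Build a dataset by extracting/encoding regions for each exon.

        Exons are matched to Ψ rows by exon_id; exons absent from the table
        are dropped with a warning.
        """
        index = {eid: i for i, eid in enumerate(psi.exon_ids)}
        keep = [e for e in exons if e.exon_id in index]
        if len(keep) < len(list(exons)):
            warnings.warn(f"{len(list(exons)) - len(keep)} exons missing from the Ψ table; dropped")
        x = np.stack([encode(extract_regions(e, genome)).stacked() for e in keep])
        rows = np.array([index[e.exon_id] for e in keep])
        sub = psi.subset(rows)
        return cls(
            x.astype(np.float32),
            sub.psi,
            sub.mask,
            sub.tissue_averages(),
        )


def masked_kl_loss(psi, psi_hat, mask) -> float:
    """Masked KL divergence between measured and predicted Ψ.

    Masked entries contribute zero to the numerator; the denominator is the
    full number of (exon, tissue) cells.
    """
    psi = np.asarray(psi, dtype=float)
    psi_hat = np.asarray(psi_hat, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if psi.shape != psi_hat.shape or psi.shape != mask.shape:
        raise ValueError("psi, psi_hat and mask must share a shape")
    p = clip_psi(np.where(mask, psi, 0.5))
    q = psi_hat
    terms = p * (np.log(p) - np.log(q)) + (1 - p) * (np.log1p(-p) - np.log1p(-q))
    return float(np.where(mask, terms, 0.0).sum() / psi.size)


def _forward_loss(net: TSpliceNet, data: SpliceDataset, batch_size: int = 256) -> float:
    """Full-dataset masked KL loss in inference mode."""
    total = 0.0
    offset = logit(clip_psi(data.psi_bar))
    for lo in range(0, len(data), batch_size):
        hi = min(lo + batch_size, len(data))
        out = net.predict(data.x[lo:hi])
        psi_hat = sigmoid(out + offset[lo:hi, None])
        total += masked_kl_loss(data.psi[lo:hi], psi_hat, data.mask[lo:hi]) * (hi - lo)
    return total / len(data)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.t = 0

    def step(self, net: TSpliceNet, grads: dict[str, np.ndarray]):
        self.t += 1
        c = self.cfg
        params = net.trainable_parameters()
        bc1 = 1 - c.adam_beta1**self.t
        bc2 = 1 - c.adam_beta2**self.t
        for name, g in grads.items():
            g = g.astype(np.float64)
            self.m[name] = c.adam_beta1 * self.m[name] + (1 - c.adam_beta1) * g
            self.v[name] = c.adam_beta2 * self.v[name] + (1 - c.adam_beta2) * g * g
            update = (
                c.learning_rate * (self.m[name] / bc1) / (np.sqrt(self.v[name] / bc2) + c.adam_eps)
            )
            net.set_parameter(name, params[name] - update.astype(np.float32))


def fit(
    net: TSpliceNet,
    train: SpliceDataset,
    val: SpliceDataset,
    config: TrainConfig | None = None,
) -> dict:
    """Train a network with Adam on the masked KL objective.

    Early stopping monitors the validation loss with the configured patience;
    the parameter state with the best validation loss is restored before
    returning. Returns a history dict with per-epoch train/val losses.
    """
    config = config or TrainConfig()
    if len(train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = _Adam(net.trainable_parameters(), config)
    t_clip = clip_psi(np.where(train.mask, train.psi, 0.5))
    offset = logit(clip_psi(train.psi_bar)).astype(np.float32)
    n_tissues = train.n_tissues
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = net.state_dict()
    best_epoch = -1
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train))
        batch_losses = []
        for lo in range(0, len(train), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            out, cache = net._forward(train.x[idx], training=True)
            z = out + offset[idx, None]
            psi_hat = sigmoid(z)
            p = t_clip[idx]
            mask = train.mask[idx]
            terms = p * (np.log(p) - np.log(psi_hat)) + (1 - p) * (
                np.log1p(-p) - np.log1p(-psi_hat)
            )
            loss = float(np.where(mask, terms, 0.0).sum() / (len(idx) * n_tissues))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}; aborting"
                )
            batch_losses.append(loss)
            dz = (np.where(mask, psi_hat - p, 0.0) / (len(idx) * n_tissues)).astype(np.float32)
            grads, _ = net._backward(cache, dz)
            opt.step(net, grads)
        val_loss = _forward_loss(net, val)
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.state_dict()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break
    net.load_state_dict(best_state)
    history["best_val_loss"] = best_val
    history["best_epoch"] = best_epoch
    return history


@dataclass
class Ensemble:
    """Averages member predictions on the Δ_tissue logit scale."""

    members: list

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble must have at least one member")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.mean([m.predict(x) for m in self.members], axis=0)

    def forward(self, encoded: EncodedExon) -> np.ndarray:
        return self.predict(encoded.stacked()[None])[0]

    def input_gradient(self, encoded: EncodedExon, target="mean") -> np.ndarray:
        return np.mean([m.input_gradient(encoded, target) for m in self.members], axis=0)


def _ensemble_loss(outputs: list[np.ndarray], data: SpliceDataset) -> float:
    mean_out = np.mean(outputs, axis=0)
    psi_hat = sigmoid(mean_out + logit(clip_psi(data.psi_bar))[:, None])
    return masked_kl_loss(data.psi, psi_hat, data.mask)


def select_ensemble(models: list[TSpliceNet], val: SpliceDataset) -> Ensemble:
    """Forward ensemble selection on validation loss.

    Models are sorted by ascending validation loss and added one at a time to
    the running average while the ensemble validation loss strictly improves;
    selection stops at the first non-improvement.
    """
    if not models:
        raise ValueError("need at least one model")
    outputs = [
        np.concatenate(
            [m.predict(val.x[lo : lo + 256]) for lo in range(0, len(val), 256)]
        )
        for m in models
    ]
    losses = [_ensemble_loss([o], val) for o in outputs]
    order = np.argsort(losses, kind="stable")
    selected = [order[0]]
    best = losses[order[0]]
    for i in order[1:]:
        candidate = selected + [int(i)]
        loss = _ensemble_loss([outputs[j] for j in candidate], val)
        if loss < best:
            best = loss
            selected = candidate
        else:
            break
    return Ensemble([models[i] for i in selected])


def train_ensemble(
    net_config: TSpliceConfig,
    train: SpliceDataset,
    val: SpliceDataset,
    config: TrainConfig | None = None,
) -> tuple[Ensemble, list[dict]]:
    """Train ``n_restarts`` networks from different initializations and build
    the forward-selected ensemble."""
    config = config or TrainConfig()
    models, histories = [], []
    for i in range(config.n_restarts):
        net = build_network(replace(net_config, seed=net_config.seed + i))
        hist = fit(net, train, val, replace(config, seed=config.seed + i))
        models.append(net)
        histories.append(hist)
    return select_ensemble(models, val), histories
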