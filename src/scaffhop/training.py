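"""VAE loss terms, KL weight annealing, and the pretrain/fine-tune loop."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .chem import MolScaffoldPair
from .config import ModelConfig, TrainConfig
from .decoder import UnknownTokenError, Vocabulary, pad_batch, tokenize
from .encoder import LatentPosterior
from .model import ScaffoldVAE
from .nn import Adam, Tensor, clip_grad_norm, concat

__all__ = [
    "LossBreakdown",
    "reconstruction_loss",
    "kl_loss",
    "beta_schedule",
    "train",
    "write_loss_log",
]


@dataclass(frozen=True)
class LossBreakdown:
    epoch: int
    recon: float
    kl: float
    beta: float

    @property
    def total(self) -> float:
        return self.recon + self.beta * self.kl


def reconstruction_loss(logits: Tensor, targets: np.ndarray, pad_idx: int) -> Tensor:
    """Mean token-level cross-entropy (nats) over non-PAD target positions.

    logits: batch x T x V; targets: batch x T integer matrix.
    """
    b, t, v = logits.data.shape
    if targets.shape != (b, t):
        raise ValueError(f"target shape {targets.shape} does not match logits {(b, t)}")
    mask = targets != pad_idx
    n_tokens = int(mask.sum())
    if n_tokens == 0:
        raise ValueError("all target positions are PAD")
    onehot = np.zeros((b, t, v))
    bb, tt = np.nonzero(mask)
    onehot[bb, tt, targets[bb, tt]] = 1.0
    logp = logits.log_softmax(axis=-1)
    return -(logp * Tensor(onehot)).sum() / n_tokens


def kl_loss(post: LatentPosterior) -> Tensor:
    """Closed-form KL(q || N(0, I)) = 1/2 sum(mu^2 + sigma^2 - 1 - log sigma^2)."""
    if np.any(post.sigma.data <= 0):
        raise ValueError("sigma must be elementwise positive")
    d = post.d_z
    return ((post.mu.square() + post.sigma.square()).sum() - d) * 0.5 - post.sigma.log().sum()


def beta_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Linear ramp from beta_start (epoch 0) to beta_end (final epoch)."""
    if not 0 <= epoch < max(cfg.epochs, 1):
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    if cfg.epochs <= 1:
        return cfg.beta_end
    frac = epoch / (cfg.epochs - 1)
    return cfg.beta_start + (cfg.beta_end - cfg.beta_start) * frac


def _check_vocabulary(pairs: Sequence[MolScaffoldPair], vocab: Vocabulary) -> None:
    for p in pairs:
        for tok in tokenize(p.scaffold.smiles):
            if tok not in vocab.index:
                raise UnknownTokenError(
                    f"token {tok!r} of scaffold {p.scaffold.smiles!r} not in vocabulary"
                )


def train(
    pairs: Sequence[MolScaffoldPair],
    cfg: TrainConfig,
    model_cfg: Optional[ModelConfig] = None,
    init: Optional[ScaffoldVAE] = None,
    mode: str = "pretrain",
) -> Tuple[ScaffoldVAE, List[LossBreakdown]]:
    """Run the training loop; returns the trained model and per-epoch losses.

    ``mode='finetune'`` warm-starts from `init` (required) at the reduced
    learning rate; the loss is unchanged between the two phases.
    """
    if not pairs:
        raise ValueError("empty pair dataset")
    if mode not in ("pretrain", "finetune"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "finetune" and init is None:
        raise ValueError("fine-tuning requires an initial checkpoint")
    if init is not None:
        model = init
        _check_vocabulary(pairs, model.vocab)
    else:
        vocab = Vocabulary.from_corpus([p.scaffold.smiles for p in pairs])
        model = ScaffoldVAE(model_cfg or ModelConfig(), vocab, seed=cfg.seed)
    lr = cfg.finetune_lr if mode == "finetune" else cfg.lr
    opt = Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(cfg.seed)
    encoded = [model.vocab.encode(p.scaffold.smiles) for p in pairs]
    log: List[LossBreakdown] = []
    for epoch in range(cfg.epochs):
        beta = beta_schedule(epoch, cfg)
        order = rng.permutation(len(pairs))
        recon_sum = kl_sum = 0.0
        n_batches = 0
        for start in range(0, len(pairs), cfg.batch_size):
            batch_idx = order[start : start + cfg.batch_size]
            conds = []
            posts = []
            for i in batch_idx:
                cond, post = model.training_condition(pairs[i], rng)
                conds.append(cond.reshape(1, -1))
                posts.append(post)
            cond_mat = concat(conds, axis=0)
            tokens = pad_batch([encoded[i] for i in batch_idx], model.vocab.pad)
            logits = model.decoder.teacher_forced_logits(cond_mat, tokens)
            recon = reconstruction_loss(logits, tokens[:, 1:], model.vocab.pad)
            kl_terms = [kl_loss(p) for p in posts]
            kl = kl_terms[0]
            for term in kl_terms[1:]:
                kl = kl + term
            kl = kl / len(kl_terms)
            total = recon + beta * kl
            opt.zero_grad()
            total.backward()
            clip_grad_norm(model.parameters(), cfg.grad_clip)
            opt.step()
            recon_sum += recon.item()
            kl_sum += kl.item()
            n_batches += 1
        log.append(
            LossBreakdown(
                epoch=epoch,
                recon=recon_sum / n_batches,
                kl=kl_sum / n_batches,
                beta=beta,
            )
        )
    return model, log


def write_loss_log(log: Sequence[LossBreakdown], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "L_recon", "L_kl", "beta", "total"])
        for entry in log:
            w.writerow([entry.epoch, entry.recon, entry.kl, entry.beta, entry.total])
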