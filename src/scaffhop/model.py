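"""The full scaffold VAE: encoder + conditional GRU decoder + checkpoint IO."""

from __future__ import annotations

import hashlib
import json
import os
from typing import List, Optional, Tuple

import numpy as np

from .chem import MolScaffoldPair
from .config import ModelConfig
from .decoder import ScaffoldDecoder, Vocabulary
from .encoder import LatentPosterior, MolEncoder, SplitEmbedding, featurize
from .nn import Module, Tensor, concat

__all__ = ["ScaffoldVAE", "save_checkpoint", "load_checkpoint"]


class ScaffoldVAE(Module):
    def __init__(self, cfg: ModelConfig, vocab: Vocabulary, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.vocab = vocab
        self.encoder = MolEncoder(cfg.encoder, rng)
        cond_len = self.encoder.embedding_len + cfg.encoder.d_z
        self.decoder = ScaffoldDecoder(cfg.decoder, len(vocab), cond_len, rng)

    # -- encoding -------------------------------------------------------------

    def encode_pair(self, pair: MolScaffoldPair) -> Tuple[SplitEmbedding, LatentPosterior]:
        g = featurize(pair.molecule.smiles)
        return self.encoder(g, pair.scaffold_atom_indices)

    def training_condition(
        self, pair: MolScaffoldPair, rng: np.random.Generator
    ) -> Tuple[Tensor, LatentPosterior]:
        """Reparameterized conditioning vector z = mu + sigma * eps."""
        split, post = self.encode_pair(pair)
        eps = rng.standard_normal(post.d_z)
        z = post.mu + post.sigma * Tensor(eps)
        cond = concat([split.z_side, z])
        return cond, post

    def inference_condition(
        self,
        pair: MolScaffoldPair,
        rng: Optional[np.random.Generator] = None,
        sigma_mode: str = "literal",
    ) -> np.ndarray:
        """Conditioning vector for sampling (no tape). See assembly.resample_h0."""
        from .assembly import resample_h0
        from .nn import no_grad

        with no_grad():
            split, post = self.encode_pair(pair)
        return resample_h0(split.z_side.data, post.mu.data, post.sigma.data, rng=rng, sigma_mode=sigma_mode)

    # -- greedy reconstruction (diagnostics / overfit tests) ------------------

    def greedy_reconstruct(self, pair: MolScaffoldPair) -> str:
        from .nn import no_grad

        with no_grad():
            split, post = self.encode_pair(pair)
            cond = np.concatenate([split.z_side.data, post.mu.data])
        return self.decoder.sample_sequence(cond, self.vocab, greedy=True)


def _config_hash(cfg: ModelConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _vocab_hash(vocab: Vocabulary) -> str:
    return hashlib.sha256(json.dumps(vocab.tokens).encode()).hexdigest()[:16]


def save_checkpoint(model: ScaffoldVAE, path: str) -> None:
    """Write `<path>.npz` (parameters) and `<path>.json` (config + vocabulary)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)) or ".", exist_ok=True)
    np.savez(path + ".npz", **model.state_dict())
    sidecar = {
        "config": model.cfg.to_dict(),
        "vocabulary": model.vocab.tokens,
        "config_hash": _config_hash(model.cfg),
        "vocab_hash": _vocab_hash(model.vocab),
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path: str) -> ScaffoldVAE:
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    cfg = ModelConfig.from_dict(sidecar["config"])
    vocab = Vocabulary(sidecar["vocabulary"])
    model = ScaffoldVAE(cfg, vocab)
    with np.load(path + ".npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
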