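"""SMILES tokenization, vocabulary, and the GRU scaffold decoder."""

from __future__ import annotations

import json
import re
from typing import List, Optional, Sequence

import numpy as np

from .config import DecoderConfig
from .nn import Embedding, GRUStack, Linear, Module, Tensor

__all__ = [
    "BOS",
    "EOS",
    "PAD",
    "Vocabulary",
    "tokenize",
    "ScaffoldDecoder",
    "UnknownTokenError",
]

BOS, EOS, PAD = "<bos>", "<eos>", "<pad>"
RESERVED = [PAD, BOS, EOS]

_TOKEN_RE = re.compile(r"(\[[^\]]*\]|Br|Cl|%\d{2}|.)")


class UnknownTokenError(KeyError):
    pass


def tokenize(s: str) -> List[str]:
    """Split a SMILES string into tokens.

    Bracket atoms, two-letter halogens and %NN ring closures are single
    tokens; everything else is one character. The concatenation of the
    returned tokens reproduces the input exactly.
    """
    if not s:
        raise ValueError("empty SMILES string")
    if s.count("[") != s.count("]"):
        raise ValueError(f"unbalanced brackets in {s!r}")
    tokens = _TOKEN_RE.findall(s)
    if "".join(tokens) != s:
        raise ValueError(f"tokenization failed for {s!r}")
    if any(t == "[" or t == "]" for t in tokens):
        raise ValueError(f"unterminated bracket atom in {s!r}")
    return tokens


class Vocabulary:
    """Bijective token <-> index map with fixed reserved slots."""

    def __init__(self, tokens: Sequence[str]):
        if list(tokens[: len(RESERVED)]) != RESERVED:
            tokens = RESERVED + [t for t in tokens if t not in RESERVED]
        self.tokens = list(tokens)
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __eq__(self, other) -> bool:
        return isinstance(other, Vocabulary) and self.tokens == other.tokens

    @property
    def pad(self) -> int:
        return self.index[PAD]

    @property
    def bos(self) -> int:
        return self.index[BOS]

    @property
    def eos(self) -> int:
        return self.index[EOS]

    @classmethod
    def from_corpus(cls, corpus: Sequence[str]) -> "Vocabulary":
        if not corpus:
            raise ValueError("empty corpus")
        seen = set()
        for smi in corpus:
            seen.update(tokenize(smi))
        return cls(RESERVED + sorted(seen))

    def encode(self, smiles: str, add_bos_eos: bool = True) -> List[int]:
        idx = []
        for t in tokenize(smiles):
            if t not in self.index:
                raise UnknownTokenError(f"token {t!r} (in {smiles!r}) not in vocabulary")
            idx.append(self.index[t])
        if add_bos_eos:
            idx = [self.bos] + idx + [self.eos]
        return idx

    def decode(self, indices: Sequence[int]) -> str:
        out = []
        for i in indices:
            if i == self.eos:
                break
            if i in (self.bos, self.pad):
                continue
            out.append(self.tokens[i])
        return "".join(out)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.tokens, fh)

    @classmethod
    def load(cls, path: str) -> "Vocabulary":
        with open(path) as fh:
            return cls(json.load(fh))


def pad_batch(sequences: List[List[int]], pad_idx: int) -> np.ndarray:
    max_len = max(len(s) for s in sequences)
    out = np.full((len(sequences), max_len), pad_idx, dtype=np.intp)
    for i, s in enumerate(sequences):
        out[i, : len(s)] = s
    return out


class ScaffoldDecoder(Module):
    """Embedding + multi-layer GRU + output projection over the vocabulary.

    The conditioning vector (concat of side-chain embedding and scaffold
    latent) is mapped by a linear bridge to the hidden size and used to
    initialize every GRU layer.
    """

    def __init__(self, cfg: DecoderConfig, vocab_size: int, cond_len: int, rng: np.random.Generator):
        self.cfg = cfg
        self.vocab_size = vocab_size
        self.cond_len = cond_len
        self.embedding = Embedding(vocab_size, cfg.d_embed, rng)
        self.bridge = Linear(cond_len, cfg.d_hidden, rng)
        self.gru = GRUStack(cfg.d_embed, cfg.d_hidden, cfg.n_layers, rng)
        self.out_proj = Linear(cfg.d_hidden, vocab_size, rng)

    def initial_state(self, cond: Tensor) -> List[Tensor]:
        """cond: batch x cond_len -> list of per-layer hidden states."""
        h0 = self.bridge(cond).tanh()
        return [h0 for _ in range(self.cfg.n_layers)]

    def teacher_forced_logits(self, cond: Tensor, tokens: np.ndarray) -> Tensor:
        """Logits for steps 1..T-1 of `tokens` (batch x T int matrix that
        starts with BOS). Output: batch x (T-1) x V stacked as a list of
        per-step (batch x V) tensors concatenated on a new axis via reshape."""
        b, t_total = tokens.shape
        if t_total - 1 > self.cfg.max_len:
            raise ValueError(f"sequence length {t_total - 1} exceeds max_len {self.cfg.max_len}")
        hs = self.initial_state(cond)
        step_logits = []
        for t in range(t_total - 1):
            x = self.embedding(tokens[:, t])
            out, hs = self.gru.step(x, hs)
            step_logits.append(self.out_proj(out))
        from .nn import concat as cat

        stacked = cat([sl.reshape(b, 1, self.vocab_size) for sl in step_logits], axis=1)
        return stacked

    # -- fast inference (plain NumPy, no tape) --------------------------------

    def _np_step(self, x: np.ndarray, hs: List[np.ndarray]) -> tuple:
        new_hs = []
        inp = x
        for cell, h in zip(self.gru.layers, hs):
            f = _sigmoid(inp @ cell.Wf.data + h @ cell.Uf.data + cell.bf.data)
            r = _sigmoid(inp @ cell.Wr.data + h @ cell.Ur.data + cell.br.data)
            hhat = np.tanh(inp @ cell.Wh.data + (r * h) @ cell.Uh.data + cell.bh.data)
            h = (1 - f) * h + f * hhat
            new_hs.append(h)
            inp = h
        return inp, new_hs

    def sample_sequence(
        self,
        cond: np.ndarray,
        vocab: Vocabulary,
        max_len: Optional[int] = None,
        temperature: float = 1.0,
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        greedy: bool = False,
    ) -> str:
        """Autoregressively sample one token sequence and decode it to SMILES.

        `temperature` scales the logits before softmax; `greedy=True` (or the
        temperature -> 0 limit) takes the argmax at each step.
        """
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        if rng is None:
            rng = np.random.default_rng(seed)
        max_len = max_len or self.cfg.max_len
        h0 = np.tanh(cond.reshape(1, -1) @ self.bridge.W.data + self.bridge.b.data)
        hs = [h0 for _ in range(self.cfg.n_layers)]
        token = vocab.bos
        out_tokens: List[int] = []
        for _ in range(max_len):
            x = self.embedding.table.data[np.asarray([token])]
            out, hs = self._np_step(x, hs)
            logits = (out @ self.out_proj.W.data + self.out_proj.b.data).ravel()
            logits[vocab.pad] = -np.inf  # PAD is never a legal emission
            if greedy:
                token = int(np.argmax(logits))
            else:
                z = logits / temperature
                z = z - z.max()
                p = np.exp(z)
                p /= p.sum()
                token = int(rng.choice(len(p), p=p))
            if token == vocab.eos:
                break
            out_tokens.append(token)
        return vocab.decode(out_tokens)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
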