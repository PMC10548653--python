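"""Configuration dataclasses shared across modules."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Optional

import yaml


@dataclass
class PrepConfig:
    """Molecule standardization / filtering limits.

    Weight and heavy-atom bounds default to ``None`` (disabled) so that small
    test molecules pass; ``chembl_like()`` gives drug-like corpus bounds.
    """

    mol_weight_min: Optional[float] = None
    mol_weight_max: Optional[float] = None
    n_heavy_min: Optional[int] = None
    n_heavy_max: Optional[int] = None
    apply_structural_filters: bool = True
    extra_filter_smarts: Optional[str] = None  # path to a SMARTS file, one per line

    @classmethod
    def chembl_like(cls) -> "PrepConfig":
        return cls(mol_weight_min=200.0, mol_weight_max=600.0, n_heavy_min=10, n_heavy_max=50)


@dataclass
class ScaffoldFilterConfig:
    max_heavy_atoms: int = 20
    max_rotatable_bonds: int = 3


@dataclass
class EncoderConfig:
    h_node: int = 128
    h_edge: int = 128
    n_layers: int = 3
    r_heads: int = 4
    d_attn: int = 64
    d_z: int = 128


@dataclass
class DecoderConfig:
    d_embed: int = 128
    d_hidden: int = 512
    n_layers: int = 3
    max_len: int = 100


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)

    @classmethod
    def small(cls) -> "ModelConfig":
        """A desk-scale configuration for tests and smoke runs."""
        return cls(
            encoder=EncoderConfig(h_node=32, h_edge=32, n_layers=2, r_heads=2, d_attn=16, d_z=16),
            decoder=DecoderConfig(d_embed=32, d_hidden=128, n_layers=1, max_len=60),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(encoder=EncoderConfig(**d["encoder"]), decoder=DecoderConfig(**d["decoder"]))


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 64
    lr: float = 1e-3
    finetune_lr: float = 1e-4
    beta_start: float = 0.0
    beta_end: float = 1.0
    seed: int = 0
    grad_clip: float = 5.0
    checkpoint_every: int = 0  # 0 = only final checkpoint

    def __post_init__(self):
        if self.finetune_lr >= self.lr:
            raise ValueError("fine-tune learning rate must be smaller than the pretraining rate")

    def to_dict(self) -> dict:
        return asdict(self)


def load_yaml_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def train_config_from_dict(d: dict) -> TrainConfig:
    known = {f.name for f in fields(TrainConfig)}
    return TrainConfig(**{k: v for k, v in d.items() if k in known})
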