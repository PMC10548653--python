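import numpy as np
import pytest

from scaffhop.chem import build_pair_dataset, standardize_molecule
from scaffhop.chem.standardize import MoleculeRecord
from scaffhop.config import ModelConfig, TrainConfig
from scaffhop.fixtures import FixtureSpec, generate_corpus
from scaffhop.training import train


@pytest.fixture(scope="session")
def fixture_corpus():
    return generate_corpus(FixtureSpec(seed=11, n_molecules=60, only_passing_cores=True))


@pytest.fixture(scope="session")
def fixture_records(fixture_corpus):
    recs = [standardize_molecule(m.smiles, mol_id=m.mol_id) for m in fixture_corpus]
    return [r for r in recs if isinstance(r, MoleculeRecord)]


@pytest.fixture(scope="session")
def fixture_pairs(fixture_records):
    pairs, _ = build_pair_dataset(fixture_records, mode="pretrain", seed=5)
    return pairs


@pytest.fixture(scope="session")
def trained_model(fixture_pairs):
    """A small model trained enough to produce mostly-valid scaffolds."""
    cfg = TrainConfig(
        epochs=60, batch_size=16, lr=5e-3, finetune_lr=5e-4,
        beta_start=0.0, beta_end=0.02, seed=0,
    )
    model, log = train(fixture_pairs, cfg, model_cfg=ModelConfig.small())
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(0)
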