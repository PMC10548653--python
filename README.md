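# scaffhop

Scaffold hopping for small molecules with a graph variational autoencoder.

A molecule is encoded by a **multi-view message-passing network** (one pass
centred on atoms, one on directed bonds), split by a scaffold atom mask into a
fixed-length **scaffold embedding** and **side-chain embedding** via structured
self-attention readout, and the scaffold embedding is projected to a latent
Gaussian. A **GRU decoder**, conditioned on the concatenation of the side-chain
embedding and a (re)sampled scaffold latent, generates scaffold SMILES token by
token. Generated scaffolds are reassembled with the reference molecule's side
chains by enumerating valence-eligible attachment sites and keeping the
candidate most similar to the reference by path-based fingerprint Tanimoto.
Outputs are scored with two metric families: general generation metrics
(validity, uniqueness@k, novelty, filter pass rate, scaffold uniqueness and
novelty) and scaffold-hopping metrics (active mean/rate, hop rate, success
rate) with activity scoring behind a pluggable interface (a deterministic mock
scorer ships with the package).

All neural components run on a small NumPy reverse-mode autodiff engine
(`scaffhop.nn`) — no deep-learning framework is required. Chemistry is handled
by RDKit.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks the closed-form KL
against Monte Carlo, message passing against a nested-loop oracle on all
connected graphs of ≤5 nodes, exhaustive permutation invariance of the
embeddings, a hand-labeled 30-scaffold filter truth table, a 1000-molecule
decompose/reassemble round trip, a 32-pair overfit-reconstruction run, metric
oracle equivalence, and an end-to-end smoke pipeline. The full run takes a few
minutes on one CPU.

## CLI

The pipeline is exposed as a `scaffhop` command group:

```bash
# 1. synthetic corpus with known scaffold/side-chain ground truth
scaffhop fixtures --n 200 --seed 7 --out fixtures/

# 2. standardize + scaffold extraction + filtering -> molecule-scaffold pairs
scaffhop prepare --input fixtures/corpus.smi --mode pretrain --seed 0 \
    --out pairs.tsv --report prep.json

# 3. train (config YAML holds train/model sections; see tests for an example)
scaffhop pretrain --pairs pairs.tsv --config cfg.yaml --out ckpt/
scaffhop finetune --init ckpt/model --pairs target_pairs.tsv --out ckpt_ft/

# 4. sample new scaffolds for a reference molecule and reattach its side chains
scaffhop sample --model ckpt/model --reference ref.smi --scaffold "c1ccncc1" \
    --n 5000 --seed 1 --out generated.tsv

# 5. evaluate
scaffhop evaluate --generated generated.tsv --train pairs.tsv \
    --reference ref.smi --scorer mock --top 0.1 --out report.json
```

Scaffold filtering keeps scaffolds with at least one non-benzene ring, at most
20 heavy atoms and at most 3 rotatable bonds. `prepare --mode pretrain` picks
one passing scaffold per molecule at random; `--mode finetune` keeps every
passing scaffold.

## Package layout

- `scaffhop.chem` — SMILES standardization, scaffold hierarchy extraction
  (Bemis–Murcko plus iterative peripheral-ring deletion), the scaffold filter,
  and molecule–scaffold pair datasets.
- `scaffhop.encoder` — graph featurization and the multi-view MPNN encoder with
  masked attention readout and latent heads.
- `scaffhop.decoder` — SMILES tokenizer, vocabulary, and the conditional GRU
  decoder (teacher forcing and autoregressive sampling).
- `scaffhop.training` — reconstruction/KL losses, β-annealing, and the
  pretrain/fine-tune loop with checkpointing.
- `scaffhop.assembly` — latent resampling, side-chain decomposition,
  attachment enumeration, candidate selection, and the end-to-end `hop`.
- `scaffhop.metrics` — GEM/SEM reports, `hop_check`, and the scorer interface.
- `scaffhop.fixtures` — deterministic synthetic corpora with ground truth.
- `scaffhop.nn` — the autograd engine, layers (Linear/Embedding/GRU), Adam.
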