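"""Molecule-scaffold pair datasets and their TSV serialization."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np

from ..config import ScaffoldFilterConfig
from .scaffolds import (
    ScaffoldRecord,
    extract_scaffold_hierarchy,
    filter_scaffold,
    scaffold_atom_mask,
    scaffold_record_from_smiles,
)
from .standardize import MoleculeRecord

__all__ = [
    "MolScaffoldPair",
    "build_pair_dataset",
    "write_pairs_tsv",
    "read_pairs_tsv",
    "read_smi_file",
]

PAIRS_HEADER = ["mol_id", "mol_smiles", "scaffold_smiles", "scaffold_atoms"]


@dataclass(frozen=True)
class MolScaffoldPair:
    molecule: MoleculeRecord
    scaffold: ScaffoldRecord
    scaffold_atom_indices: Tuple[int, ...]

    def __post_init__(self):
        idx = self.scaffold_atom_indices
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate scaffold atom indices")


def build_pair_dataset(
    mols: Iterable[MoleculeRecord],
    mode: str,
    seed: int = 0,
    filter_cfg: Optional[ScaffoldFilterConfig] = None,
) -> Tuple[List[MolScaffoldPair], int]:
    """Build (pairs, n_dropped).

    ``pretrain``: one uniformly chosen passing scaffold per molecule.
    ``finetune``: one pair per (molecule, passing scaffold).
    Molecules without any passing scaffold are dropped and counted.
    """
    if mode not in ("pretrain", "finetune"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    pairs: List[MolScaffoldPair] = []
    dropped = 0
    for mol in mols:
        passing = [s for s in extract_scaffold_hierarchy(mol) if filter_scaffold(s, filter_cfg)]
        if not passing:
            dropped += 1
            continue
        chosen = [passing[rng.integers(len(passing))]] if mode == "pretrain" else passing
        for s in chosen:
            pairs.append(MolScaffoldPair(mol, s, scaffold_atom_mask(mol, s)))
    return pairs, dropped


def write_pairs_tsv(pairs: Iterable[MolScaffoldPair], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(PAIRS_HEADER)
        for p in pairs:
            w.writerow(
                [
                    p.molecule.id,
                    p.molecule.smiles,
                    p.scaffold.smiles,
                    ",".join(str(i) for i in p.scaffold_atom_indices),
                ]
            )


def read_pairs_tsv(path: str) -> List[MolScaffoldPair]:
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    pairs = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != PAIRS_HEADER:
            raise ValueError(f"unexpected pairs TSV header: {header}")
        for row in reader:
            mol_id, mol_smiles, scaffold_smiles, atoms = row
            mol = Chem.MolFromSmiles(mol_smiles)
            if mol is None:
                raise ValueError(f"unparsable molecule in pairs TSV: {mol_smiles!r}")
            rec = MoleculeRecord(
                id=mol_id,
                smiles=Chem.MolToSmiles(mol),
                n_heavy=mol.GetNumHeavyAtoms(),
                mol_weight=round(Descriptors.MolWt(mol), 3),
            )
            scaffold = scaffold_record_from_smiles(scaffold_smiles)
            idx = tuple(int(i) for i in atoms.split(",")) if atoms else ()
            pairs.append(MolScaffoldPair(rec, scaffold, idx))
    return pairs


def read_smi_file(path: str) -> List[Tuple[str, str]]:
    """Read a .smi file -> list of (smiles, id). '#' comment lines ignored."""
    out = []
    with open(path) as fh:
        for n, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{n}"
            out.append((smiles, mol_id))
    return out


def write_prep_report(path: str, n_in: int, n_ok: int, rejections: dict, n_dropped_no_scaffold: int) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n_input": n_in,
                "n_standardized": n_ok,
                "rejections_by_reason": rejections,
                "n_dropped_no_passing_scaffold": n_dropped_no_scaffold,
            },
            fh,
            indent=2,
        )
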