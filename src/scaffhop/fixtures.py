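"""Deterministic synthetic SMILES corpora with known scaffold/side-chain truth.

Each generated molecule is one ring-system core plus 0-3 small substituents
at random valence-eligible positions, so scaffold extraction, pair building,
decomposition and assembly can all be tested without external data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

__all__ = ["FixtureSpec", "generate_corpus", "CORE_LIBRARY", "SIDECHAIN_LIBRARY"]

# ~30 cores: filter-passers (non-benzene rings, small, rigid) and deliberate
# filter-failers (benzene-only, oversized, too floppy).
CORE_LIBRARY = [
    # pass: single heteroaromatic / saturated rings
    "c1ccncc1",  # pyridine
    "c1ccoc1",  # furan
    "c1ccsc1",  # thiophene
    "c1cc[nH]c1",  # pyrrole
    "c1cncnc1",  # pyrimidine
    "c1ccnnc1",  # pyridazine
    "c1cnccn1",  # pyrazine
    "C1CCNCC1",  # piperidine
    "C1CCOCC1",  # tetrahydropyran
    "C1CCSCC1",  # thiane
    "C1CNCCN1",  # piperazine
    "C1COCCN1",  # morpholine
    "C1CCCC1",  # cyclopentane
    "C1CCCCC1",  # cyclohexane
    "C1CCNC1",  # pyrrolidine
    "c1cnc[nH]1",  # imidazole
    "c1cn[nH]c1",  # pyrazole
    "c1csnn1",  # thiadiazole
    "c1ocnc1",  # oxazole
    # pass: fused bicyclics
    "c1ccc2ncccc2c1",  # quinoline
    "c1ccc2[nH]ccc2c1",  # indole
    "c1ccc2ncncc2c1",  # quinazoline-like
    "c1ccc2[nH]cnc2c1",  # benzimidazole
    "C1CCC2CCCCC2C1",  # decalin
    "c1ccc2c(c1)CCCC2",  # tetralin
    "c1ccc2c(c1)OCO2",  # benzodioxole
    # pass: biaryl with one non-benzene ring
    "c1ccc(-c2ccncc2)cc1",  # phenylpyridine
    # fail rule 1: benzene only
    "c1ccccc1",
    "c1ccc(-c2ccccc2)cc1",  # biphenyl
    # fail rule 2: > 20 heavy atoms
    "C1CC2CCC1CC2.c1ccc2ncccc2c1",  # placeholder replaced below
    # fail rule 3: > 3 rotatable bonds
    "c1ccncc1CCCCCc1ccncc1",
]
# a single connected >20-heavy-atom scaffold (three linked pyridines)
CORE_LIBRARY[-2] = "c1ccc(-c2ccc(-c3ccc(-c4ccncc4)nc3)cc2)nc1"

SIDECHAIN_LIBRARY = ["C", "CC", "CCC", "O", "N", "F", "Cl", "Br", "OC", "C#N", "C(C)C", "C(F)(F)F"]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_molecules: int = 100
    cores: Tuple[str, ...] = tuple(CORE_LIBRARY)
    sidechains: Tuple[str, ...] = tuple(SIDECHAIN_LIBRARY)
    max_substituents: int = 3
    only_passing_cores: bool = False
    max_retries: int = 20


@dataclass(frozen=True)
class FixtureMolecule:
    mol_id: str
    smiles: str
    core: str  # intended scaffold (canonical)
    sidechains: Tuple[str, ...]


def _passing_cores(cores: Sequence[str]) -> List[str]:
    from .chem import filter_scaffold, scaffold_record_from_smiles

    return [c for c in cores if filter_scaffold(scaffold_record_from_smiles(c))]


def _attach_one(core: Chem.Mol, sub_smiles: str, site: int) -> Optional[Chem.Mol]:
    sub = Chem.MolFromSmiles(sub_smiles)
    if sub is None:
        return None
    rw = Chem.RWMol(core)
    offset = rw.GetNumAtoms()
    rw.InsertMol(sub)
    rw.AddBond(site, offset, Chem.BondType.SINGLE)
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def generate_corpus(spec: FixtureSpec) -> List[FixtureMolecule]:
    """Deterministically build the corpus; identical spec -> identical output."""
    if not spec.cores or not spec.sidechains:
        raise ValueError("core and side-chain libraries must be non-empty")
    rng = np.random.default_rng(spec.seed)
    cores = _passing_cores(spec.cores) if spec.only_passing_cores else list(spec.cores)
    out: List[FixtureMolecule] = []
    skipped = 0
    for i in range(spec.n_molecules):
        core_smi = cores[int(rng.integers(len(cores)))]
        core = Chem.MolFromSmiles(core_smi)
        n_subs = int(rng.integers(spec.max_substituents + 1))
        built = None
        for _ in range(spec.max_retries):
            mol = Chem.Mol(core)
            chosen: List[str] = []
            used_sites: set = set()
            ok = True
            for _ in range(n_subs):
                # one substituent per core atom, matching the injective
                # fragment->site enumeration used at assembly time
                sites = [
                    i
                    for i in range(core.GetNumAtoms())
                    if i not in used_sites and mol.GetAtomWithIdx(i).GetTotalNumHs() >= 1
                ]
                if not sites:
                    ok = False
                    break
                site = sites[int(rng.integers(len(sites)))]
                used_sites.add(site)
                sub = spec.sidechains[int(rng.integers(len(spec.sidechains)))]
                attached = _attach_one(mol, sub, site)
                if attached is None:
                    ok = False
                    break
                mol = attached
                chosen.append(sub)
            if ok:
                built = (mol, tuple(chosen))
                break
        if built is None:
            skipped += 1
            continue
        mol, chosen = built
        out.append(
            FixtureMolecule(
                mol_id=f"fx{i:05d}",
                smiles=Chem.MolToSmiles(mol),
                core=Chem.MolToSmiles(core),
                sidechains=chosen,
            )
        )
    return out


def write_corpus(mols: Sequence[FixtureMolecule], smi_path: str, truth_path: str) -> None:
    with open(smi_path, "w") as fh:
        for m in mols:
            fh.write(f"{m.smiles}\t{m.mol_id}\n")
    with open(truth_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["mol_id", "smiles", "core", "sidechains"])
        for m in mols:
            w.writerow([m.mol_id, m.smiles, m.core, ",".join(m.sidechains)])
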