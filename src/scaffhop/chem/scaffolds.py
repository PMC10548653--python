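"""Scaffold hierarchy extraction and the scaffold pass/fail rules.

Level 0 is the Bemis-Murcko framework; deeper levels are produced by
repeatedly deleting one peripheral ring at a time (a ring whose exclusive
atoms can be removed without disconnecting the scaffold) until a single ring
remains, deduplicating by canonical SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from ..config import ScaffoldFilterConfig
from .standardize import MoleculeRecord

__all__ = [
    "ScaffoldRecord",
    "InconsistentPairError",
    "extract_scaffold_hierarchy",
    "filter_scaffold",
    "scaffold_atom_mask",
    "scaffold_record_from_smiles",
    "murcko_scaffold_smiles",
]


class InconsistentPairError(ValueError):
    """Raised when a scaffold is not a substructure of its claimed parent."""


@dataclass(frozen=True)
class ScaffoldRecord:
    smiles: str
    n_rings_non_benzene: int
    n_heavy: int
    n_rotatable: int
    level: int


def _is_benzene_ring(mol: Chem.Mol, ring: Tuple[int, ...]) -> bool:
    if len(ring) != 6:
        return False
    return all(
        mol.GetAtomWithIdx(i).GetSymbol() == "C" and mol.GetAtomWithIdx(i).GetIsAromatic()
        for i in ring
    )


def _count_non_benzene_rings(mol: Chem.Mol) -> int:
    return sum(1 for ring in mol.GetRingInfo().AtomRings() if not _is_benzene_ring(mol, ring))


def scaffold_record_from_smiles(smiles: str, level: int = 0) -> ScaffoldRecord:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable scaffold SMILES: {smiles!r}")
    return ScaffoldRecord(
        smiles=Chem.MolToSmiles(mol),
        n_rings_non_benzene=_count_non_benzene_rings(mol),
        n_heavy=mol.GetNumHeavyAtoms(),
        n_rotatable=rdMolDescriptors.CalcNumRotatableBonds(mol),
        level=level,
    )


def murcko_scaffold_smiles(smiles: str) -> Optional[str]:
    """Canonical Bemis-Murcko framework SMILES, or None for acyclic input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    core = MurckoScaffold.GetScaffoldForMol(mol)
    if core is None or core.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(core)


def _remove_one_ring(mol: Chem.Mol, ring_idx: int) -> Optional[Chem.Mol]:
    """Delete the atoms exclusive to ring `ring_idx`, re-extract the Murcko
    framework of the remainder. None if the ring is not peripheral."""
    rings = mol.GetRingInfo().AtomRings()
    ring = set(rings[ring_idx])
    shared = set()
    for j, other in enumerate(rings):
        if j != ring_idx:
            shared |= ring & set(other)
    exclusive = sorted(ring - shared, reverse=True)
    if not exclusive:
        return None
    rw = Chem.RWMol(mol)
    for i in exclusive:
        rw.RemoveAtom(i)
    frag = rw.GetMol()
    try:
        Chem.SanitizeMol(frag)
    except Exception:
        return None
    if frag.GetNumAtoms() == 0 or len(Chem.GetMolFrags(frag)) != 1:
        return None
    core = MurckoScaffold.GetScaffoldForMol(frag)
    if core is None or core.GetNumAtoms() == 0 or core.GetRingInfo().NumRings() == 0:
        return None
    try:
        Chem.SanitizeMol(core)
    except Exception:
        return None
    return core


def extract_scaffold_hierarchy(mol: MoleculeRecord) -> List[ScaffoldRecord]:
    """Bemis-Murcko scaffold plus all sub-scaffolds from iterative peripheral
    ring deletion; acyclic molecules give an empty list."""
    parent = Chem.MolFromSmiles(mol.smiles)
    if parent is None:
        raise ValueError(f"unparsable molecule SMILES: {mol.smiles!r}")
    top = murcko_scaffold_smiles(mol.smiles)
    if top is None:
        return []
    best_level: dict[str, int] = {top: 0}
    frontier = [(Chem.MolFromSmiles(top), 0)]
    while frontier:
        current, level = frontier.pop()
        n_rings = current.GetRingInfo().NumRings()
        if n_rings <= 1:
            continue
        for ring_idx in range(n_rings):
            sub = _remove_one_ring(current, ring_idx)
            if sub is None:
                continue
            smi = Chem.MolToSmiles(sub)
            # soundness: the sub-scaffold must still embed in the parent
            query = Chem.MolFromSmiles(smi)
            if query is None or not parent.HasSubstructMatch(query):
                continue
            if smi not in best_level or level + 1 < best_level[smi]:
                best_level[smi] = level + 1
                frontier.append((sub, level + 1))
    return [scaffold_record_from_smiles(smi, level=lvl) for smi, lvl in sorted(best_level.items(), key=lambda kv: (kv[1], kv[0]))]


def filter_scaffold(s: ScaffoldRecord, cfg: Optional[ScaffoldFilterConfig] = None) -> bool:
    """True iff the scaffold has >=1 non-benzene ring, <=20 heavy atoms and
    <=3 rotatable bonds (thresholds configurable)."""
    cfg = cfg or ScaffoldFilterConfig()
    return (
        s.n_rings_non_benzene >= 1
        and s.n_heavy <= cfg.max_heavy_atoms
        and s.n_rotatable <= cfg.max_rotatable_bonds
    )


def scaffold_atom_mask(mol: MoleculeRecord, s: ScaffoldRecord) -> Tuple[int, ...]:
    """Atom indices of one substructure match of the scaffold in the molecule."""
    parent = Chem.MolFromSmiles(mol.smiles)
    query = Chem.MolFromSmiles(s.smiles)
    if parent is None or query is None:
        raise ValueError("unparsable SMILES in mol/scaffold pair")
    match = parent.GetSubstructMatch(query)
    if not match:
        raise InconsistentPairError(
            f"scaffold {s.smiles!r} is not a substructure of {mol.smiles!r}"
        )
    return tuple(match)
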