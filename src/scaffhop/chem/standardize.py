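"""SMILES standardization: largest organic fragment, neutralization, filters."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from ..config import PrepConfig

RDLogger.DisableLog("rdApp.*")

__all__ = ["MoleculeRecord", "Rejection", "standardize_molecule", "passes_structural_filters"]

_ORGANIC_ELEMENTS = {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}

# Small built-in medicinal-chemistry / PAINS-style SMARTS screen. Users can
# extend it with a file of extra patterns (one SMARTS per line, '#' comments).
_DEFAULT_FILTER_SMARTS = [
    ("acyl_halide", "[CX3](=O)[F,Cl,Br,I]"),
    ("nitroso", "[#6]N=O"),
    ("azo", "[#6]N=N[#6]"),
    ("isocyanate", "N=C=O"),
    ("thiocyanate", "SC#N"),
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("peroxide", "[OX2][OX2]"),
    ("michael_acceptor_nitrile", "C=CC#N"),
    ("quinone", "O=C1C=CC(=O)C=C1"),
    ("hydrazine", "[NX3][NX3]"),
    ("catechol_pains", "c1ccc(O)c(O)c1"),
    ("rhodanine_pains", "S1C(=O)NC(=S)C1"),
    ("ene_rhodanine", "C=C1SC(=S)NC1=O"),
    ("alkyl_halide_primary", "[CH2][Br,I]"),
    ("phosphorus_halide", "P[F,Cl,Br,I]"),
]

_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


@dataclass(frozen=True)
class MoleculeRecord:
    id: str
    smiles: str
    n_heavy: int
    mol_weight: float


@dataclass(frozen=True)
class Rejection:
    id: str
    reason: str  # invalid | metal | mw_out_of_range | filter_hit
    detail: str = ""


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return max(frags, key=lambda f: f.GetNumHeavyAtoms())


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Zero out isolated formal charges by adjusting hydrogen counts."""
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    if not matches:
        return mol
    mol = Chem.RWMol(mol)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h_count = atom.GetTotalNumHs()
        if charge > 0 and h_count >= charge:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(h_count - charge)
        elif charge < 0:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(h_count - charge)
        atom.UpdatePropertyCache(strict=False)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def _load_filter_patterns(limits: PrepConfig):
    patterns = [(name, Chem.MolFromSmarts(s)) for name, s in _DEFAULT_FILTER_SMARTS]
    if limits.extra_filter_smarts:
        with open(limits.extra_filter_smarts) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                patt = Chem.MolFromSmarts(line)
                if patt is not None:
                    patterns.append((f"user_{i}", patt))
    return patterns


def passes_structural_filters(mol: Chem.Mol, limits: Optional[PrepConfig] = None) -> Optional[str]:
    """Return the name of the first hit pattern, or None if the molecule is clean."""
    limits = limits or PrepConfig()
    for name, patt in _load_filter_patterns(limits):
        if patt is not None and mol.HasSubstructMatch(patt):
            return name
    return None


def standardize_molecule(
    raw: str, limits: Optional[PrepConfig] = None, mol_id: str = ""
) -> Union[MoleculeRecord, Rejection]:
    """Standardize one raw SMILES.

    Keeps the largest fragment, neutralizes isolated charges, rejects
    organometallics, and applies weight/heavy-atom bounds and structural
    SMARTS screens from `limits`.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("empty SMILES string")
    limits = limits or PrepConfig()
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        return Rejection(mol_id, "invalid", raw)
    if mol.GetNumHeavyAtoms() == 0:
        return Rejection(mol_id, "invalid", "no heavy atoms")
    mol = _largest_fragment(mol)
    if any(a.GetSymbol() not in _ORGANIC_ELEMENTS for a in mol.GetAtoms()):
        bad = next(a.GetSymbol() for a in mol.GetAtoms() if a.GetSymbol() not in _ORGANIC_ELEMENTS)
        return Rejection(mol_id, "metal", bad)
    try:
        mol = _neutralize(mol)
    except Exception:
        return Rejection(mol_id, "invalid", "neutralization failed")
    mw = Descriptors.MolWt(mol)
    n_heavy = mol.GetNumHeavyAtoms()
    if limits.mol_weight_min is not None and mw < limits.mol_weight_min:
        return Rejection(mol_id, "mw_out_of_range", f"{mw:.1f}")
    if limits.mol_weight_max is not None and mw > limits.mol_weight_max:
        return Rejection(mol_id, "mw_out_of_range", f"{mw:.1f}")
    if limits.n_heavy_min is not None and n_heavy < limits.n_heavy_min:
        return Rejection(mol_id, "mw_out_of_range", f"heavy={n_heavy}")
    if limits.n_heavy_max is not None and n_heavy > limits.n_heavy_max:
        return Rejection(mol_id, "mw_out_of_range", f"heavy={n_heavy}")
    if limits.apply_structural_filters:
        hit = passes_structural_filters(mol, limits)
        if hit is not None:
            return Rejection(mol_id, "filter_hit", hit)
    return MoleculeRecord(
        id=mol_id, smiles=Chem.MolToSmiles(mol), n_heavy=n_heavy, mol_weight=round(mw, 3)
    )
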