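"""Scaffold hopping: latent resampling, scaffold decoding, side-chain reattachment.

Side chains are cut from the reference molecule at every bond crossing the
scaffold mask, then enumerated back onto a newly decoded scaffold at all
valence-eligible sites; the candidate most similar to the reference (by
path-based topological fingerprint Tanimoto) is kept.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem, DataStructs

from .chem import MolScaffoldPair, MoleculeRecord

__all__ = [
    "SideChainFragment",
    "SideChainSet",
    "GeneratedMolecule",
    "resample_h0",
    "decompose_reference",
    "decomposable",
    "reattach_original",
    "enumerate_attachments",
    "select_candidate",
    "side_chains_present",
    "assemble",
    "hop",
    "write_generated_tsv",
    "read_generated_tsv",
]

FP_MAX_PATH = 7
FP_N_BITS = 2048
DEFAULT_ENUM_CAP = 5000


@dataclass(frozen=True)
class SideChainFragment:
    smiles: str  # fragment SMILES containing one dummy atom [*]
    attach_atom: int  # atom index on the *scaffold query* where it was attached
    bond_order: float  # 1.0 single, 2.0 double, 3.0 triple

    @property
    def h_needed(self) -> int:
        return int(round(self.bond_order))


@dataclass(frozen=True)
class SideChainSet:
    fragments: Tuple[SideChainFragment, ...]
    scaffold_smiles: str
    source_id: str


@dataclass(frozen=True)
class GeneratedMolecule:
    scaffold_smiles: str
    assembled_smiles: Optional[str]
    reference_id: str
    attachment_map: Tuple[Tuple[str, int], ...] = ()
    similarity: float = 0.0
    valid: bool = False
    hopped: bool = False


def _fingerprint(mol: Chem.Mol):
    return Chem.RDKFingerprint(mol, maxPath=FP_MAX_PATH, fpSize=FP_N_BITS)


def tanimoto(mol_a: Chem.Mol, mol_b: Chem.Mol) -> float:
    return DataStructs.TanimotoSimilarity(_fingerprint(mol_a), _fingerprint(mol_b))


# -- latent resampling --------------------------------------------------------


def resample_h0(
    z_side: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    sigma_mode: str = "literal",
) -> np.ndarray:
    """h0 = concat(Z_side, mu + s * eps) with eps ~ N(0, I).

    ``sigma_mode='literal'`` scales by sigma^2 (as printed in the source
    formulation); ``'standard'`` uses the conventional sigma scaling.
    """
    if sigma_mode not in ("literal", "standard"):
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = rng.standard_normal(mu.shape[0])
    scale = sigma ** 2 if sigma_mode == "literal" else sigma
    return np.concatenate([z_side, mu + scale * eps])


# -- decomposition ------------------------------------------------------------


def decompose_reference(ref: MolScaffoldPair) -> SideChainSet:
    """Cut every bond between a scaffold-mask atom and a non-mask atom."""
    mol = Chem.MolFromSmiles(ref.molecule.smiles)
    query = Chem.MolFromSmiles(ref.scaffold.smiles)
    if mol is None or query is None:
        raise ValueError("unparsable reference pair")
    mask = set(ref.scaffold_atom_indices)
    if not mask or not all(0 <= i < mol.GetNumAtoms() for i in mask):
        raise ValueError("invalid scaffold mask")
    mol_to_query = {m: q for q, m in enumerate(ref.scaffold_atom_indices)}
    cut_bonds = []
    bond_info = []  # (scaffold query atom, bond order)
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (a in mask) != (b in mask):
            if bond.IsInRing():
                raise ValueError(
                    f"scaffold mask boundary crosses a ring bond in {ref.molecule.smiles!r}; "
                    "side chains must attach through acyclic bonds"
                )
            scaffold_atom = a if a in mask else b
            cut_bonds.append(bond.GetIdx())
            bond_info.append((mol_to_query[scaffold_atom], bond.GetBondTypeAsDouble()))
    if not cut_bonds:
        return SideChainSet(fragments=(), scaffold_smiles=ref.scaffold.smiles, source_id=ref.molecule.id)
    labels = [(i + 1, i + 1) for i in range(len(cut_bonds))]
    fragmented = Chem.FragmentOnBonds(mol, cut_bonds, addDummies=True, dummyLabels=labels)
    n_orig = mol.GetNumAtoms()  # dummy atoms are appended after the originals
    frag_atom_tuples = Chem.GetMolFrags(fragmented)
    frags = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)
    side_frags: List[SideChainFragment] = []
    for atom_tuple, frag in zip(frag_atom_tuples, frags):
        orig_atoms = [i for i in atom_tuple if i < n_orig]
        if orig_atoms and orig_atoms[0] in mask:
            continue  # the scaffold piece
        dummies = [a for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise ValueError(
                f"side-chain fragment with {len(dummies)} attachment points in "
                f"{ref.molecule.smiles!r}; multi-attachment side chains unsupported"
            )
        label = dummies[0].GetIsotope() - 1
        attach_atom, order = bond_info[label]
        side_frags.append(
            SideChainFragment(
                smiles=Chem.MolToSmiles(frag), attach_atom=attach_atom, bond_order=order
            )
        )
    side_frags.sort(key=lambda f: (f.attach_atom, f.smiles))
    return SideChainSet(
        fragments=tuple(side_frags), scaffold_smiles=ref.scaffold.smiles, source_id=ref.molecule.id
    )


def decomposable(ref: MolScaffoldPair) -> bool:
    """True iff the reference can be split into scaffold + one-point side chains."""
    try:
        decompose_reference(ref)
        return True
    except ValueError:
        return False


_BOND_TYPE = {1.0: Chem.BondType.SINGLE, 1.5: Chem.BondType.AROMATIC, 2.0: Chem.BondType.DOUBLE, 3.0: Chem.BondType.TRIPLE}


def _attach_fragments(
    scaffold: Chem.Mol, assignment: Sequence[Tuple[SideChainFragment, int]]
) -> Optional[str]:
    """Attach each fragment at its assigned scaffold atom; canonical SMILES or
    None if the result does not sanitize."""
    combo = Chem.RWMol(scaffold)
    for frag, site in assignment:
        frag_mol = Chem.MolFromSmiles(frag.smiles)
        if frag_mol is None:
            return None
        offset = combo.GetNumAtoms()
        combo.InsertMol(frag_mol)
        dummy_idx = None
        for atom in frag_mol.GetAtoms():
            if atom.GetAtomicNum() == 0:
                dummy_idx = atom.GetIdx()
                break
        if dummy_idx is None:
            return None
        nbr = frag_mol.GetAtomWithIdx(dummy_idx).GetNeighbors()[0].GetIdx()
        bond_type = _BOND_TYPE.get(frag.bond_order, Chem.BondType.SINGLE)
        combo.AddBond(site, offset + nbr, bond_type)
        combo.RemoveAtom(offset + dummy_idx)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def reattach_original(side: SideChainSet) -> Optional[str]:
    """Rebuild the reference molecule from its scaffold and fragments."""
    scaffold = Chem.MolFromSmiles(side.scaffold_smiles)
    if scaffold is None:
        return None
    return _attach_fragments(scaffold, [(f, f.attach_atom) for f in side.fragments])


# -- enumeration + selection --------------------------------------------------


def _eligible_sites(scaffold: Chem.Mol, h_needed: int) -> List[int]:
    """Scaffold atoms with enough hydrogens to accept the new bond, ordered by
    canonical rank for deterministic enumeration."""
    ranks = list(Chem.CanonicalRankAtoms(scaffold, breakTies=True))
    sites = [a.GetIdx() for a in scaffold.GetAtoms() if a.GetTotalNumHs() >= h_needed]
    sites.sort(key=lambda i: ranks[i])
    return sites


def enumerate_attachments(
    new_scaffold: str, side: SideChainSet, cap: int = DEFAULT_ENUM_CAP
) -> List[Tuple[str, Tuple[Tuple[str, int], ...]]]:
    """All injective fragment->site assignments that sanitize, deduplicated by
    canonical SMILES. Returns (assembled_smiles, attachment_map) tuples."""
    scaffold = Chem.MolFromSmiles(new_scaffold)
    if scaffold is None:
        raise ValueError(f"unparsable scaffold SMILES: {new_scaffold!r}")
    frags = side.fragments
    if not frags:
        return [(Chem.MolToSmiles(scaffold), ())]
    per_frag_sites = [_eligible_sites(scaffold, f.h_needed) for f in frags]
    seen = {}
    n_tried = 0
    for combo in itertools.product(*per_frag_sites):
        if len(set(combo)) != len(combo):
            continue
        n_tried += 1
        if n_tried > cap:
            break
        smi = _attach_fragments(scaffold, list(zip(frags, combo)))
        if smi is None:
            continue
        if smi not in seen:
            seen[smi] = tuple((f.smiles, s) for f, s in zip(frags, combo))
    return [(smi, amap) for smi, amap in seen.items()]


def select_candidate(
    candidates: Sequence[Tuple[str, Tuple[Tuple[str, int], ...]]],
    reference: MoleculeRecord,
    scaffold_smiles: str = "",
    reference_id: Optional[str] = None,
) -> GeneratedMolecule:
    """Pick the candidate with maximal topological-fingerprint Tanimoto to the
    reference; ties break to the lexicographically smallest canonical SMILES."""
    ref_id = reference_id if reference_id is not None else reference.id
    ref_mol = Chem.MolFromSmiles(reference.smiles)
    best = None
    for smi, amap in candidates:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        sim = tanimoto(mol, ref_mol)
        key = (-sim, smi)
        if best is None or key < best[0]:
            best = (key, smi, amap, sim)
    if best is None:
        return GeneratedMolecule(
            scaffold_smiles=scaffold_smiles, assembled_smiles=None, reference_id=ref_id, valid=False
        )
    _, smi, amap, sim = best
    return GeneratedMolecule(
        scaffold_smiles=scaffold_smiles,
        assembled_smiles=smi,
        reference_id=ref_id,
        attachment_map=amap,
        similarity=round(sim, 6),
        valid=True,
    )


def assemble(
    new_scaffold: str, side: SideChainSet, reference: MoleculeRecord, cap: int = DEFAULT_ENUM_CAP
) -> GeneratedMolecule:
    """Enumerate attachments of `side` on `new_scaffold`, select the best, and
    set the hopped flag."""
    scaffold_mol = Chem.MolFromSmiles(new_scaffold)
    if scaffold_mol is None:
        return GeneratedMolecule(
            scaffold_smiles=new_scaffold, assembled_smiles=None, reference_id=side.source_id, valid=False
        )
    canon_new = Chem.MolToSmiles(scaffold_mol)
    candidates = enumerate_attachments(canon_new, side, cap=cap)
    gen = select_candidate(candidates, reference, scaffold_smiles=canon_new, reference_id=side.source_id)
    if gen.valid:
        ref_scaffold = Chem.MolToSmiles(Chem.MolFromSmiles(side.scaffold_smiles))
        hopped = canon_new != ref_scaffold and side_chains_present(
            gen.assembled_smiles, canon_new, side
        )
        gen = GeneratedMolecule(
            scaffold_smiles=gen.scaffold_smiles,
            assembled_smiles=gen.assembled_smiles,
            reference_id=gen.reference_id,
            attachment_map=gen.attachment_map,
            similarity=gen.similarity,
            valid=True,
            hopped=hopped,
        )
    return gen


def side_chains_present(
    assembled_smiles: Optional[str], scaffold_smiles: str, side: SideChainSet
) -> bool:
    """True iff every side-chain fragment occurs (with multiplicity) among the
    atoms *outside* some substructure match of the scaffold.

    Checking outside the scaffold match is what makes the test meaningful: a
    bare methyl query would otherwise match any ring carbon.
    """
    if assembled_smiles is None:
        return False
    mol = Chem.MolFromSmiles(assembled_smiles)
    scaffold = Chem.MolFromSmiles(scaffold_smiles)
    if mol is None or scaffold is None:
        return False
    if not side.fragments:
        return True
    groups: dict = {}
    for frag in side.fragments:
        groups[frag.smiles] = groups.get(frag.smiles, 0) + 1
    scaffold_matches = mol.GetSubstructMatches(scaffold, maxMatches=64)
    if not scaffold_matches:
        return False
    for sca_match in scaffold_matches:
        outside = set(range(mol.GetNumAtoms())) - set(sca_match)
        ok = True
        for frag_smiles, multiplicity in groups.items():
            query = _fragment_query(frag_smiles)
            if query is None:
                ok = False
                break
            hits = {
                frozenset(m)
                for m in mol.GetSubstructMatches(query, uniquify=True, maxMatches=256)
                if set(m) <= outside
            }
            if len(hits) < multiplicity:
                ok = False
                break
        if ok:
            return True
    return False


def _fragment_query(frag_smiles: str) -> Optional[Chem.Mol]:
    """Fragment SMILES with its dummy atom removed, for substructure checks."""
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        return None
    rw = Chem.RWMol(frag)
    for atom in sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        rw.RemoveAtom(atom)
    out = rw.GetMol()
    if out.GetNumAtoms() == 0:
        return None
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


# -- end-to-end hop -----------------------------------------------------------


def hop(
    ref: MolScaffoldPair,
    model,
    n: int,
    seed: int = 0,
    temperature: float = 1.0,
    sigma_mode: str = "literal",
    dedup_scaffolds: bool = False,
    enum_cap: int = DEFAULT_ENUM_CAP,
) -> List[GeneratedMolecule]:
    """Sample `n` scaffolds from the model conditioned on `ref` and assemble
    each with the reference side chains. Invalid samples are kept, flagged."""
    from .nn import no_grad

    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    with no_grad():
        split, post = model.encode_pair(ref)
    z_side, mu, sigma = split.z_side.data, post.mu.data, post.sigma.data
    side = decompose_reference(ref)
    out: List[GeneratedMolecule] = []
    seen_scaffolds = set()
    attempts = 0
    max_attempts = 10 * n + 100
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        cond = resample_h0(z_side, mu, sigma, rng=rng, sigma_mode=sigma_mode)
        smi = model.decoder.sample_sequence(cond, model.vocab, temperature=temperature, rng=rng)
        if dedup_scaffolds:
            mol = Chem.MolFromSmiles(smi) if smi else None
            key = Chem.MolToSmiles(mol) if mol is not None else smi
            if key in seen_scaffolds:
                continue
            seen_scaffolds.add(key)
        if not smi or Chem.MolFromSmiles(smi) is None:
            out.append(
                GeneratedMolecule(
                    scaffold_smiles=smi, assembled_smiles=None, reference_id=ref.molecule.id, valid=False
                )
            )
            continue
        out.append(assemble(smi, side, ref.molecule, cap=enum_cap))
    return out


# -- IO -----------------------------------------------------------------------

GENERATED_HEADER = ["reference_id", "scaffold_smiles", "assembled_smiles", "similarity", "valid", "hopped"]


def write_generated_tsv(generated: Sequence[GeneratedMolecule], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(GENERATED_HEADER)
        for g in generated:
            w.writerow(
                [
                    g.reference_id,
                    g.scaffold_smiles,
                    g.assembled_smiles or "",
                    f"{g.similarity:.6f}",
                    int(g.valid),
                    int(g.hopped),
                ]
            )


def read_generated_tsv(path: str) -> List[GeneratedMolecule]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != GENERATED_HEADER:
            raise ValueError(f"unexpected generated TSV header: {header}")
        for ref_id, sca, asm, sim, valid, hopped in reader:
            out.append(
                GeneratedMolecule(
                    scaffold_smiles=sca,
                    assembled_smiles=asm or None,
                    reference_id=ref_id,
                    similarity=float(sim),
                    valid=bool(int(valid)),
                    hopped=bool(int(hopped)),
                )
            )
    return out
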