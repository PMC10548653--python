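"""Generation-quality (GEM) and scaffold-hopping (SEM) metric reports."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from typing import Callable, List, Optional, Sequence, Set

from rdkit import Chem

from .assembly import (
    GeneratedMolecule,
    SideChainSet,
    decompose_reference,
    side_chains_present,
)
from .chem import MolScaffoldPair, murcko_scaffold_smiles
from .chem.standardize import passes_structural_filters

__all__ = [
    "GemReport",
    "SemReport",
    "ActivityScorer",
    "gem_report",
    "hop_check",
    "sem_report",
    "mock_scorer",
    "MockScorer",
]


@dataclass(frozen=True)
class GemReport:
    validity: float
    uniqueness1k: float
    uniqueness5k: float
    filter_rate: float
    novelty: float
    scaffold_uniqueness: float
    scaffold_novelty: float
    n_generated: int = 0
    n_valid: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SemReport:
    active_mean: Optional[float]
    active_rate: Optional[float]
    hop_rate: Optional[float]
    success_rate: Optional[float]
    n_valid: int = 0
    n_evaluated: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


class ActivityScorer:
    """Interface: deterministic score for a molecule against a target.

    `orientation` is +1 when larger scores mean better activity (DTA-style)
    and -1 when smaller scores are better (docking-style).
    """

    name: str = "base"
    orientation: int = +1

    def score(self, smiles: str, target: str = "") -> float:
        raise NotImplementedError

    def __call__(self, smiles: str, target: str = "") -> float:
        return self.score(smiles, target)


def _canon(smiles: str) -> Optional[str]:
    if not smiles:
        return None
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def _uniqueness_at_k(canon_list: List[Optional[str]], k: int) -> float:
    if k > len(canon_list):
        warnings.warn(
            f"k={k} exceeds the number of generated molecules ({len(canon_list)}); "
            "computing on the full list"
        )
    head = canon_list[:k]
    valid = [c for c in head if c is not None]
    if not valid:
        return 0.0
    return len(set(valid)) / len(valid)


def gem_report(
    generated: Sequence[str],
    train_mols: Set[str],
    train_scaffolds: Set[str],
    k1: int = 1000,
    k2: int = 5000,
) -> GemReport:
    """Compute the seven generation metrics on an ordered SMILES list."""
    canon_list = [_canon(s) for s in generated]
    n = len(canon_list)
    valid = [c for c in canon_list if c is not None]
    validity = len(valid) / n if n else 0.0
    unique_valid = sorted(set(valid))
    novelty = (
        sum(1 for c in unique_valid if c not in train_mols) / len(unique_valid)
        if unique_valid
        else 0.0
    )
    n_pass = 0
    scaffolds: List[str] = []
    for c in valid:
        mol = Chem.MolFromSmiles(c)
        if passes_structural_filters(mol) is None:
            n_pass += 1
        sca = murcko_scaffold_smiles(c)
        if sca is not None:
            scaffolds.append(sca)
    filter_rate = n_pass / len(valid) if valid else 0.0
    unique_scaffolds = sorted(set(scaffolds))
    scaffold_uniqueness = len(unique_scaffolds) / len(scaffolds) if scaffolds else 0.0
    scaffold_novelty = (
        sum(1 for s in unique_scaffolds if s not in train_scaffolds) / len(unique_scaffolds)
        if unique_scaffolds
        else 0.0
    )
    return GemReport(
        validity=validity,
        uniqueness1k=_uniqueness_at_k(canon_list, k1),
        uniqueness5k=_uniqueness_at_k(canon_list, k2),
        filter_rate=filter_rate,
        novelty=novelty,
        scaffold_uniqueness=scaffold_uniqueness,
        scaffold_novelty=scaffold_novelty,
        n_generated=n,
        n_valid=len(valid),
    )


def hop_check(gen: GeneratedMolecule, ref: MolScaffoldPair, side: Optional[SideChainSet] = None) -> bool:
    """True iff every reference side chain embeds in the assembled molecule and
    the generated scaffold differs from the reference scaffold."""
    if not gen.valid or not gen.assembled_smiles:
        return False
    gen_scaffold = _canon(gen.scaffold_smiles)
    ref_scaffold = _canon(ref.scaffold.smiles)
    if gen_scaffold is None or gen_scaffold == ref_scaffold:
        return False
    if side is None:
        side = decompose_reference(ref)
    return side_chains_present(gen.assembled_smiles, gen_scaffold, side)


def sem_report(
    generated: Sequence[GeneratedMolecule],
    ref: MolScaffoldPair,
    scorer: ActivityScorer,
    top_fraction: float = 0.10,
    target: str = "",
) -> SemReport:
    """Score the valid molecules, keep the best `top_fraction`, and report
    active mean/rate, hop rate and success rate on that subset."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    valid = [g for g in generated if g.valid and g.assembled_smiles]
    if not valid:
        return SemReport(None, None, None, None, n_valid=0, n_evaluated=0)
    side = decompose_reference(ref)
    scored = [(scorer.score(g.assembled_smiles, target), g) for g in valid]
    scored.sort(key=lambda t: -scorer.orientation * t[0])
    n_top = max(1, int(round(top_fraction * len(scored))))
    top = scored[:n_top]
    ref_score = scorer.score(ref.molecule.smiles, target)
    n_active = n_hop = n_success = 0
    for score, g in top:
        better = scorer.orientation * score > scorer.orientation * ref_score
        hopped = hop_check(g, ref, side=side)
        n_active += better
        n_hop += hopped
        n_success += better and hopped
    report = SemReport(
        active_mean=sum(s for s, _ in top) / n_top,
        active_rate=n_active / n_top,
        hop_rate=n_hop / n_top,
        success_rate=n_success / n_top,
        n_valid=len(valid),
        n_evaluated=n_top,
    )
    assert report.success_rate <= min(report.active_rate, report.hop_rate) + 1e-12
    return report


class MockScorer(ActivityScorer):
    """Deterministic stand-in for an external activity predictor.

    Scores are a smooth function of heavy-atom and ring counts plus a small
    hash-derived term from the canonical SMILES and the target id, giving a
    stable but non-trivial ordering. Higher is better; unparsable input gets
    the worst possible score.
    """

    name = "mock"
    orientation = +1
    WORST = -100.0

    def score(self, smiles: str, target: str = "") -> float:
        import math

        canon = _canon(smiles)
        if canon is None:
            return self.WORST
        mol = Chem.MolFromSmiles(canon)
        n_heavy = mol.GetNumHeavyAtoms()
        n_rings = mol.GetRingInfo().NumRings()
        digest = hashlib.sha256(f"{canon}|{target}".encode()).digest()
        jitter = int.from_bytes(digest[:4], "big") / 2 ** 32  # in [0, 1)
        return round(5.0 + 2.0 * math.sin(0.37 * n_heavy) + 0.5 * n_rings + jitter, 6)


def mock_scorer(smiles: str, target: str = "") -> float:
    return MockScorer().score(smiles, target)


def write_report(path: str, gem: Optional[GemReport], sem: Optional[SemReport]) -> None:
    payload = {}
    if gem is not None:
        payload["gem"] = gem.to_dict()
    if sem is not None:
        payload["sem"] = sem.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
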