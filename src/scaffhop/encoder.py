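"""Molecular graph featurization and the multi-view message-passing encoder.

Two message-passing views run in parallel over the molecular graph:

* node view: ``h_v^{l+1} = relu(W_node [sum_u h_u^l ; sum_u e_vu] + h_v^0)``
* edge view (directed states, no immediate backtracking):
  ``h_vw^{l+1} = relu(W_edge [sum_{u in N_v \\ w} h_uv^l ; sum x_u] + h_vw^0)``

after L layers the edge view is read back onto nodes, the two per-node
outputs are concatenated, and masked structured self-attention pools the
scaffold rows and side-chain rows into fixed-length vectors Z_sca / Z_side.
A pair of linear heads on Z_sca gives the latent Gaussian posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .config import EncoderConfig
from .nn import Linear, Module, Tensor, concat, gather_rows

__all__ = [
    "MoleculeGraph",
    "featurize",
    "graph_from_arrays",
    "MolEncoder",
    "LatentPosterior",
    "SplitEmbedding",
]

ATOM_TYPES = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B"]  # + trailing "other" slot
MAX_DEGREE = 5
BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

NODE_FEAT_DIM = len(ATOM_TYPES) + 1 + (MAX_DEGREE + 1) + 1 + 1 + 1 + 1
EDGE_FEAT_DIM = len(BOND_TYPES) + 2


@dataclass
class MoleculeGraph:
    """Featurized molecular graph with precomputed aggregation operators.

    All matrices are constants of the graph topology so the message-passing
    updates reduce to (autograd-tracked) matrix products.
    """

    n_nodes: int
    node_feats: np.ndarray  # n x NODE_FEAT_DIM
    edge_feats: np.ndarray  # m_directed x EDGE_FEAT_DIM (both directions share features)
    edges: np.ndarray  # m_directed x 2 (v, w) meaning state h_vw
    adj: np.ndarray  # n x n, 0/1
    edge_feat_sum: np.ndarray  # n x EDGE_FEAT_DIM : sum_u e_vu
    node_feat_nbr_sum: np.ndarray  # n x NODE_FEAT_DIM : sum_{u in N_v} x_u
    edge_agg: np.ndarray  # m x m : [vw, uv] = 1 for u in N_v \ {w}
    edge_node_sum: np.ndarray  # m x NODE_FEAT_DIM : sum_{u in N_v \ w} x_u
    incoming: np.ndarray  # n x m : [v, uv] = 1 for u in N_v


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    f = np.zeros(NODE_FEAT_DIM)
    sym = atom.GetSymbol()
    f[ATOM_TYPES.index(sym) if sym in ATOM_TYPES else len(ATOM_TYPES)] = 1.0
    off = len(ATOM_TYPES) + 1
    deg = min(atom.GetDegree(), MAX_DEGREE)
    f[off + deg] = 1.0
    off += MAX_DEGREE + 1
    f[off] = atom.GetTotalValence() / 4.0
    f[off + 1] = float(atom.GetFormalCharge())
    f[off + 2] = float(atom.GetIsAromatic())
    f[off + 3] = float(atom.IsInRing())
    return f


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    f = np.zeros(EDGE_FEAT_DIM)
    bt = bond.GetBondType()
    if bt in BOND_TYPES:
        f[BOND_TYPES.index(bt)] = 1.0
    f[len(BOND_TYPES)] = float(bond.GetIsConjugated())
    f[len(BOND_TYPES) + 1] = float(bond.IsInRing())
    return f


def featurize(smiles_or_mol) -> MoleculeGraph:
    """Build the featurized graph for a SMILES string or RDKit Mol."""
    if isinstance(smiles_or_mol, str):
        mol = Chem.MolFromSmiles(smiles_or_mol)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {smiles_or_mol!r}")
    else:
        mol = smiles_or_mol
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError("empty molecule")
    X = np.stack([_atom_features(a) for a in mol.GetAtoms()])
    undirected = []
    efeats = []
    for bond in mol.GetBonds():
        undirected.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        efeats.append(_bond_features(bond))
    E = np.stack(efeats) if efeats else np.zeros((0, EDGE_FEAT_DIM))
    return graph_from_arrays(n, undirected, X, E)


def graph_from_arrays(
    n: int, undirected_edges, node_feats: np.ndarray, bond_feats: np.ndarray
) -> MoleculeGraph:
    """Assemble a MoleculeGraph (with all aggregation operators) from raw
    arrays: one row of `bond_feats` per undirected edge."""
    X = np.asarray(node_feats, dtype=np.float64)
    edges = []
    efeats = []
    for k, (v, w) in enumerate(undirected_edges):
        bf = np.asarray(bond_feats[k], dtype=np.float64)
        edges.append((v, w))
        efeats.append(bf)
        edges.append((w, v))
        efeats.append(bf)
    m = len(edges)
    bond_feats = np.asarray(bond_feats, dtype=np.float64)
    e_dim = bond_feats.shape[1] if bond_feats.ndim == 2 else EDGE_FEAT_DIM
    E = np.stack(efeats) if m else np.zeros((0, e_dim))
    edges_arr = np.asarray(edges, dtype=np.intp).reshape(m, 2)
    adj = np.zeros((n, n))
    for v, w in edges_arr:
        adj[v, w] = 1.0
    edge_feat_sum = np.zeros((n, E.shape[1]))
    node_nbr_sum = adj @ X
    incoming = np.zeros((n, m))
    for k, (v, w) in enumerate(edges_arr):
        edge_feat_sum[v] += E[k]  # e_vw contributes to node v's edge-feature sum
        incoming[w, k] = 1.0  # state h_vw is incoming at node w
    edge_agg = np.zeros((m, m))
    edge_node_sum = np.zeros((m, X.shape[1]))
    index = {(v, w): k for k, (v, w) in enumerate(map(tuple, edges_arr))}
    for k, (v, w) in enumerate(edges_arr):
        # aggregate states h_uv for u in N_v excluding w
        for u in np.flatnonzero(adj[v]):
            if u == w:
                continue
            edge_agg[k, index[(u, v)]] = 1.0
            edge_node_sum[k] += X[u]
    return MoleculeGraph(
        n_nodes=n,
        node_feats=X,
        edge_feats=E,
        edges=edges_arr,
        adj=adj,
        edge_feat_sum=edge_feat_sum,
        node_feat_nbr_sum=node_nbr_sum,
        edge_agg=edge_agg,
        edge_node_sum=edge_node_sum,
        incoming=incoming,
    )


@dataclass
class LatentPosterior:
    mu: Tensor
    sigma: Tensor  # elementwise positive

    @property
    def d_z(self) -> int:
        return self.mu.data.shape[-1]


@dataclass
class SplitEmbedding:
    z_sca: Tensor  # length r * (h_node + h_edge)
    z_side: Tensor  # same length; zero vector when every atom is scaffold


class MolEncoder(Module):
    """Multi-view MPNN encoder with masked attention readout and latent heads."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        h, he = cfg.h_node, cfg.h_edge
        self.w_nin = Linear(NODE_FEAT_DIM, h, rng, bias=False)
        self.w_ein = Linear(EDGE_FEAT_DIM, he, rng, bias=False)
        self.w_node = Linear(h + EDGE_FEAT_DIM, h, rng, bias=False)
        self.w_edge = Linear(he + NODE_FEAT_DIM, he, rng, bias=False)
        self.w_eout = Linear(he + NODE_FEAT_DIM, he, rng, bias=False)
        d_out = h + he
        self.attn_w1 = Linear(d_out, cfg.d_attn, rng, bias=False)
        self.attn_w2 = Linear(cfg.d_attn, cfg.r_heads, rng, bias=False)
        self.mu_head = Linear(cfg.r_heads * d_out, cfg.d_z, rng)
        self.logvar_head = Linear(cfg.r_heads * d_out, cfg.d_z, rng)

    # -- message passing ------------------------------------------------------

    def node_view(self, g: MoleculeGraph) -> Tensor:
        h0 = self.w_nin(Tensor(g.node_feats)).relu()
        h = h0
        for _ in range(self.cfg.n_layers):
            agg = concat([Tensor(g.adj) @ h, Tensor(g.edge_feat_sum)], axis=1)
            h = (self.w_node(agg) + h0).relu()
        return h

    def edge_view(self, g: MoleculeGraph) -> Tensor:
        """Returns the per-node output of the edge-central view (n x h_edge)."""
        if len(g.edges) == 0:
            return self._edge_view_empty(g)
        h0 = self.w_ein(Tensor(g.edge_feats)).relu()
        h = h0
        for _ in range(self.cfg.n_layers):
            agg = concat([Tensor(g.edge_agg) @ h, Tensor(g.edge_node_sum)], axis=1)
            h = (self.w_edge(agg) + h0).relu()
        readin = concat([Tensor(g.incoming) @ h, Tensor(g.node_feat_nbr_sum)], axis=1)
        return self.w_eout(readin).relu()

    def _edge_view_empty(self, g: MoleculeGraph) -> Tensor:
        agg = Tensor(np.zeros((g.n_nodes, self.cfg.h_edge)))
        readin = concat([agg, Tensor(g.node_feat_nbr_sum)], axis=1)
        return self.w_eout(readin).relu()

    def node_matrix(self, g: MoleculeGraph) -> Tensor:
        """H_node: n x (h_node + h_edge), node view next to edge view."""
        return concat([self.node_view(g), self.edge_view(g)], axis=1)

    # -- readout --------------------------------------------------------------

    def _attend(self, rows: Tensor) -> Tensor:
        scores = self.attn_w2(self.attn_w1(rows).tanh())  # n_sel x r
        attn = scores.softmax(axis=0)  # per-head distribution over nodes
        return (attn.T @ rows).flatten()  # r x d_out, flattened

    def split_readout(self, h_node: Tensor, mask: Sequence[int]) -> SplitEmbedding:
        n = h_node.data.shape[0]
        mask = np.asarray(sorted(mask), dtype=np.intp)
        if len(mask) == 0:
            raise ValueError("scaffold mask must be non-empty")
        if mask.min() < 0 or mask.max() >= n:
            raise ValueError("scaffold mask index out of range")
        side = np.setdiff1d(np.arange(n), mask)
        z_sca = self._attend(gather_rows(h_node, mask))
        if len(side) == 0:
            z_side = Tensor(np.zeros(z_sca.data.shape))
        else:
            z_side = self._attend(gather_rows(h_node, side))
        return SplitEmbedding(z_sca=z_sca, z_side=z_side)

    def encode_latent(self, z_sca: Tensor) -> LatentPosterior:
        row = z_sca.reshape(1, -1)
        mu = self.mu_head(row).flatten()
        logvar = self.logvar_head(row).flatten()
        sigma = (logvar * 0.5).exp()
        return LatentPosterior(mu=mu, sigma=sigma)

    def __call__(self, g: MoleculeGraph, mask: Sequence[int]) -> Tuple[SplitEmbedding, LatentPosterior]:
        split = self.split_readout(self.node_matrix(g), mask)
        return split, self.encode_latent(split.z_sca)

    @property
    def embedding_len(self) -> int:
        return self.cfg.r_heads * (self.cfg.h_node + self.cfg.h_edge)
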