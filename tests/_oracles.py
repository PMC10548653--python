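"""Independent brute-force oracles shared by unit and acceptance tests."""

import itertools

import numpy as np

from scaffhop.encoder import EDGE_FEAT_DIM, NODE_FEAT_DIM, MolEncoder


def relu(x):
    return np.maximum(x, 0.0)


def oracle_forward(enc: MolEncoder, n, edges, X, E_und):
    """Naive nested-loop implementation of the node view, edge view and
    edge-to-node readin, using the encoder's own weight matrices."""
    L = enc.cfg.n_layers
    Wnin, Wein = enc.w_nin.W.data, enc.w_ein.W.data
    Wnode, Wedge, Weout = enc.w_node.W.data, enc.w_edge.W.data, enc.w_eout.W.data
    nbrs = {v: [] for v in range(n)}
    efeat = {}
    for k, (a, b) in enumerate(edges):
        nbrs[a].append(b)
        nbrs[b].append(a)
        efeat[(a, b)] = E_und[k]
        efeat[(b, a)] = E_und[k]
    h0 = {v: relu(X[v] @ Wnin) for v in range(n)}
    h = dict(h0)
    for _ in range(L):
        new = {}
        for v in range(n):
            acc = np.zeros(enc.cfg.h_node + EDGE_FEAT_DIM)
            for u in nbrs[v]:
                acc += np.concatenate([h[u], efeat[(v, u)]])
            new[v] = relu(acc @ Wnode + h0[v])
        h = new
    H_nout = np.stack([h[v] for v in range(n)])
    directed = list(efeat)
    he0 = {d: relu(efeat[d] @ Wein) for d in directed}
    he = dict(he0)
    for _ in range(L):
        new = {}
        for (v, w) in directed:
            acc = np.zeros(enc.cfg.h_edge + NODE_FEAT_DIM)
            for u in nbrs[v]:
                if u == w:
                    continue
                acc += np.concatenate([he[(u, v)], X[u]])
            new[(v, w)] = relu(acc @ Wedge + he0[(v, w)])
        he = new
    H_eout = np.zeros((n, enc.cfg.h_edge))
    for v in range(n):
        acc = np.zeros(enc.cfg.h_edge + NODE_FEAT_DIM)
        for u in nbrs[v]:
            acc += np.concatenate([he[(u, v)], X[u]])
        H_eout[v] = relu(acc @ Weout)
    return np.concatenate([H_nout, H_eout], axis=1)


def connected_graphs(n):
    """All connected labeled simple graphs on n nodes, as edge lists."""
    possible = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(possible)):
        edges = [e for i, e in enumerate(possible) if bits >> i & 1]
        adj = {v: set() for v in range(n)}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        seen = {0}
        stack = [0]
        while stack:
            for u in adj[stack.pop()]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        if len(seen) == n:
            yield edges
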