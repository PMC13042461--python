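"""Shared brute-force oracles used by the unit and acceptance suites."""

import numpy as np

from latentmol.chemio import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolecularGraph
from latentmol.encoder import Encoder
from latentmol.nn import Tensor


def random_graph(rng, n_atoms, n_bonds):
    """A random featurized graph (paired directed edges, no self loops)."""
    pairs = set()
    while len(pairs) < n_bonds:
        u, v = rng.integers(0, n_atoms, 2)
        if u != v:
            pairs.add((min(u, v), max(u, v)))
    src, dst, bf = [], [], []
    for u, v in sorted(pairs):
        row = rng.random(BOND_FEATURE_DIM)
        for a, b in ((u, v), (v, u)):
            src.append(a)
            dst.append(b)
            bf.append(row)
    return MolecularGraph(
        atom_features=rng.random((n_atoms, ATOM_FEATURE_DIM)),
        bond_features=np.asarray(bf).reshape(len(src), BOND_FEATURE_DIM),
        edge_src=np.asarray(src, dtype=np.intp),
        edge_dst=np.asarray(dst, dtype=np.intp),
    )


def dense_oracle(enc: Encoder, g: MolecularGraph):
    """Plain-loop recomputation of the encoder forward pass.

    Implements the atom embedding, the message-passing rounds, the bias-free
    gated readout and softmax attention pooling with explicit Python loops
    and dense matrix-vector products, independent of the vectorized path.
    """
    relu = lambda x: np.maximum(x, 0.0)
    W = {name: lin.weight.data for name, lin in [
        ("in", enc.atom_in), ("bin", enc.bond_in), ("c", enc.contact),
        ("a", enc.aggregate), ("gs", enc.gate_self), ("gb", enc.gate_bond),
        ("ga", enc.gate_atom)]}
    b = {name: lin.bias.data for name, lin in [
        ("in", enc.atom_in), ("bin", enc.bond_in), ("c", enc.contact),
        ("a", enc.aggregate)]}
    n = g.n_atoms
    h = np.stack([relu(W["in"].T @ g.atom_features[v] + b["in"]) for v in range(n)])
    e = np.stack([relu(W["bin"].T @ g.bond_features[k] + b["bin"])
                  for k in range(g.n_edges)]) if g.n_edges else np.zeros((0, h.shape[1]))
    for _ in range(enc.config.mp_rounds):
        e_new = np.stack([
            relu(W["c"].T @ np.concatenate([h[g.edge_src[k]], e[k]]) + b["c"])
            for k in range(g.n_edges)]) if g.n_edges else e
        h_new = np.empty_like(h)
        for v in range(n):
            agg = np.zeros(h.shape[1])
            for k in range(g.n_edges):
                if g.edge_dst[k] == v:
                    agg += e_new[k]
            h_new[v] = relu(W["a"].T @ np.concatenate([h[v], agg]) + b["a"])
        h, e = h_new, e_new
    h_fin = np.empty_like(h)
    for v in range(n):
        neigh = np.zeros(h.shape[1])
        for k in range(g.n_edges):
            if g.edge_dst[k] == v:
                neigh += (W["gb"].T @ e[k]) * (W["ga"].T @ h[g.edge_src[k]])
        h_fin[v] = (W["gs"].T @ h[v]) * neigh
    logits = enc.attention_mlp(Tensor(h_fin)).data.ravel()
    w = np.exp(logits - logits.max())
    w = w / w.sum()
    pooled = (h_fin * w[:, None]).sum(axis=0)
    return h, e, h_fin, w, pooled
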