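"""Graph-neural representation module.

A Weisfeiler-Lehman style message-passing network turns a featurized
molecular graph into per-atom vectors, a gated readout mixes each atom with
its bond-weighted neighbourhood, and a global attention pooling collapses the
graph into one 1D representation vector.  Two projection heads map a pair of
representation vectors onto the 8-component similarity label (3 fingerprint
similarities, 5 CSPS descriptors).

Update rules, per message-passing round (weights shared across rounds):

    h_v(0)   = ReLU(W_in h_v + b_in)
    m_uv     = ReLU(W_contact [h_u || e_uv] + b_contact)
    e_uv     <- m_uv
    h_v      <- ReLU(W_agg [h_v || sum_{u in N(v)} e_uv] + b_agg)
    h_v^fin  = W_self h_v  ⊙  sum_{u in N(v)} (W_bond e_uv ⊙ W_atom h_u)

with the three readout gates bias-free.  Pooling weights come from an MLP
(sigmoid after every linear layer, including the scalar output) normalized by
a softmax over the atoms of each graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemio import (
    ATOM_FEATURE_DIM, BOND_FEATURE_DIM, Molecule, MolecularGraph, featurize,
)
from .nn import (
    AdamW, BatchNorm1d, Linear, Module, Tensor, concat, gather_rows, segment_sum,
)

FULL_REP_DIM = 2048


def _scale(width: int, rep_dim: int, minimum: int = 4) -> int:
    """Scale a full-profile layer width proportionally to rep_dim."""
    return max(minimum, int(round(width * rep_dim / FULL_REP_DIM)))


@dataclass
class EncoderConfig:
    rep_dim: int = FULL_REP_DIM
    mp_rounds: int = 4
    attention_mlp_widths: tuple[int, ...] = (6144, 1024, 128, 128, 128, 1)
    seed: int = 0

    def __post_init__(self):
        if self.rep_dim < 8:
            raise ValueError("rep_dim must be at least 8")
        if self.mp_rounds < 1:
            raise ValueError("mp_rounds must be at least 1")

    @classmethod
    def desk(cls, rep_dim: int = 128, seed: int = 0) -> "EncoderConfig":
        widths = tuple(_scale(w, rep_dim) for w in (6144, 1024, 128, 128, 128))
        return cls(rep_dim=rep_dim, attention_mlp_widths=widths + (1,), seed=seed)


@dataclass
class ProjectionHeadConfig:
    rep_dim: int = FULL_REP_DIM
    expansion_factor: int = 5
    reduction_widths: tuple[int, ...] = (2048, 512, 512, 512)
    output_dim: int = 3

    @property
    def pair_dim(self) -> int:
        return 2 * self.rep_dim

    @property
    def expanded_dim(self) -> int:
        return self.pair_dim * self.expansion_factor

    @property
    def concat_dim(self) -> int:
        # expanded features concatenated with the original pair
        return self.pair_dim * (1 + self.expansion_factor)

    def width_trace(self) -> tuple[int, ...]:
        return (self.concat_dim,) + self.reduction_widths + (self.output_dim,)

    @classmethod
    def desk(cls, rep_dim: int = 128, output_dim: int = 3) -> "ProjectionHeadConfig":
        return cls(rep_dim=rep_dim, output_dim=output_dim,
                   reduction_widths=tuple(_scale(w, rep_dim) for w in (2048, 512, 512, 512)))


class AttentionPoolMLP(Module):
    """Per-atom attention logit MLP: sigmoid after every linear layer,
    batch normalization after the first two."""

    def __init__(self, rep_dim: int, widths: tuple[int, ...], rng):
        super().__init__()
        dims = (rep_dim,) + tuple(widths)
        self.linears = [Linear(dims[i], dims[i + 1], rng, init="xavier")
                        for i in range(len(dims) - 1)]
        self.norms = [BatchNorm1d(dims[1]), BatchNorm1d(dims[2])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, lin in enumerate(self.linears):
            x = lin(x)
            if i < 2:
                x = self.norms[i](x)
            x = x.sigmoid()
        return x


class Encoder(Module):
    """Molecular-graph encoder producing rep_dim representation vectors."""

    def __init__(self, config: EncoderConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.rep_dim
        self.atom_in = Linear(ATOM_FEATURE_DIM, d, rng)
        self.bond_in = Linear(BOND_FEATURE_DIM, d, rng)
        self.contact = Linear(2 * d, d, rng)
        self.aggregate = Linear(2 * d, d, rng)
        # the three readout gates are bias-free
        self.gate_self = Linear(d, d, rng, bias=False)
        self.gate_bond = Linear(d, d, rng, bias=False)
        self.gate_atom = Linear(d, d, rng, bias=False)
        self.attention_mlp = AttentionPoolMLP(d, config.attention_mlp_widths[:-1] + (1,), rng)

    # -- stages (exposed individually for oracle checks) --------------------
    def embed_atoms(self, g: MolecularGraph) -> Tensor:
        if g.atom_features.shape[1] != ATOM_FEATURE_DIM:
            raise ValueError("atom feature width mismatch")
        return self.atom_in(Tensor(g.atom_features)).relu()

    def embed_bonds(self, g: MolecularGraph) -> Tensor:
        return self.bond_in(Tensor(g.bond_features)).relu()

    def propagate_messages(self, g: MolecularGraph, h: Tensor, e: Tensor,
                           rounds: int | None = None) -> tuple[Tensor, Tensor]:
        rounds = self.config.mp_rounds if rounds is None else rounds
        n = h.shape[0]
        for _ in range(rounds):
            h_src = gather_rows(h, g.edge_src)
            m = self.contact(concat([h_src, e], axis=-1)).relu()
            e = m
            agg = segment_sum(e, g.edge_dst, n)
            h = self.aggregate(concat([h, agg], axis=-1)).relu()
        return h, e

    def gated_readout(self, g: MolecularGraph, h: Tensor, e: Tensor) -> Tensor:
        gated = self.gate_bond(e) * self.gate_atom(gather_rows(h, g.edge_src))
        neighbour = segment_sum(gated, g.edge_dst, h.shape[0])
        return self.gate_self(h) * neighbour

    def attention_pool(self, node_vectors: Tensor,
                       graph_ids: np.ndarray | None = None,
                       n_graphs: int = 1) -> tuple[Tensor, Tensor]:
        """Softmax-normalized attention pooling; returns (pooled, weights)."""
        n = node_vectors.shape[0]
        if n == 0:
            raise ValueError("cannot pool an empty graph")
        if graph_ids is None:
            graph_ids = np.zeros(n, dtype=np.intp)
        logits = self.attention_mlp(node_vectors)          # (n, 1)
        # per-graph softmax via segment arithmetic (shift is grad-free)
        shift = np.full(n_graphs, -np.inf)
        np.maximum.at(shift, graph_ids, logits.data.ravel())
        shifted = logits - Tensor(shift[graph_ids][:, None])
        num = shifted.exp()
        den = segment_sum(num, graph_ids, n_graphs)
        weights = num * gather_rows(den, graph_ids) ** -1.0
        pooled = segment_sum(node_vectors * weights, graph_ids, n_graphs)
        return pooled, weights

    # -- full passes ---------------------------------------------------------
    def forward_graphs(self, graphs: list[MolecularGraph]) -> Tensor:
        """Encode a batch of graphs as one block-diagonal graph."""
        offsets = np.cumsum([0] + [g.n_atoms for g in graphs])
        merged = MolecularGraph(
            atom_features=np.concatenate([g.atom_features for g in graphs]),
            bond_features=np.concatenate([g.bond_features for g in graphs])
            if any(g.n_edges for g in graphs) else np.zeros((0, BOND_FEATURE_DIM)),
            edge_src=np.concatenate([g.edge_src + o for g, o in zip(graphs, offsets)]).astype(np.intp),
            edge_dst=np.concatenate([g.edge_dst + o for g, o in zip(graphs, offsets)]).astype(np.intp),
        )
        graph_ids = np.concatenate([np.full(g.n_atoms, i, dtype=np.intp)
                                    for i, g in enumerate(graphs)])
        h = self.embed_atoms(merged)
        e = self.embed_bonds(merged)
        h, e = self.propagate_messages(merged, h, e)
        h_final = self.gated_readout(merged, h, e)
        pooled, _ = self.attention_pool(h_final, graph_ids, len(graphs))
        return pooled

    def encode(self, m: Molecule | str) -> np.ndarray:
        """Deterministic 1D representation of a molecule (evaluation mode)."""
        was_training = self.training
        self.eval()
        rep = self.forward_graphs([featurize(m)]).data[0].copy()
        if was_training:
            self.train()
        return rep

    def atom_attention(self, m: Molecule | str) -> np.ndarray:
        """Per-atom pooling weights (sum to 1), for interpretability."""
        was_training = self.training
        self.eval()
        g = featurize(m)
        h = self.embed_atoms(g)
        e = self.embed_bonds(g)
        h, e = self.propagate_messages(g, h, e)
        h_final = self.gated_readout(g, h, e)
        _, weights = self.attention_pool(h_final)
        if was_training:
            self.train()
        return weights.data.ravel().copy()


class ProjectionHead(Module):
    """Pair representation -> similarity components, all squashed to (0, 1).

    Rectifier expansion (LeakyReLU + batch norm) to five times the pair
    width, concatenation with the original pair, then staged reductions with
    SiLU between linears and batch norm after the first two, ending in a
    sigmoid output neuron.
    """

    def __init__(self, config: ProjectionHeadConfig, rng):
        super().__init__()
        self.config = config
        self.expand = Linear(config.pair_dim, config.expanded_dim, rng)
        self.expand_norm = BatchNorm1d(config.expanded_dim)
        dims = (config.concat_dim,) + config.reduction_widths
        self.reduce = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.reduce_norms = [BatchNorm1d(dims[1]), BatchNorm1d(dims[2])]
        self.out = Linear(dims[-1], config.output_dim, rng, init="xavier")

    def __call__(self, pair: Tensor) -> Tensor:
        x = self.expand_norm(self.expand(pair).leaky_relu())
        x = concat([x, pair], axis=-1)
        for i, lin in enumerate(self.reduce):
            x = lin(x)
            if i < 2:
                x = self.reduce_norms[i](x)
            x = x.silu()
        return self.out(x).sigmoid()


class SimilarityProjector(Module):
    """The two similarity heads: fingerprint (3 outputs) and CSPS (5 outputs)."""

    def __init__(self, rep_dim: int = FULL_REP_DIM, seed: int = 0,
                 desk: bool = False):
        super().__init__()
        rng = np.random.default_rng(seed + 101)
        if desk or rep_dim != FULL_REP_DIM:
            fp_cfg = ProjectionHeadConfig.desk(rep_dim, output_dim=3)
            csps_cfg = ProjectionHeadConfig.desk(rep_dim, output_dim=5)
        else:
            fp_cfg = ProjectionHeadConfig(rep_dim=rep_dim, output_dim=3)
            csps_cfg = ProjectionHeadConfig(rep_dim=rep_dim, output_dim=5)
        self.fingerprint_head = ProjectionHead(fp_cfg, rng)
        self.csps_head = ProjectionHead(csps_cfg, rng)

    def __call__(self, query_reps: Tensor, ref_reps: Tensor) -> Tensor:
        """Predict the 8 similarity components for aligned (query, ref) rows.

        Output column order matches the label layout: 5 CSPS then 3
        fingerprint components.
        """
        pair = concat([query_reps, ref_reps], axis=-1)
        return concat([self.csps_head(pair), self.fingerprint_head(pair)], axis=-1)


class RepresentationModel(Module):
    """Encoder + similarity projection heads, trained jointly."""

    def __init__(self, config: EncoderConfig):
        super().__init__()
        self.encoder = Encoder(config)
        self.projector = SimilarityProjector(rep_dim=config.rep_dim,
                                             seed=config.seed)

    def project_pair(self, eq: np.ndarray, er: np.ndarray) -> np.ndarray:
        """8-float similarity prediction for one representation pair."""
        eq, er = np.atleast_2d(eq), np.atleast_2d(er)
        if eq.shape[1] != self.encoder.config.rep_dim:
            raise ValueError("representation length must equal rep_dim")
        was_training = self.training
        self.eval()
        out = self.projector(Tensor(eq), Tensor(er)).data.copy()
        if was_training:
            self.train()
        return out[0] if out.shape[0] == 1 else out
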