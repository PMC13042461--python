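"""Autoregressive SMILES reconstruction from 1D representation vectors.

A transformer decoder treats the molecular representation as a one-position
cross-attention memory.  Target tokens are embedded and rotated with rotary
positional encoding before entering the causally masked self-attention stack;
a three-layer MLP head maps the hidden states to vocabulary logits.

Sampling is Gumbel-max at temperature T:

    s = log softmax(y / T) + g,     g = -log(-log u + eps),  u ~ U(0, 1)

and the sampled index is argmax(s), which draws exactly from softmax(y/T).

The training loss is frequency-weighted cross-entropy: each target token's
loss is scaled by w_i = min(N_total / f_i, 100) where f_i is its count in the
batch and N_total the number of valid (non-pad, non-start) targets; unseen
tokens get weight 1, pad targets are excluded, and the sum is divided by the
valid-token count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import DataStructs
from rdkit.Chem.AtomPairs import Pairs

from .chemio import Molecule, TokenSequence, Vocabulary, detokenize
from .nn import Embedding, LayerNorm, Linear, Module, Tensor, concat

FULL_MODEL_DIM = 2048
GUMBEL_EPS = 1e-10
WEIGHT_CAP = 100.0


def _scale(width: int, model_dim: int, minimum: int = 8) -> int:
    return max(minimum, int(round(width * model_dim / FULL_MODEL_DIM)))


@dataclass
class DecoderConfig:
    vocab_size: int
    model_dim: int = FULL_MODEL_DIM
    layers: int = 4
    heads: int = 32
    head_mlp_widths: tuple[int, ...] = (4096, 1024)
    max_len: int = 128

    def __post_init__(self):
        if self.model_dim % self.heads != 0:
            raise ValueError("heads must divide model_dim")

    @classmethod
    def desk(cls, vocab_size: int, model_dim: int = 128, heads: int = 4,
             layers: int = 4, max_len: int = 128) -> "DecoderConfig":
        return cls(vocab_size=vocab_size, model_dim=model_dim, heads=heads,
                   layers=layers, max_len=max_len,
                   head_mlp_widths=tuple(_scale(w, model_dim) for w in (4096, 1024)))


@dataclass
class SamplerState:
    temperature: float = 1.0
    noise_scale: float = 0.0
    mask_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.noise_scale < 0 or not (0 <= self.mask_probability <= 1):
            raise ValueError("invalid sampler state")


# ---------------------------------------------------------------------------
# Rotary positional encoding
# ---------------------------------------------------------------------------

def _rope_tables(length: int, dim: int) -> tuple[np.ndarray, np.ndarray]:
    half = dim // 2
    inv_freq = 1.0 / (10000.0 ** (np.arange(half) / half))
    angles = np.arange(length)[:, None] * inv_freq[None, :]
    cos = np.concatenate([np.cos(angles), np.cos(angles)], axis=-1)
    sin = np.concatenate([np.sin(angles), np.sin(angles)], axis=-1)
    return cos, sin


def apply_rope(x: Tensor) -> Tensor:
    """Rotate the last axis pairwise by position-dependent angles.

    Uses the half-split convention: rotate_half(x) = [-x_hi, x_lo].
    ``x`` has shape (..., L, D) with D even.
    """
    L, D = x.shape[-2], x.shape[-1]
    cos, sin = _rope_tables(L, D)
    half = D // 2
    lo = x[..., :, :half]
    hi = x[..., :, half:]
    rotated = concat([-hi, lo], axis=-1)
    return x * Tensor(cos) + rotated * Tensor(sin)


# ---------------------------------------------------------------------------
# Transformer decoder
# ---------------------------------------------------------------------------

class MultiHeadAttention(Module):
    def __init__(self, dim: int, heads: int, rng):
        super().__init__()
        self.heads = heads
        self.dh = dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.heads, self.dh).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor,
                 mask: np.ndarray | None = None) -> Tensor:
        B, Lq = query.shape[0], query.shape[1]
        Lk = key.shape[1]
        q = self._split(self.wq(query), B, Lq)
        k = self._split(self.wk(key), B, Lk)
        v = self._split(self.wv(value), B, Lk)
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(self.dh))
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Lq, self.heads * self.dh)
        return self.wo(out)


class DecoderLayer(Module):
    def __init__(self, dim: int, heads: int, rng):
        super().__init__()
        self.self_attn = MultiHeadAttention(dim, heads, rng)
        self.cross_attn = MultiHeadAttention(dim, heads, rng)
        self.ff1 = Linear(dim, 4 * dim, rng)
        self.ff2 = Linear(4 * dim, dim, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.norm3 = LayerNorm(dim)

    def __call__(self, x: Tensor, memory: Tensor, causal_mask: np.ndarray) -> Tensor:
        x = self.norm1(x + self.self_attn(x, x, x, causal_mask))
        x = self.norm2(x + self.cross_attn(x, memory, memory))
        x = self.norm3(x + self.ff2(self.ff1(x).silu()))
        return x


class Decoder(Module):
    """Representation-conditioned SMILES decoder."""

    def __init__(self, config: DecoderConfig, rep_dim: int, seed: int = 0):
        super().__init__()
        self.config = config
        self.rep_dim = rep_dim
        rng = np.random.default_rng(seed + 202)
        d = config.model_dim
        self.embedding = Embedding(config.vocab_size, d, rng)
        self.memory_proj = Linear(rep_dim, d, rng)
        # representation magnitudes vary over orders of magnitude between
        # encoders; the memory path divides by this calibrated scale so the
        # cross-attention values start well-conditioned
        self._buffers = {"rep_scale": np.asarray(1.0)}
        self.layers = [DecoderLayer(d, config.heads, rng) for _ in range(config.layers)]
        dims = (d,) + config.head_mlp_widths + (config.vocab_size,)
        self.head = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]

    def calibrate_memory_scale(self, reps: np.ndarray):
        """Set the memory normalization from a set of training representations."""
        scale = float(np.abs(np.asarray(reps)).max())
        self._buffers["rep_scale"] = np.asarray(max(scale, 1e-8))

    def _head_mlp(self, x: Tensor) -> Tensor:
        for i, lin in enumerate(self.head):
            x = lin(x)
            if i < len(self.head) - 1:
                x = x.silu()
        return x

    def forward_tokens(self, reps: np.ndarray | Tensor, tokens: np.ndarray) -> Tensor:
        """Logits for next-token prediction at every input position.

        ``reps``: (B, rep_dim); ``tokens``: (B, L) int input prefix.  Returns
        (B, L, vocab) logits; position i sees only tokens <= i (causal mask).
        """
        reps = reps if isinstance(reps, Tensor) else Tensor(reps)
        tokens = np.atleast_2d(np.asarray(tokens, dtype=np.intp))
        B, L = tokens.shape
        if L > self.config.max_len:
            raise ValueError(f"sequence length {L} exceeds max_len {self.config.max_len}")
        x = apply_rope(self.embedding(tokens))
        scaled = reps * (1.0 / float(self._buffers["rep_scale"]))
        memory = self.memory_proj(scaled).reshape(B, 1, self.config.model_dim)
        causal = np.where(np.triu(np.ones((L, L)), k=1) > 0, -1e9, 0.0)
        for layer in self.layers:
            x = layer(x, memory, causal)
        return self._head_mlp(x)

    def teacher_forced_logits(self, rep: np.ndarray, target: TokenSequence) -> Tensor:
        """Per-position logits for a single target sequence.

        Input is the target without its final token; logits row i predicts
        target token i+1, so the shape is (len(target) - 1, vocab).
        """
        idx = np.asarray(target.indices, dtype=np.intp)
        return self.forward_tokens(np.atleast_2d(rep), idx[None, :-1]).reshape(
            len(idx) - 1, self.config.vocab_size)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

class LossError(ValueError):
    pass


def token_weights(targets: np.ndarray, vocab_size: int, pad_index: int = 0,
                  cap: float = WEIGHT_CAP) -> np.ndarray:
    """Per-vocabulary-token loss weights from batch frequencies.

    w_i = min(N_total / f_i, cap) for tokens present in the batch, 1 for
    absent tokens; N_total counts valid (non-pad) target positions.
    """
    targets = np.asarray(targets, dtype=np.intp).ravel()
    valid = targets != pad_index
    counts = np.bincount(targets[valid], minlength=vocab_size).astype(np.float64)
    n_total = float(valid.sum())
    weights = np.ones(vocab_size, dtype=np.float64)
    present = counts > 0
    weights[present] = np.minimum(n_total / counts[present], cap)
    return weights


def weighted_ce_loss(logits: Tensor, targets: np.ndarray, pad_index: int = 0,
                     cap: float = WEIGHT_CAP) -> Tensor:
    """Frequency-weighted cross-entropy over valid target positions.

    ``logits``: (..., L, vocab); ``targets``: (..., L) ground-truth token at
    each predicted position (the start token never appears here because
    prediction begins at the second sequence position).
    """
    targets = np.asarray(targets, dtype=np.intp)
    if logits.shape[:-1] != targets.shape:
        raise LossError("logits and targets disagree in shape")
    vocab = logits.shape[-1]
    flat_logits = logits.reshape(-1, vocab)
    flat_targets = targets.ravel()
    valid = flat_targets != pad_index
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise LossError("no valid (non-pad) target tokens in batch")
    weights = token_weights(targets, vocab, pad_index=pad_index, cap=cap)
    lp = flat_logits.log_softmax(axis=-1)
    picked = lp[np.arange(flat_targets.size), flat_targets]
    scale = weights[flat_targets] * valid
    return -(picked * Tensor(scale)).sum() * (1.0 / n_valid)


# ---------------------------------------------------------------------------
# Sampling / perturbation
# ---------------------------------------------------------------------------

def gumbel_sample(logits: np.ndarray, temperature: float,
                  rng: np.random.Generator, eps: float = GUMBEL_EPS) -> int:
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    y = np.asarray(logits, dtype=np.float64) / temperature
    logp = y - y.max()
    logp = logp - np.log(np.exp(logp).sum())
    u = rng.random(logp.shape)
    g = -np.log(-np.log(u) + eps)
    return int(np.argmax(logp + g))


def perturb_representation(rep: np.ndarray, noise_scale: float,
                           mask_probability: float = 0.5,
                           rng: np.random.Generator | None = None,
                           seed: int | None = None) -> np.ndarray:
    """v = E + N * n ⊙ m with standard-normal n and Bernoulli(p) mask m."""
    if noise_scale < 0:
        raise ValueError("noise scale must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    rep = np.asarray(rep, dtype=np.float64)
    n = rng.standard_normal(rep.shape)
    m = rng.random(rep.shape) < mask_probability
    return rep + noise_scale * n * m


def decode(decoder: Decoder, vocabulary: Vocabulary, rep: np.ndarray,
           temperature: float = 1.0, max_len: int | None = None,
           rng: np.random.Generator | None = None,
           seed: int | None = None) -> tuple[str, bool]:
    """Autoregressively sample a SMILES from a representation vector.

    Stops at the end token or ``max_len``; returns (smiles, valid) where
    validity means RDKit sanitization (valence + aromaticity) succeeds.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    max_len = max_len or decoder.config.max_len
    was_training = decoder.training
    decoder.eval()
    tokens = [vocabulary.start_index]
    rep2d = np.atleast_2d(rep)
    while len(tokens) < max_len:
        logits = decoder.forward_tokens(rep2d, np.asarray(tokens)[None, :]).data[0, -1]
        nxt = gumbel_sample(logits, temperature, rng)
        if nxt == vocabulary.end_index:
            break
        tokens.append(nxt)
    if was_training:
        decoder.train()
    smiles = detokenize(TokenSequence(indices=tuple(tokens + [vocabulary.end_index])),
                        vocabulary)
    valid = Chem.MolFromSmiles(smiles) is not None and smiles != ""
    return smiles, valid


def assess_reconstruction(original: Molecule | str, decoded: str) -> float:
    """AtomPairs fingerprint Tanimoto between source and decoded structures.

    Unparseable decodes score 0 by convention.
    """
    orig = original.to_rdkit() if isinstance(original, Molecule) \
        else Chem.MolFromSmiles(original)
    dec = Chem.MolFromSmiles(decoded) if decoded else None
    if orig is None or dec is None:
        return 0.0
    return float(DataStructs.TanimotoSimilarity(
        Pairs.GetAtomPairFingerprint(orig), Pairs.GetAtomPairFingerprint(dec)))
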