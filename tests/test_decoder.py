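"""Decoder contracts: causality, rotary encoding, weighted loss, sampling."""

import numpy as np
import pytest

from latentmol.chemio import TokenSequence, build_vocabulary, canonicalize, tokenize
from latentmol.decoder import (
    Decoder, DecoderConfig, LossError, SamplerState, apply_rope,
    assess_reconstruction, decode, gumbel_sample, perturb_representation,
    token_weights, weighted_ce_loss,
)
from latentmol.nn import Tensor


@pytest.fixture(scope="module")
def tiny_decoder():
    return Decoder(DecoderConfig.desk(vocab_size=12, model_dim=32, heads=4,
                                      layers=2), rep_dim=16, seed=7).eval()


# -- architecture ------------------------------------------------------------

def test_heads_must_divide_width():
    with pytest.raises(ValueError):
        DecoderConfig(vocab_size=10, model_dim=100, heads=32)


def test_full_scale_head_mlp_widths():
    cfg = DecoderConfig(vocab_size=43)
    assert cfg.model_dim == 2048 and cfg.layers == 4 and cfg.heads == 32
    assert cfg.head_mlp_widths == (4096, 1024)


def test_causality_prefix_dependence(tiny_decoder, rng):
    """Changing token j never changes logits at positions < j."""
    for _ in range(20):
        L = int(rng.integers(3, 9))
        rep = rng.normal(0, 1, 16)
        toks = rng.integers(0, 12, size=L)
        base = tiny_decoder.forward_tokens(rep[None], toks[None]).data[0]
        j = int(rng.integers(1, L))
        mutated = toks.copy()
        mutated[j] = (mutated[j] + 1 + rng.integers(0, 10)) % 12
        out = tiny_decoder.forward_tokens(rep[None], mutated[None]).data[0]
        np.testing.assert_allclose(out[:j], base[:j], atol=1e-9)
        assert not np.allclose(out[j], base[j])


def test_teacher_forced_logits_shape(tiny_decoder, rng):
    target = TokenSequence(indices=(1, 4, 5, 6, 2))
    logits = tiny_decoder.teacher_forced_logits(rng.normal(0, 1, 16), target)
    assert logits.shape == (4, 12)


def test_different_representations_give_different_logits(tiny_decoder, rng):
    toks = np.array([[1, 3, 4, 5]])
    a = tiny_decoder.forward_tokens(rng.normal(0, 1, (1, 16)), toks).data
    b = tiny_decoder.forward_tokens(rng.normal(0, 1, (1, 16)), toks).data
    assert not np.allclose(a, b)


def test_overlong_target_rejected(tiny_decoder):
    toks = np.zeros((1, tiny_decoder.config.max_len + 1), dtype=int)
    with pytest.raises(ValueError, match="max_len"):
        tiny_decoder.forward_tokens(np.zeros((1, 16)), toks)


def test_rope_preserves_norm_and_position_zero(rng):
    x = rng.normal(0, 1, (1, 5, 8))
    out = apply_rope(Tensor(x)).data
    np.testing.assert_allclose(out[0, 0], x[0, 0], atol=1e-12)  # angle 0
    np.testing.assert_allclose(np.linalg.norm(out, axis=-1),
                               np.linalg.norm(x, axis=-1), atol=1e-9)


# -- weighted cross-entropy --------------------------------------------------

def test_token_weight_cap_at_rare_token():
    targets = np.concatenate([[5], np.full(999_999, 3)])
    w = token_weights(targets, vocab_size=10)
    assert w[5] == 100.0                      # min(1e6 / 1, 100)
    assert w[3] == pytest.approx(1e6 / 999_999)


def test_token_weight_absent_token_is_one():
    w = token_weights(np.array([3, 3, 4]), vocab_size=6)
    assert w[5] == 1.0
    assert w[0] == 1.0                        # pad excluded from counting


def test_uniform_frequencies_reduce_to_plain_mean_ce(rng):
    logits = Tensor(rng.normal(0, 1, (2, 3, 5)))
    targets = np.array([[1, 2, 3], [4, 1, 2]])  # token 1,2 twice; 3,4 once
    # make frequencies uniform: each of 1..4 appears once in a 4-token batch
    targets = np.array([[1, 2], [3, 4]])
    logits = Tensor(rng.normal(0, 1, (2, 2, 5)))
    loss = weighted_ce_loss(logits, targets)
    lp = logits.data - np.log(np.exp(logits.data).sum(-1, keepdims=True))
    plain = -np.mean([lp[i, j, targets[i, j]] for i in range(2) for j in range(2)])
    # uniform weight = N/f = 4/1 capped at 100 -> 4, applied to every token,
    # then averaged: equals 4x the plain mean; relative shape is preserved
    assert loss.data == pytest.approx(4 * plain)


def test_hand_computed_toy_batch():
    """2-token batch with hand-set logits matches manual arithmetic,
    including pad exclusion."""
    logits = Tensor(np.array([[[2.0, 0.0, 1.0], [0.0, 3.0, 0.0]],
                              [[1.0, 1.0, 1.0], [5.0, 0.0, 0.0]]]))
    targets = np.array([[2, 1], [1, 0]])      # last position is pad
    z = logits.data
    lp = z - np.log(np.exp(z).sum(-1, keepdims=True))
    n_total = 3.0                             # three non-pad targets
    w2, w1 = min(n_total / 1, 100), min(n_total / 2, 100)
    expected = -(w2 * lp[0, 0, 2] + w1 * lp[0, 1, 1] + w1 * lp[1, 0, 1]) / 3.0
    loss = weighted_ce_loss(logits, targets)
    assert loss.data == pytest.approx(expected)


def test_all_pad_batch_raises():
    with pytest.raises(LossError):
        weighted_ce_loss(Tensor(np.zeros((1, 2, 4))), np.zeros((1, 2), dtype=int))


# -- sampling ----------------------------------------------------------------

def test_gumbel_low_temperature_is_argmax(rng):
    y = np.array([0.1, 5.0, -2.0, 1.0])
    draws = {gumbel_sample(y, 1e-6, rng) for _ in range(50)}
    assert draws == {1}


def test_gumbel_matches_softmax_distribution(rng):
    y = np.array([0.0, np.log(2.0)])
    draws = np.array([gumbel_sample(y, 1.0, rng) for _ in range(100_000)])
    freq = draws.mean()
    assert freq == pytest.approx(2 / 3, abs=0.01)


def test_gumbel_shift_invariance():
    y = np.array([0.3, -1.2, 2.0])
    a = [gumbel_sample(y, 0.7, np.random.default_rng(5)) for _ in range(200)]
    b = [gumbel_sample(y + 10.0, 0.7, np.random.default_rng(5)) for _ in range(200)]
    assert a == b


def test_sampler_state_validation():
    with pytest.raises(ValueError):
        SamplerState(temperature=0.0)
    with pytest.raises(ValueError):
        SamplerState(temperature=1.0, noise_scale=-1.0)


# -- perturbation ------------------------------------------------------------

def test_zero_noise_is_identity(rng):
    e = rng.normal(0, 1, 64)
    np.testing.assert_array_equal(perturb_representation(e, 0.0, rng=rng), e)


def test_half_of_coordinates_change_on_average():
    e = np.zeros(2000)
    rng = np.random.default_rng(8)
    changed = np.mean([
        (perturb_representation(e, 1.0, rng=rng) != 0).mean() for _ in range(20)])
    assert changed == pytest.approx(0.5, abs=0.02)


def test_unmasked_coordinate_variance_is_noise_squared():
    e = np.zeros(4000)
    rng = np.random.default_rng(9)
    noise_scale = 0.7
    deltas = np.concatenate([
        perturb_representation(e, noise_scale, rng=rng) for _ in range(20)])
    nonzero = deltas[deltas != 0]
    assert nonzero.var() == pytest.approx(noise_scale ** 2, rel=0.05)


# -- decoding ----------------------------------------------------------------

def test_decode_determinism_and_length(tiny_decoder):
    from latentmol.chemio import Vocabulary, PAD_TOKEN, START_TOKEN, END_TOKEN

    tokens = {PAD_TOKEN: 0, START_TOKEN: 1, END_TOKEN: 2}
    for i, ch in enumerate("CNOc1()=", start=3):
        tokens[ch] = i
    vocab = Vocabulary(token_to_index=tokens)
    rep = np.random.default_rng(3).normal(0, 1, 16)
    s1, v1 = decode(tiny_decoder, vocab, rep, temperature=1.0, seed=4, max_len=20)
    s2, v2 = decode(tiny_decoder, vocab, rep, temperature=1.0, seed=4, max_len=20)
    assert (s1, v1) == (s2, v2)
    assert len(s1) <= 20


def test_assess_reconstruction_conventions():
    assert assess_reconstruction(canonicalize("CCO"), "CCO") == 1.0
    assert assess_reconstruction(canonicalize("CCO"), "((((") == 0.0
    assert assess_reconstruction(canonicalize("CCO"), "") == 0.0


def test_assess_reconstruction_matches_bitset_oracle():
    from rdkit import Chem
    from rdkit.Chem.AtomPairs import Pairs
    a = Chem.MolFromSmiles("CCO")
    b = Chem.MolFromSmiles("CCN")
    fa = Pairs.GetAtomPairFingerprint(a).GetNonzeroElements()
    fb = Pairs.GetAtomPairFingerprint(b).GetNonzeroElements()
    inter = sum(min(fa[k], fb[k]) for k in fa if k in fb)
    union = sum(fa.values()) + sum(fb.values()) - inter
    assert assess_reconstruction(canonicalize("CCO"), "CCN") == pytest.approx(inter / union)
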