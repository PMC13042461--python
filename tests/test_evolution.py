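"""Screening, early-recognition metrics, and representation-space procedures."""

import numpy as np
import pytest

from latentmol.evolution import (
    ObjectiveSpec, RepresentationStatistics, apply_screen_filter, auroc,
    bedroc, chemical_fusion, cosine_similarity_matrix, directed_migration,
    enrichment_factor, fusion_loss, ligand_efficiency,
    migration_loss_terms, migration_similarity_loss, screen,
)
from latentmol.nn import Tensor


# -- screening ---------------------------------------------------------------

def test_query_identical_to_reference_scores_one(rng):
    refs = rng.normal(0, 1, (4, 16))
    lib = np.vstack([refs[2], rng.normal(0, 1, (5, 16))])
    res = screen(lib, [refs])
    assert res.per_set_scores[0, 0] == pytest.approx(1.0)


def test_filter_resets_scores_below_half():
    np.testing.assert_array_equal(apply_screen_filter(np.array([0.49, 0.51])),
                                  [0.0, 0.51])
    np.testing.assert_array_equal(apply_screen_filter(np.array([0.5])), [0.5])


def test_ranking_matches_bruteforce_recomputation(rng):
    lib = rng.normal(0, 1, (20, 8))
    sets = [rng.normal(0, 1, (3, 8)), rng.normal(0, 1, (2, 8))]
    res = screen(lib, sets)
    totals = []
    for q in lib:
        total = 0.0
        for refs in sets:
            best = max(
                float(np.dot(q, r) / (np.linalg.norm(q) * np.linalg.norm(r)))
                for r in refs)
            total += best if best >= 0.5 else 0.0
        totals.append(total)
    np.testing.assert_allclose(res.total_scores, totals, atol=1e-12)
    np.testing.assert_array_equal(res.ranking, np.argsort(-np.asarray(totals),
                                                          kind="stable"))
    assert sorted(res.ranking.tolist()) == list(range(20))


def test_empty_reference_set_rejected(rng):
    with pytest.raises(ValueError):
        screen(rng.normal(0, 1, (3, 4)), [])


def test_top_fraction_flags_at_least_one(rng):
    res = screen(rng.normal(0, 1, (50, 4)), [rng.normal(0, 1, (2, 4))])
    assert res.top_flagged.sum() == 1


# -- early-recognition metrics ----------------------------------------------

def test_bedroc_perfect_and_inverted_ranking():
    labels = np.array([1] * 5 + [0] * 995)
    scores = -np.arange(1000, dtype=float)
    assert bedroc(scores, labels) > 0.99
    assert bedroc(-scores, labels) < 0.01


def test_bedroc_random_ranking_matches_permutation_null(rng):
    """Monte Carlo over label-independent scores against the analytic null
    alpha*Ra/(1-exp(-alpha)) ~ Ra for large alpha (Truchon & Bayly)."""
    n, n_act, alpha = 400, 40, 20.0
    labels = np.array([1] * n_act + [0] * (n - n_act))
    ra = n_act / n
    vals = []
    for _ in range(200):
        vals.append(bedroc(rng.random(n), labels, alpha=alpha))
    # analytic expectation of the null
    expected = ra * (1.0 / (1.0 - np.exp(-alpha * (1 - ra)))) \
        + 1.0 / (1.0 - np.exp(alpha * (1 - ra)))
    assert np.mean(vals) == pytest.approx(expected, abs=0.02)


def test_bedroc_degenerate_labels_rejected():
    with pytest.raises(ValueError):
        bedroc(np.arange(4.0), np.ones(4))


def test_auroc_and_enrichment_factor(rng):
    labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
    scores = np.arange(10, 0, -1, dtype=float)  # both actives first
    assert auroc(scores, labels) == 1.0
    assert enrichment_factor(scores, labels, fraction=0.2) == pytest.approx(5.0)


# -- representation statistics & propagation ---------------------------------

def test_sigma_from_reference_set(rng):
    reps = rng.normal(0, 2.0, (500, 32))
    stats = RepresentationStatistics.from_representations(reps, "lib")
    assert stats.sigma.shape == (32,)
    assert np.all(stats.sigma > 0)
    assert stats.reference_set_id == "lib"


def test_zero_sigma_walk_is_identity(tiny_decoder_bundle):
    decoder, vocab = tiny_decoder_bundle
    from latentmol.evolution import stochastic_propagation

    start = np.random.default_rng(0).normal(0, 1, 16)
    stats = RepresentationStatistics(sigma=np.zeros(16))
    traj = stochastic_propagation(start, stats, decoder, vocab, steps=5, seed=1)
    for step in traj.steps:
        np.testing.assert_array_equal(step.representation, start)
        assert step.similarities["to_start"] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def tiny_decoder_bundle():
    from latentmol.chemio import Vocabulary, PAD_TOKEN, START_TOKEN, END_TOKEN
    from latentmol.decoder import Decoder, DecoderConfig

    tokens = {PAD_TOKEN: 0, START_TOKEN: 1, END_TOKEN: 2}
    for i, ch in enumerate("CNO()=1c", start=3):
        tokens[ch] = i
    vocab = Vocabulary(token_to_index=tokens)
    decoder = Decoder(DecoderConfig.desk(vocab_size=len(tokens), model_dim=16,
                                         heads=2, layers=1, max_len=12),
                      rep_dim=16, seed=5).eval()
    return decoder, vocab


def test_propagation_trajectory_bookkeeping(tiny_decoder_bundle, rng):
    decoder, vocab = tiny_decoder_bundle
    from latentmol.evolution import stochastic_propagation

    stats = RepresentationStatistics(sigma=np.ones(16), reference_set_id="x")
    traj = stochastic_propagation(rng.normal(0, 1, 16), stats, decoder, vocab,
                                  steps=8, seed=3)
    assert len(traj.steps) == 8
    assert traj.header["sigma_reference_set"] == "x"
    for s in traj.steps:
        assert isinstance(s.valid, bool) or s.valid in (True, False)


# -- directed migration ------------------------------------------------------

def test_similarity_loss_minimized_at_anchor():
    assert migration_similarity_loss(0.8) == 0.0
    assert migration_similarity_loss(1.0) == pytest.approx(0.2)


def test_scaffold_hop_loss_zero_at_target(rng):
    target = rng.normal(0, 1, 16)
    obj = ObjectiveSpec(mode="scaffold_hop", target_rep=target)
    e = Tensor(target[None].copy(), requires_grad=True)
    loss, parts = migration_loss_terms(e, obj)
    assert loss.data == pytest.approx(0.0, abs=1e-12)


def test_objective_spec_validation(rng):
    with pytest.raises(ValueError):
        ObjectiveSpec(mode="migrate")
    with pytest.raises(ValueError):
        ObjectiveSpec(mode="scaffold_hop")


class _QuadHead:
    """Convex synthetic predictor: f(E) = sum((E - 0.5)^2)."""

    def forward(self, e):
        return ((e - Tensor(np.full((1, 16), 0.5))) ** 2.0).sum().reshape(1, 1)

    def eval(self):
        return self


def test_migration_reduces_convex_loss_tenfold(rng):
    start = rng.normal(0, 1, 16)
    obj = ObjectiveSpec(mode="migrate", property_targets={"q": 0.0},
                        predictors={"q": (_QuadHead(), None)},
                        start_rep=start.copy())
    traj = directed_migration(start, obj, lr=2e-2, steps=600, seed=1)
    first, last = traj.steps[0].losses["total"], traj.steps[-1].losses["total"]
    assert first / max(last, 1e-12) >= 10
    monotone = np.mean([
        traj.steps[i + 1].losses["total"] <= traj.steps[i].losses["total"] + 1e-9
        for i in range(len(traj.steps) - 1)])
    assert monotone >= 0.95


def test_migration_weight_is_count_times_point_two(rng):
    start = rng.normal(0, 1, 16)
    obj = ObjectiveSpec(mode="migrate",
                        property_targets={"a": 0.0, "b": 0.0, "c": 0.0},
                        predictors={k: (_QuadHead(), None) for k in "abc"},
                        start_rep=start.copy())
    e = Tensor(start[None].copy(), requires_grad=True)
    loss, parts = migration_loss_terms(e, obj)
    assert loss.data == pytest.approx(3 * 0.2 * parts["l_sim"] + parts["l_prop"])


# -- chemical fusion ---------------------------------------------------------

def test_fusion_term_values_at_landmarks(rng):
    d = 16
    ref = np.zeros(d)
    ref[0] = 1.0
    # similarity exactly 0.6 to the reference -> term 1/(1+10000^0) = 0.5
    v = np.zeros(d)
    v[0] = 0.6
    v[1] = np.sqrt(1 - 0.36)
    e = Tensor(v[None], requires_grad=True)
    loss, _ = fusion_loss(e, np.stack([ref, rng.normal(0, 1, d)* 0 + np.eye(d)[2]]))
    assert loss.data == pytest.approx(0.5, abs=1e-9)
    # sim -> 1: term -> 1/(1+10000^0.4) ~ 0.0245 ; sim -> -1: term -> ~1
    e1 = Tensor(ref[None].copy(), requires_grad=True)
    loss1, _ = fusion_loss(e1, np.stack([ref, np.eye(d)[2]]))
    assert loss1.data == pytest.approx(1.0 / (1.0 + 10_000 ** 0.4), abs=1e-9)
    e2 = Tensor(-ref[None], requires_grad=True)
    loss2, arg = fusion_loss(e2, np.stack([ref, ref]))
    assert loss2.data > 0.999


def test_fusion_requires_two_references(rng):
    with pytest.raises(ValueError):
        chemical_fusion(np.ones((1, 8)), np.zeros(8))


def test_fusion_loss_decreases_toward_orthogonal_references(rng):
    refs = np.stack([np.eye(16)[0] * 3, np.eye(16)[1] * 3])
    traj = chemical_fusion(refs, rng.normal(0, 0.1, 16), lr=3e-2, steps=200, seed=2)
    assert traj.steps[-1].losses["total"] < traj.steps[0].losses["total"]
    assert traj.steps[-1].similarities["max_reference_sim"] > 0.9


# -- ligand efficiency -------------------------------------------------------

@pytest.mark.parametrize("dg, n, expected", [
    (-3.7, 1, -3.7),
    (0.0, 10, 0.0),
    (-50.0, 25, -50.0 / (1.0 + np.log(25))),
])
def test_ligand_efficiency(dg, n, expected):
    assert ligand_efficiency(dg, n) == pytest.approx(expected)


def test_ligand_efficiency_domain():
    with pytest.raises(ValueError):
        ligand_efficiency(-5.0, 0)


def test_trajectory_dedup(tiny_decoder_bundle):
    from latentmol.evolution import Trajectory, TrajectoryStep

    traj = Trajectory(steps=[
        TrajectoryStep(0, np.zeros(2), "CCO", True),
        TrajectoryStep(1, np.zeros(2), "CCO", True),
        TrajectoryStep(2, np.zeros(2), "bad", False),
        TrajectoryStep(3, np.zeros(2), "CCN", True),
    ])
    assert traj.novel_valid_smiles() == ["CCO", "CCN"]
    assert traj.novel_valid_smiles(exclude={"CCO"}) == ["CCN"]


def test_migration_alternative_precedence_flag(rng):
    start = rng.normal(0, 1, 16)
    kw = dict(mode="migrate", property_targets={"q": 0.0},
              predictors={"q": (_QuadHead(), None)}, start_rep=start.copy())
    e = Tensor(start[None].copy(), requires_grad=True)
    base, parts = migration_loss_terms(e, ObjectiveSpec(**kw))
    e2 = Tensor(start[None].copy(), requires_grad=True)
    scaled, parts2 = migration_loss_terms(
        e2, ObjectiveSpec(**kw, scale_property_term=True))
    assert scaled.data == pytest.approx(
        1 * 0.2 * (parts2["l_sim"] + parts2["l_prop"]))
    assert base.data == pytest.approx(1 * 0.2 * parts["l_sim"] + parts["l_prop"])
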