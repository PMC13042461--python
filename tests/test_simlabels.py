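"""Similarity labels: fingerprints, energy windows, conformers, CSPS."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from latentmol.chemio import canonicalize
from latentmol.simlabels import (
    ENERGY_WINDOW_FACTORS, build_similarity_matrix, csps_vector,
    energy_windows, fingerprint_similarity_vector, generate_conformer_ensembles,
    overlay_similarity, similarity_record,
)

BENZENE = canonicalize("c1ccccc1")
PYRIDINE = canonicalize("c1ccncc1")


def test_self_similarity_fingerprints_are_one(library):
    for m in library[:5]:
        np.testing.assert_allclose(fingerprint_similarity_vector(m, m), 1.0)


def test_tanimoto_components_are_symmetric(library, rng):
    idx = rng.integers(0, len(library), size=(30, 2))
    for i, j in idx:
        ab = fingerprint_similarity_vector(library[i], library[j])
        ba = fingerprint_similarity_vector(library[j], library[i])
        np.testing.assert_allclose(ab[:2], ba[:2])   # ECFP4, MACCS Tanimoto


def test_ecfp4_tanimoto_matches_bitset_enumeration():
    """Brute-force |A∩B| / |A∪B| on the explicit on-bit sets."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    a = set(gen.GetFingerprint(BENZENE.to_rdkit()).GetOnBits())
    b = set(gen.GetFingerprint(PYRIDINE.to_rdkit()).GetOnBits())
    expected = len(a & b) / len(a | b)
    got = fingerprint_similarity_vector(BENZENE, PYRIDINE)[0]
    assert got == pytest.approx(expected)


def test_components_lie_in_unit_interval(library, rng):
    for _ in range(10):
        i, j = rng.integers(0, len(library), size=2)
        v = fingerprint_similarity_vector(library[i], library[j])
        assert np.all((v >= 0) & (v <= 1))


def test_energy_window_arithmetic():
    m = canonicalize("CCCCCCCCCCCC")  # n-dodecane: 9 rotatable bonds
    assert m.rotatable_bond_count == 9
    w = energy_windows(m)
    np.testing.assert_allclose(w, [9 * f for f in ENERGY_WINDOW_FACTORS])
    assert np.all(np.diff(w) > 0)


def test_energy_window_scaling_factor_product():
    # 10 rotatable bonds at the second factor -> 5.060 kcal/mol
    class Stub:
        rotatable_bond_count = 10
    assert energy_windows(Stub())[1] == pytest.approx(5.060)


def test_rigid_molecule_windows_hit_the_floor():
    w = energy_windows(BENZENE, floor=0.1)
    np.testing.assert_allclose(w, 0.1)


def test_benzene_has_single_conformer_everywhere():
    ensembles = generate_conformer_ensembles(BENZENE, seed=4)
    assert [len(e.conformers) for e in ensembles] == [1, 1, 1, 1]


def test_ensembles_are_nested_and_deduplicated(library):
    flexible = next(m for m in library if m.rotatable_bond_count >= 1)
    ensembles = generate_conformer_ensembles(flexible, seed=5)
    sizes = [len(e.conformers) for e in ensembles]
    assert sizes == sorted(sizes)
    for small, big in zip(ensembles, ensembles[1:]):
        for conf in small.conformers:
            assert any(np.allclose(conf, c) for c in big.conformers)


def test_rmsd_duplicates_are_removed():
    """Identical embeddings (same seed, duplicated budget) collapse to the
    same de-duplicated set as a single run."""
    once = generate_conformer_ensembles(BENZENE, seed=6, n_embed=10)
    twice = generate_conformer_ensembles(BENZENE, seed=6, n_embed=40)
    assert len(once[-1].conformers) == len(twice[-1].conformers) == 1


def test_butane_largest_window_has_anti_and_gauche():
    """Torsion-scan oracle: n-butane's C-C-C-C dihedral has minima near 180
    (anti) and ±60 (gauche); the largest window must contain >= 2 rotamers."""
    butane = canonicalize("CCCC")
    ensembles = generate_conformer_ensembles(butane, seed=7, n_embed=50)
    big = ensembles[-1]
    assert len(big.conformers) >= 2
    from rdkit.Chem import AllChem, rdMolTransforms
    dihedrals = []
    for coords in big.conformers:
        mol = butane.to_rdkit()
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, xyz in enumerate(coords):
            conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        mol.AddConformer(conf)
        dihedrals.append(abs(rdMolTransforms.GetDihedralDeg(mol.GetConformer(),
                                                            0, 1, 2, 3)))
    assert any(d > 120 for d in dihedrals)      # anti rotamer
    assert any(d < 120 for d in dihedrals)      # gauche rotamer


def test_csps_self_similarity_rigid():
    v = csps_vector(BENZENE, BENZENE, seed=8)
    assert np.all(v[:4] >= 0.99)
    assert v[4] <= 0.01


def test_csps_window_monotonicity(library, rng):
    pairs = rng.integers(0, len(library), size=(3, 2))
    for i, j in pairs:
        v = csps_vector(library[i], library[j], seed=9)
        assert np.all(np.diff(v[:4]) >= -1e-12)
        assert np.all((v >= 0) & (v <= 1))
        assert v[4] == pytest.approx(np.clip(v[3] - v[0], 0, 1))


def test_rigid_pair_window0_equals_single_pair_evaluation():
    """Benzene x pyridine both have one conformer: the window-0 component must
    equal direct scoring of that single aligned pair."""
    ens_a = generate_conformer_ensembles(BENZENE, seed=10)
    ens_b = generate_conformer_ensembles(PYRIDINE, seed=11)
    v = csps_vector(BENZENE, PYRIDINE, ensembles_a=ens_a, ensembles_b=ens_b)
    assert len(ens_a[0].conformers) == len(ens_b[0].conformers) == 1
    # all four windows see the same single pair
    assert v[0] == pytest.approx(v[3])
    assert 0 < v[0] <= 1


def test_similarity_record_has_eight_unit_components(library):
    rec = similarity_record(library[0], library[1], seed=12)
    arr = rec.as_array()
    assert arr.shape == (8,)
    assert np.all((arr >= 0) & (arr <= 1))


def test_matrix_shape_determinism_and_cell_recompute(library, tmp_path):
    queries, refs = library[:3], library[3:5]
    mat = build_similarity_matrix(queries, refs, seed=13)
    assert mat.values.shape == (3, 2, 8)
    assert np.all(np.isfinite(mat.values))
    mat2 = build_similarity_matrix(queries, refs, seed=13)
    np.testing.assert_array_equal(mat.values, mat2.values)
    # independent cell-by-cell recomputation
    rec = similarity_record(queries[1], refs[0], seed=13,
                            ensembles_a=None, ensembles_b=None)
    # fingerprint components are conformer-free and must agree exactly
    np.testing.assert_allclose(mat.values[1, 0, 5:], rec.as_array()[5:])
    mat.save(tmp_path / "m")
    loaded = type(mat).load(tmp_path / "m")
    np.testing.assert_array_equal(loaded.values, mat.values)
    assert loaded.provenance["config_hash"] == mat.provenance["config_hash"]


def test_overlay_similarity_bounds(rng):
    xa = rng.normal(0, 1, (5, 3))
    feats = {f: np.arange(2) for f in
             ("donor", "acceptor", "aromatic", "hydrophobe", "positive", "negative")}
    s_self = overlay_similarity(xa, xa, feats, feats)
    assert s_self == pytest.approx(1.0)
    xb = xa + 100.0
    assert overlay_similarity(xa, xb, feats, feats) < 0.05
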