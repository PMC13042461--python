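"""Deterministic synthetic molecule fixtures.

A small fragment grammar (ring-system templates with substitution slots plus
a substituent table) assembles valid, drug-like-but-small molecules entirely
in code, so every training and evaluation routine in the package can run
without any external download.  Molecules are kept small and fairly rigid
(<= 2 rotatable bonds by default) so that conformer-ensemble labels stay
cheap; the grammar still spans several chemotype families, which gives the
fingerprint-similarity distribution a wide spread and lets whole families be
held out as non-homologous validation/test splits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import DataStructs, Descriptors, rdFingerprintGenerator

from .chemio import Molecule, canonicalize
from .simlabels import SimilarityMatrix, build_similarity_matrix

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

# ring-system templates: "{a}" / "{b}" are substitution slots
SCAFFOLDS = [
    "{a}c1ccc({b})cc1",        # para-substituted benzene
    "{a}c1cccc({b})c1",        # meta-substituted benzene
    "{a}c1ccc({b})cn1",        # pyridine
    "{a}c1ccc({b})s1",         # thiophene
    "{a}c1ccc({b})o1",         # furan
    "{a}c1cnc({b})cn1",        # pyrazine
    "{a}c1nc({b})no1",         # oxadiazole
    "{a}C1CCC({b})CC1",        # cyclohexane
    "{a}C1CCN({b})CC1",        # piperidine
    "{a}c1ccc2ccc({b})cc2c1",  # naphthalene
    "{a}c1ccc2[nH]c({b})cc2c1",  # indole
    "{a}c1nc({b})cs1",         # thiazole
]

# scaffold indices grouped by chemotype relatedness; whole families are
# assigned to a single split so held-out molecules are non-homologous
SCAFFOLD_FAMILIES = [
    [0, 1, 9],    # benzenes + naphthalene
    [2, 5],       # azines
    [3, 11],      # S-heterocycles
    [4, 6],       # O-heterocycles
    [7, 8],       # saturated rings
    [10],         # indole
]

SUBSTITUENTS = [
    "", "C", "N", "O", "F", "Cl", "Br", "CC", "C(C)C", "OC", "CO", "CN",
    "NC", "C#N", "C(=O)O", "C(=O)N", "C(F)(F)F", "[N+](=O)[O-]", "S(C)(=O)=O",
    "C(=O)C", "OC(F)F",
]

PROPERTY_RULES = {
    # continuous size + polarity blend: atomic masses break rank ties, so the
    # label is a well-posed target for rank-correlation recovery tests
    "size_polarity": lambda mol: (
        0.05 * Descriptors.MolWt(mol)
        + 1.0 * sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))),
    # deterministic structure-derived labels for parameter-recovery tests
    "heteroatom_count": lambda mol: float(
        sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))),
    "heavy_atom_count": lambda mol: float(mol.GetNumHeavyAtoms()),
    "ring_atom_count": lambda mol: float(
        sum(1 for a in mol.GetAtoms() if a.IsInRing())),
    "polarity_size": lambda mol: (
        1.0 * sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
        + 0.3 * mol.GetNumHeavyAtoms()
        + 0.5 * sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())),
}


class GenerationError(RuntimeError):
    pass


@dataclass
class FixtureConfig:
    n_train: int = 120
    n_valid: int = 16
    n_test: int = 16
    n_references: int = 8
    seed: int = 0
    property_rule: str = "size_polarity"
    property_noise_sd: float = 0.0
    max_heavy_atoms: int = 24
    max_rotatable_bonds: int = 2
    homology_cutoff: float = 0.3   # cross-split ECFP4 Tanimoto bound
    conformer_budget: int = 50

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FixtureBundle:
    molecules: list[Molecule]
    splits: dict[str, list[int]]            # name -> indices into molecules
    reference_indices: list[int]
    similarity: SimilarityMatrix | None
    property_table: np.ndarray              # (n, 1) labels
    provenance_hash: str = ""

    def split_molecules(self, name: str) -> list[Molecule]:
        return [self.molecules[i] for i in self.splits[name]]


def sample_library(n: int, seed: int,
                   max_heavy_atoms: int = 24,
                   max_rotatable_bonds: int = 2,
                   scaffold_indices: list[int] | None = None,
                   exclude: set[str] | None = None) -> list[Molecule]:
    """Draw n unique valid molecules from the fragment grammar."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    scaffolds = [SCAFFOLDS[i] for i in scaffold_indices] if scaffold_indices \
        else SCAFFOLDS
    seen: set[str] = set(exclude or ())
    out: list[Molecule] = []
    attempts = stale = 0
    max_attempts = 400 * n
    while len(out) < n:
        attempts += 1
        stale += 1
        # a long run without a new unique structure means the grammar's
        # combinatorial space is (effectively) exhausted
        if attempts > max_attempts or stale > 5000:
            raise GenerationError(
                f"fragment grammar exhausted after {attempts} attempts "
                f"({len(out)}/{n} unique molecules)")
        template = scaffolds[rng.integers(len(scaffolds))]
        a = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        b = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        smiles = template.format(a=a, b=b)
        if Chem.MolFromSmiles(smiles) is None:
            continue
        m = canonicalize(smiles)
        if m.smiles in seen:
            continue
        if m.heavy_atom_count > max_heavy_atoms:
            continue
        if m.rotatable_bond_count > max_rotatable_bonds:
            continue
        seen.add(m.smiles)
        out.append(m)
        stale = 0
    return out


def synthetic_property(m: Molecule, rule: str = "size_polarity",
                       noise_sd: float = 0.0,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None) -> float:
    """Deterministic structure-derived label plus optional Gaussian noise."""
    if rule not in PROPERTY_RULES:
        raise ValueError(f"unknown property rule {rule!r}; "
                         f"registered: {sorted(PROPERTY_RULES)}")
    value = PROPERTY_RULES[rule](m.to_rdkit())
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        value += float(rng.normal(0.0, noise_sd))
    return value


def _max_similarity_to(molecule: Molecule, fps: list) -> float:
    fp = _MORGAN.GetFingerprint(molecule.to_rdkit())
    return max(DataStructs.BulkTanimotoSimilarity(fp, fps)) if fps else 0.0


def build_tiny_fixture(cfg: FixtureConfig,
                       with_similarity_matrix: bool = True) -> FixtureBundle:
    """Assemble the desk-scale fixture bundle.

    Whole scaffold families are assigned to a single split and held-out
    molecules are additionally rejection-filtered against the training set,
    so no validation/test molecule has an ECFP4 Tanimoto >= the homology
    cutoff against any training molecule.  References for the similarity
    matrix are drawn from the training split, mirroring the query x reference
    layout used in similarity pre-training.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    order = rng.permutation(len(SCAFFOLD_FAMILIES))
    test_scaffolds = SCAFFOLD_FAMILIES[order[0]]
    valid_scaffolds = SCAFFOLD_FAMILIES[order[1]]
    train_scaffolds = [s for fam in (SCAFFOLD_FAMILIES[i] for i in order[2:])
                       for s in fam]

    kw = dict(max_heavy_atoms=cfg.max_heavy_atoms,
              max_rotatable_bonds=cfg.max_rotatable_bonds)
    train = sample_library(cfg.n_train, cfg.seed,
                           scaffold_indices=train_scaffolds, **kw)
    train_fps = [_MORGAN.GetFingerprint(m.to_rdkit()) for m in train]

    def held_out(n: int, seed: int, scaffold_indices: list[int],
                 taken: set[str]) -> list[Molecule]:
        out: list[Molecule] = []
        for retry in range(40):
            pool = sample_library(n + 8 * (retry + 1), seed + retry,
                                  scaffold_indices=scaffold_indices,
                                  exclude=taken, **kw)
            out = [m for m in pool
                   if _max_similarity_to(m, train_fps) < cfg.homology_cutoff][:n]
            if len(out) == n:
                return out
        raise GenerationError("library too small for the requested disjoint splits")

    taken = {m.smiles for m in train}
    test = held_out(cfg.n_test, cfg.seed + 50, test_scaffolds, taken)
    taken |= {m.smiles for m in test}
    valid = held_out(cfg.n_valid, cfg.seed + 90, valid_scaffolds, taken)

    molecules = train + valid + test
    splits = {
        "train": list(range(cfg.n_train)),
        "valid": list(range(cfg.n_train, cfg.n_train + cfg.n_valid)),
        "test": list(range(cfg.n_train + cfg.n_valid, len(molecules))),
    }

    prop_rng = np.random.default_rng(cfg.seed + 2)
    labels = np.asarray([
        synthetic_property(m, cfg.property_rule, cfg.property_noise_sd, rng=prop_rng)
        for m in molecules
    ])[:, None]

    ref_rng = np.random.default_rng(cfg.seed + 3)
    reference_indices = sorted(
        ref_rng.choice(splits["train"], size=cfg.n_references, replace=False).tolist())

    similarity = None
    if with_similarity_matrix:
        similarity = build_similarity_matrix(
            queries=molecules,
            references=[molecules[i] for i in reference_indices],
            seed=cfg.seed + 4, n_embed=cfg.conformer_budget)

    return FixtureBundle(
        molecules=molecules, splits=splits,
        reference_indices=reference_indices,
        similarity=similarity, property_table=labels,
        provenance_hash=cfg.digest(),
    )
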