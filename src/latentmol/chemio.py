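"""Chemical I/O: SMILES canonicalization, tokenization, graph featurization.

All structure handling is delegated to RDKit; this module fixes the SMILES
dialect (canonical, isomeric, aromatic lowercase, implicit hydrogens), the
byte-pair tokenizer shared by the reconstruction decoder, and the fixed-width
atom/bond featurization consumed by the graph encoder.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

PAD_TOKEN = "<pad>"
START_TOKEN = "<s>"
END_TOKEN = "</s>"

ATOM_TYPES = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I"]  # + "other" bucket
HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
FORMAL_CHARGES = [-1, 0, 1]  # + "other" bucket
CHIRAL_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
]
BOND_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
]

ATOM_FEATURE_DIM = len(ATOM_TYPES) + 1 + len(HYBRIDIZATIONS) + 1 \
    + len(FORMAL_CHARGES) + 1 + len(CHIRAL_TAGS) + 1 + 2
BOND_FEATURE_DIM = 2 + len(BOND_STEREO) + 1


class SmilesParseError(ValueError):
    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class TokenizationError(ValueError):
    pass


@dataclass(frozen=True)
class Molecule:
    """A molecule pinned to its canonical isomeric SMILES."""

    smiles: str
    heavy_atom_count: int
    rotatable_bond_count: int

    def to_rdkit(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


def canonicalize(raw_smiles: str) -> Molecule:
    """Normalize a SMILES string to its canonical isomeric form.

    Deterministic and idempotent: the returned ``Molecule.smiles`` maps to
    itself under a second call.
    """
    if not raw_smiles or not raw_smiles.strip():
        raise SmilesParseError(raw_smiles)
    mol = Chem.MolFromSmiles(raw_smiles.strip())
    if mol is None:
        raise SmilesParseError(raw_smiles)
    smiles = Chem.MolToSmiles(mol, isomericSmiles=True)
    return Molecule(
        smiles=smiles,
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        rotatable_bond_count=int(Descriptors.NumRotatableBonds(mol)),
    )


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

@dataclass
class Vocabulary:
    """Byte-pair vocabulary over SMILES characters.

    Index 0 is the padding token; merges are ranked so segmentation is
    reproducible from the serialized form alone.
    """

    token_to_index: dict[str, int]
    merge_ranks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.token_to_index.get(PAD_TOKEN) != 0:
            raise ValueError("pad token must sit at index 0")
        self.index_to_token = {i: t for t, i in self.token_to_index.items()}
        if len(self.index_to_token) != len(self.token_to_index):
            raise ValueError("token -> index mapping must be bijective")

    def __len__(self):
        return len(self.token_to_index)

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def start_index(self) -> int:
        return self.token_to_index[START_TOKEN]

    @property
    def end_index(self) -> int:
        return self.token_to_index[END_TOKEN]

    def save(self, path: str | Path):
        payload = {"tokens": self.token_to_index, "merges": self.merge_ranks}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(token_to_index=payload["tokens"], merge_ranks=payload["merges"])


def build_vocabulary(corpus: list[Molecule], merge_budget: int = 16) -> Vocabulary:
    """Learn a character + byte-pair-merge vocabulary from a SMILES corpus.

    Base tokens are the single characters occurring in the corpus; up to
    ``merge_budget`` most-frequent adjacent pairs are merged iteratively.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    sequences = [list(m.smiles) for m in corpus]
    base = sorted({ch for seq in sequences for ch in seq})

    merges: list[str] = []
    for _ in range(max(0, merge_budget)):
        counts: dict[tuple[str, str], int] = {}
        for seq in sequences:
            for a, b in zip(seq, seq[1:]):
                counts[(a, b)] = counts.get((a, b), 0) + 1
        if not counts:
            break
        # deterministic: highest count, then lexicographic
        (a, b), n = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if n < 2:
            break
        merged = a + b
        merges.append(merged)
        for seq in sequences:
            i = 0
            while i < len(seq) - 1:
                if seq[i] == a and seq[i + 1] == b:
                    seq[i:i + 2] = [merged]
                else:
                    i += 1

    tokens = [PAD_TOKEN, START_TOKEN, END_TOKEN] + base + merges
    return Vocabulary(
        token_to_index={t: i for i, t in enumerate(tokens)},
        merge_ranks={t: r for r, t in enumerate(merges)},
    )


@dataclass(frozen=True)
class TokenSequence:
    indices: tuple[int, ...]

    def __len__(self):
        return len(self.indices)


def tokenize(m: Molecule | str, v: Vocabulary) -> TokenSequence:
    """Segment a SMILES greedily by longest vocabulary match."""
    smiles = m.smiles if isinstance(m, Molecule) else m
    max_len = max((len(t) for t in v.token_to_index
                   if t not in (PAD_TOKEN, START_TOKEN, END_TOKEN)), default=1)
    out = [v.start_index]
    i = 0
    while i < len(smiles):
        for L in range(min(max_len, len(smiles) - i), 0, -1):
            piece = smiles[i:i + L]
            if piece in v.token_to_index:
                out.append(v.token_to_index[piece])
                i += L
                break
        else:
            raise TokenizationError(
                f"character {smiles[i]!r} at position {i} is not in the vocabulary"
            )
    out.append(v.end_index)
    return TokenSequence(indices=tuple(out))


def detokenize(t: TokenSequence, v: Vocabulary) -> str:
    pieces = []
    for idx in t.indices:
        tok = v.index_to_token[idx]
        if tok in (PAD_TOKEN, START_TOKEN, END_TOKEN):
            continue
        pieces.append(tok)
    return "".join(pieces)


# ---------------------------------------------------------------------------
# Graph featurization
# ---------------------------------------------------------------------------

@dataclass
class MolecularGraph:
    """Featurized molecular graph with paired directed edges.

    ``edge_src[k] -> edge_dst[k]`` is one directed edge; each chemical bond
    contributes two, so ``len(edge_src) == 2 * bond count``.
    """

    atom_features: np.ndarray   # (n_atoms, ATOM_FEATURE_DIM)
    bond_features: np.ndarray   # (n_edges, BOND_FEATURE_DIM)
    edge_src: np.ndarray
    edge_dst: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_src.shape[0]


def _one_hot(value, choices: list) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def featurize(m: Molecule | str) -> MolecularGraph:
    """Build the fixed-width atom/bond feature graph for the encoder.

    Hydrogens stay implicit; node count equals the heavy-atom count.
    """
    mol = m.to_rdkit() if isinstance(m, Molecule) else canonicalize(m).to_rdkit()
    atom_feats = []
    for atom in mol.GetAtoms():
        row = _one_hot(atom.GetSymbol(), ATOM_TYPES)
        row += _one_hot(atom.GetHybridization(), HYBRIDIZATIONS)
        row += _one_hot(atom.GetFormalCharge(), FORMAL_CHARGES)
        row += _one_hot(atom.GetChiralTag(), CHIRAL_TAGS)
        row += [float(atom.IsInRing()), float(atom.GetIsAromatic())]
        atom_feats.append(row)

    bond_feats, src, dst = [], [], []
    for bond in mol.GetBonds():
        row = [float(bond.GetIsConjugated()), float(bond.IsInRing())]
        row += _one_hot(bond.GetStereo(), BOND_STEREO)
        u, vtx = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for a, b in ((u, vtx), (vtx, u)):
            bond_feats.append(row)
            src.append(a)
            dst.append(b)

    n = mol.GetNumAtoms()
    return MolecularGraph(
        atom_features=np.asarray(atom_feats, dtype=np.float64).reshape(n, ATOM_FEATURE_DIM),
        bond_features=np.asarray(bond_feats, dtype=np.float64).reshape(len(src), BOND_FEATURE_DIM),
        edge_src=np.asarray(src, dtype=np.intp),
        edge_dst=np.asarray(dst, dtype=np.intp),
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_smiles_file(path: str | Path,
                     max_length: int = 128) -> list[Molecule]:
    """Read a .smi file (one SMILES per line, optional tab-separated id).

    Molecules whose canonical SMILES exceeds ``max_length`` characters are
    rejected with a logged warning (they could not be decoded within the
    sequence budget anyway).
    """
    molecules = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = canonicalize(line.split("\t")[0].split()[0])
        if max_length is not None and len(m.smiles) > max_length:
            logging.getLogger(__name__).warning(
                "skipping %s: %d characters exceeds the %d limit",
                m.smiles[:40] + "...", len(m.smiles), max_length)
            continue
        molecules.append(m)
    return molecules


def write_smiles_file(path: str | Path, molecules: list[Molecule],
                      ids: list[str] | None = None):
    lines = []
    for i, m in enumerate(molecules):
        lines.append(f"{m.smiles}\t{ids[i]}" if ids else m.smiles)
    Path(path).write_text("\n".join(lines) + "\n")


def read_property_csv(path: str | Path, smiles_column: str = "smiles"):
    """Read a property table (smiles + numeric label columns)."""
    df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise ValueError(f"CSV is missing a {smiles_column!r} column")
    molecules = [canonicalize(s) for s in df[smiles_column]]
    labels = df.drop(columns=[smiles_column]).to_numpy(dtype=np.float64)
    return molecules, labels
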