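"""Inter-molecular similarity labels for representation pre-training.

Each molecule pair gets an 8-component label: five conformational-space
pharmacophore similarity (CSPS) descriptors — the best pharmacophore/shape
alignment score over all conformer pairs inside four strain-energy windows,
plus the max-window minus min-window difference — and three 2D fingerprint
similarities (ECFP4 Tanimoto, MACCS Tanimoto, AtomPairs Tversky).

The conformer engine is RDKit ETKDG embedding with MMFF94 minimization; the
overlay scorer is Open3DAlign (Crippen variant) followed by an analytic
Gaussian-overlap Tanimoto combining heavy-atom shape and SMARTS-typed
pharmacophore features.  Energy windows scale with the rotatable-bond count
(factors 0.14806, 0.5060, 0.88836, 1.4806 kcal/mol) and ensembles are nested:
every conformer admitted at a small window is also present at every larger
one, so the per-window similarity maxima are non-decreasing by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem, rdMolAlign
from rdkit.Chem import rdFingerprintGenerator, MACCSkeys
from rdkit.Chem.AtomPairs import Pairs

from .chemio import Molecule, canonicalize

ENERGY_WINDOW_FACTORS = (0.14806, 0.5060, 0.88836, 1.4806)  # kcal/mol per rotatable bond
WINDOW_FLOOR = 0.1            # kcal/mol; keeps rigid-molecule ensembles non-empty
RMSD_DEDUP_CUTOFF = 0.5       # Angstrom
DEFAULT_EMBED_BUDGET = 50     # conformer embeddings per molecule
TVERSKY_ALPHA = 0.9
TVERSKY_BETA = 0.1
GAUSSIAN_ALPHA = 0.3          # 1/A^2, width of the atom-centred overlap kernel

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

# SMARTS pharmacophore families (donor/acceptor definitions follow the usual
# minimal typing used in ligand-based screening)
PHARMACOPHORE_SMARTS = {
    "donor": "[$([N;!H0;v3,v4&+1]),$([O;H1;+0]),$([n;H1;+0])]",
    "acceptor": "[$([O;H0;v2;+0]),$([O;-]),$([o;+0]),$([N;v3;H0;+0;!$(N=O)]),$([n;H0;+0])]",
    "aromatic": "a",
    "hydrophobe": "[C;!$(C~[#7,#8,#15,#16]);!$(C#N)]",
    "positive": "[+,$([N;H2;+0;!$(N-C=O)])]",
    "negative": "[-,$([O;H1;$(O-C=O)])]",
}


class ConformerError(RuntimeError):
    """3D embedding failed for a molecule; the pair is skipped upstream."""


@dataclass
class ConformerEnsemble:
    molecule: Molecule
    window_kcal: float
    conformers: list[np.ndarray]          # heavy-atom coordinates, (n_atoms, 3)
    energies: list[float]                 # kcal/mol relative to the global minimum


@dataclass(frozen=True)
class SimilarityRecord:
    """8-component pair label: 5 CSPS descriptors + 3 fingerprint similarities."""

    csps: tuple[float, ...]
    fp: tuple[float, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.csps + self.fp, dtype=np.float64)


@dataclass
class SimilarityMatrix:
    queries: list[Molecule]
    references: list[Molecule]
    values: np.ndarray                    # (Q, R, 8)
    provenance: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "matrix.npy", self.values)
        sidecar = {
            "shape": list(self.values.shape),
            "queries": [m.smiles for m in self.queries],
            "references": [m.smiles for m in self.references],
            "provenance": self.provenance,
        }
        (out / "matrix.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, out_dir: str | Path) -> "SimilarityMatrix":
        out = Path(out_dir)
        sidecar = json.loads((out / "matrix.json").read_text())
        return cls(
            queries=[canonicalize(s) for s in sidecar["queries"]],
            references=[canonicalize(s) for s in sidecar["references"]],
            values=np.load(out / "matrix.npy"),
            provenance=sidecar.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# Fingerprint similarities
# ---------------------------------------------------------------------------

def fingerprint_similarity_vector(a: Molecule, b: Molecule,
                                  tversky_alpha: float = TVERSKY_ALPHA,
                                  tversky_beta: float = TVERSKY_BETA) -> np.ndarray:
    """(ECFP4 Tanimoto, MACCS Tanimoto, AtomPairs Tversky) for a (query, reference) pair.

    The Tversky component treats the reference ``b`` as the prototype side:
    bits unique to the query are weighted by ``tversky_alpha``, bits unique to
    the reference by ``tversky_beta``.
    """
    ma, mb = a.to_rdkit(), b.to_rdkit()
    ecfp = DataStructs.TanimotoSimilarity(_MORGAN.GetFingerprint(ma),
                                          _MORGAN.GetFingerprint(mb))
    maccs = DataStructs.TanimotoSimilarity(MACCSkeys.GenMACCSKeys(ma),
                                           MACCSkeys.GenMACCSKeys(mb))
    ap = DataStructs.TverskySimilarity(Pairs.GetAtomPairFingerprint(ma),
                                       Pairs.GetAtomPairFingerprint(mb),
                                       tversky_alpha, tversky_beta)
    return np.asarray([ecfp, maccs, ap], dtype=np.float64)


# ---------------------------------------------------------------------------
# Conformer ensembles
# ---------------------------------------------------------------------------

def energy_windows(m: Molecule, floor: float = WINDOW_FLOOR) -> np.ndarray:
    """Four strain-energy windows in kcal/mol, rotatable-bond scaled.

    ``window_k = max(n_rot * factor_k, floor)``; ascending (all equal to the
    floor only in the rigid zero-rotatable-bond case).
    """
    return np.asarray(
        [max(m.rotatable_bond_count * f, floor) for f in ENERGY_WINDOW_FACTORS]
    )


def _embed_and_minimize(m: Molecule, seed: int, n_embed: int):
    mol = Chem.AddHs(m.to_rdkit())
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    params.numThreads = 1
    cids = AllChem.EmbedMultipleConfs(mol, numConfs=n_embed, params=params)
    if len(cids) == 0:
        raise ConformerError(f"3D embedding failed for {m.smiles}")
    if AllChem.MMFFHasAllMoleculeParams(mol):
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=500)
    energies = np.asarray([e for _, e in results], dtype=np.float64)
    heavy = Chem.RemoveHs(mol)
    return heavy, energies


def generate_conformer_ensembles(m: Molecule, seed: int,
                                 n_embed: int = DEFAULT_EMBED_BUDGET,
                                 floor: float = WINDOW_FLOOR,
                                 rmsd_cutoff: float = RMSD_DEDUP_CUTOFF,
                                 ) -> list[ConformerEnsemble]:
    """Build the four nested energy-window conformer ensembles of a molecule.

    Conformers are embedded once, minimized, sorted by energy, de-duplicated
    at ``rmsd_cutoff`` (symmetry-aware heavy-atom RMSD, lowest energy kept),
    and filtered into each window relative to the global minimum.
    """
    heavy, energies = _embed_and_minimize(m, seed, n_embed)
    rel = energies - energies.min()
    order = np.argsort(rel, kind="stable")

    kept: list[int] = []
    for ci in order:
        duplicate = False
        for cj in kept:
            rms = rdMolAlign.GetBestRMS(heavy, heavy, prbId=int(ci), refId=int(cj),
                                        maxMatches=1000)
            if rms < rmsd_cutoff:
                duplicate = True
                break
        if not duplicate:
            kept.append(int(ci))

    coords = {ci: np.asarray(heavy.GetConformer(ci).GetPositions()) for ci in kept}
    windows = energy_windows(m, floor=floor)
    ensembles = []
    for w in windows:
        members = [ci for ci in kept if rel[ci] <= w + 1e-9]
        ensembles.append(ConformerEnsemble(
            molecule=m, window_kcal=float(w),
            conformers=[coords[ci] for ci in members],
            energies=[float(rel[ci]) for ci in members],
        ))
    return ensembles


def write_ensembles_sdf(path: str | Path, m: Molecule,
                        ensembles: list[ConformerEnsemble]):
    """Write the largest-window ensemble as an SDF with relative-energy tags."""
    biggest = ensembles[-1]
    mol = m.to_rdkit()
    writer = Chem.SDWriter(str(path))
    for coords, energy in zip(biggest.conformers, biggest.energies):
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, (x, y, z) in enumerate(coords):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        mol.RemoveAllConformers()
        mol.AddConformer(conf, assignId=True)
        mol.SetProp("rel_energy_kcal", f"{energy:.6f}")
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# Pharmacophore/shape overlay scoring
# ---------------------------------------------------------------------------

def _pharmacophore_atoms(mol: Chem.Mol) -> dict[str, np.ndarray]:
    out = {}
    for family, smarts in PHARMACOPHORE_SMARTS.items():
        patt = Chem.MolFromSmarts(smarts)
        idx = sorted({match[0] for match in mol.GetSubstructMatches(patt)})
        out[family] = np.asarray(idx, dtype=np.intp)
    return out


def _gaussian_overlap(xa: np.ndarray, xb: np.ndarray,
                      alpha: float = GAUSSIAN_ALPHA) -> float:
    if len(xa) == 0 or len(xb) == 0:
        return 0.0
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=-1)
    return float(np.exp(-alpha * d2).sum())


def overlay_similarity(coords_a: np.ndarray, coords_b: np.ndarray,
                       feats_a: dict[str, np.ndarray],
                       feats_b: dict[str, np.ndarray]) -> float:
    """Gaussian-overlap Tanimoto of two aligned conformers in [0, 1].

    Equal-weight blend of heavy-atom shape overlap and per-family
    pharmacophore overlap; each part is normalized as V_ab/(V_aa+V_bb-V_ab).
    """
    vab = _gaussian_overlap(coords_a, coords_b)
    vaa = _gaussian_overlap(coords_a, coords_a)
    vbb = _gaussian_overlap(coords_b, coords_b)
    shape = vab / max(vaa + vbb - vab, 1e-12)

    num = den = 0.0
    for family in PHARMACOPHORE_SMARTS:
        fa, fb = feats_a[family], feats_b[family]
        if len(fa) == 0 and len(fb) == 0:
            continue
        pab = _gaussian_overlap(coords_a[fa], coords_b[fb])
        paa = _gaussian_overlap(coords_a[fa], coords_a[fa])
        pbb = _gaussian_overlap(coords_b[fb], coords_b[fb])
        num += pab
        den += paa + pbb - pab
    pharm = num / den if den > 1e-12 else shape
    return float(np.clip(0.5 * shape + 0.5 * pharm, 0.0, 1.0))


def _mol_with_conformers(m: Molecule, conformers: list[np.ndarray]) -> Chem.Mol:
    mol = Chem.Mol(m.to_rdkit())
    mol.RemoveAllConformers()
    for coords in conformers:
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, (x, y, z) in enumerate(coords):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        mol.AddConformer(conf, assignId=True)
    return mol


def csps_vector(a: Molecule, b: Molecule, seed: int = 0,
                ensembles_a: list[ConformerEnsemble] | None = None,
                ensembles_b: list[ConformerEnsemble] | None = None) -> np.ndarray:
    """Five CSPS descriptors for a molecule pair.

    Components 0-3: the best overlay similarity over all conformer pairs whose
    members both fall inside energy window k.  Component 4: window-3 minus
    window-0 value, clamped to [0, 1].  Because ensembles are nested, the
    window components are non-decreasing in k.
    """
    if ensembles_a is None:
        ensembles_a = generate_conformer_ensembles(a, seed)
    if ensembles_b is None:
        ensembles_b = generate_conformer_ensembles(b, seed + 1)

    big_a, big_b = ensembles_a[-1], ensembles_b[-1]
    mol_a = _mol_with_conformers(a, big_a.conformers)
    mol_b = _mol_with_conformers(b, big_b.conformers)
    feats_a = _pharmacophore_atoms(mol_a)
    feats_b = _pharmacophore_atoms(mol_b)

    # score every conformer pair once at the largest window, then take window
    # maxima over the nested index sets
    scores = np.zeros((len(big_a.conformers), len(big_b.conformers)))
    for i in range(len(big_a.conformers)):
        for j in range(len(big_b.conformers)):
            try:
                o3a = rdMolAlign.GetCrippenO3A(mol_b, mol_a, prbCid=j, refCid=i,
                                               maxIters=30)
                o3a.Align()
            except (RuntimeError, ValueError):
                pass
            ca = np.asarray(mol_a.GetConformer(i).GetPositions())
            cb = np.asarray(mol_b.GetConformer(j).GetPositions())
            scores[i, j] = overlay_similarity(ca, cb, feats_a, feats_b)

    ea = np.asarray(big_a.energies)
    eb = np.asarray(big_b.energies)
    comps = []
    for k in range(4):
        wa = ensembles_a[k].window_kcal
        wb = ensembles_b[k].window_kcal
        mask = (ea[:, None] <= wa + 1e-9) & (eb[None, :] <= wb + 1e-9)
        comps.append(float(scores[mask].max()) if mask.any() else 0.0)
    diff = float(np.clip(comps[3] - comps[0], 0.0, 1.0))
    return np.asarray(comps + [diff], dtype=np.float64)


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

def similarity_record(a: Molecule, b: Molecule, seed: int = 0, **kw) -> SimilarityRecord:
    csps = csps_vector(a, b, seed=seed, **kw)
    fp = fingerprint_similarity_vector(a, b)
    return SimilarityRecord(csps=tuple(csps), fp=tuple(fp))


def build_similarity_matrix(queries: list[Molecule], references: list[Molecule],
                            seed: int = 0,
                            n_embed: int = DEFAULT_EMBED_BUDGET) -> SimilarityMatrix:
    """Assemble the complete Q x R x 8 label grid for pre-training.

    Conformer ensembles are generated once per distinct molecule and shared
    across all pairs; a pair whose conformer generation fails invalidates the
    matrix (no silent missing cells).
    """
    cache: dict[str, list[ConformerEnsemble]] = {}

    def ensembles(m: Molecule, offset: int) -> list[ConformerEnsemble]:
        if m.smiles not in cache:
            cache[m.smiles] = generate_conformer_ensembles(
                m, seed=seed + offset, n_embed=n_embed)
        return cache[m.smiles]

    values = np.zeros((len(queries), len(references), 8), dtype=np.float64)
    for qi, q in enumerate(queries):
        ens_q = ensembles(q, offset=qi)
        for ri, r in enumerate(references):
            ens_r = ensembles(r, offset=10_000 + ri)
            csps = csps_vector(q, r, ensembles_a=ens_q, ensembles_b=ens_r)
            fp = fingerprint_similarity_vector(q, r)
            values[qi, ri, :5] = csps
            values[qi, ri, 5:] = fp

    config = {"seed": int(seed), "n_embed": int(n_embed),
              "factors": ENERGY_WINDOW_FACTORS, "floor": WINDOW_FLOOR,
              "rmsd_cutoff": RMSD_DEDUP_CUTOFF}
    digest = hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
    return SimilarityMatrix(queries=queries, references=references, values=values,
                            provenance={**config, "config_hash": digest})
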