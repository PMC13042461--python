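# latentmol

Molecular representation learning, SMILES reconstruction, and
representation-space molecular generation — a desk-scale, pure
NumPy + RDKit implementation for method developers and computational
chemists who want every moving part of this model family inspectable and
testable on one CPU.

## What it implements

The package couples four components around a single 1D molecular
representation E (default length 2048; desk profile 128):

1. **Representation module** — a Weisfeiler–Lehman message-passing network
   over the molecular graph G = (V, E) with a gated readout
   `h_v = W_self h_v ⊙ Σ_u (W_bond e_uv ⊙ W_atom h_u)` and global attention
   pooling `H = Σ_i h_i · softmax(a_i)`, pre-trained by *similarity
   projection*: two heads predict, for a molecule pair, three fingerprint
   similarities (ECFP4/MACCS Tanimoto, AtomPairs Tversky) and five
   conformational-space pharmacophore similarity (CSPS) descriptors — the
   best pharmacophore/shape overlay score over conformer pairs inside four
   strain-energy windows (`max(n_rot · f_k, 0.1)` kcal/mol,
   f = 0.14806/0.5060/0.88836/1.4806) plus a max−min flexibility term.
2. **Reconstruction module** — a transformer decoder that autoregressively
   rebuilds the SMILES from E used as a one-position cross-attention
   memory, trained with frequency-weighted cross-entropy
   `w_i = min(N_total/f_i, 100)` and sampled by Gumbel-max at temperature T.
3. **Property predictors** — residual MLP heads mapping E to numeric
   properties, in frozen-representation (projection) or cloned-encoder
   fine-tuning mode.
4. **Representation-space procedures** — cosine-similarity screening with a
   0.5 post-filter and BEDROC/AUROC/EF metrics; stochastic propagation
   `v ← E + 0.05·n⊙σ⊙m`; directed migration
   `L = |J|·0.2·|sim_start − 0.8| + Σ_j |c_j − f_j(E)|`; chemical fusion
   `L = min_r 1/(1 + 10000^(sim(E_r,E) − 0.6))`; and ligand efficiency
   `LE = ΔG/(1 + ln N_heavy)`.

All neural components run on a small reverse-mode autodiff engine included
in the package (`latentmol.nn`); all cheminformatics goes through RDKit.
A fragment-grammar fixture generator (`latentmol.synthdata`) produces
disjoint-scaffold molecule libraries, similarity matrices and synthetic
property labels, so the entire pipeline trains and evaluates with no
external data.  See `docs/methods.md` for the full model account.

## Worked example

```python
import numpy as np
from latentmol import (canonicalize, fingerprint_similarity_vector,
                       energy_windows, ligand_efficiency, screen)
from latentmol.synthdata import sample_library
from latentmol.encoder import Encoder, EncoderConfig

celecoxib = canonicalize("Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1")
aspirin = canonicalize("CC(=O)Oc1ccccc1C(=O)O")
print("aspirin:", aspirin.smiles, "| heavy atoms:", aspirin.heavy_atom_count,
      "| rotatable bonds:", aspirin.rotatable_bond_count)
print("fingerprint similarity (ECFP4, MACCS, AtomPairs-Tversky):",
      np.round(fingerprint_similarity_vector(aspirin, celecoxib), 3))
print("strain-energy windows (kcal/mol):", np.round(energy_windows(celecoxib), 3))
print("ligand efficiency (dG=-50, 25 heavy atoms):",
      round(ligand_efficiency(-50.0, 25), 3))

library = sample_library(40, seed=3)
encoder = Encoder(EncoderConfig.desk(seed=0)).eval()
reps = np.stack([encoder.encode(m) for m in library])
result = screen(reps, [reps[:3]])
print("top-ranked molecule:", library[result.ranking[0]].smiles,
      "| score:", round(result.total_scores[result.ranking[0]], 3))
```

prints

```
aspirin: CC(=O)Oc1ccccc1C(=O)O | heavy atoms: 13 | rotatable bonds: 2
fingerprint similarity (ECFP4, MACCS, AtomPairs-Tversky): [0.085 0.134 0.37 ]
strain-energy windows (kcal/mol): [0.444 1.518 2.665 4.442]
ligand efficiency (dG=-50, 25 heavy atoms): -11.851
top-ranked molecule: Cc1ccc2ccc(O)cc2c1 | score: 1.0
```

Aspirin and celecoxib share little 2D substructure (ECFP4 Tanimoto 0.085),
though the asymmetric AtomPairs Tversky — which asks how much of the
reference is embedded in the query — is higher.  Celecoxib's three
rotatable bonds set its four conformer-ensemble energy windows at 0.44 to
4.44 kcal/mol.  In the screening call, the first three library molecules
serve as their own reference set, so the top-ranked hit is one of them with
a perfect cosine score of 1.0.

A trained desk pipeline (fixture generation → similarity pre-training →
reconstruction training → property heads → generation procedures) is
exercised end-to-end by `tests/test_acceptance.py`; the CLI (`latentmol
fixtures|simlabels|train-encoder|train-decoder|encode|decode|screen`)
wraps the same functions for shell use.

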