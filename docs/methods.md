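# Methods

`latentmol` couples four trainable components around a single 1D molecular
representation space, plus the procedures that operate inside that space.
This note records the model, the defaults and why they are set where they
are, what the synthetic data emulates, and the numerical choices that are
not visible from the code's surface.

## Representation module

A molecule is parsed and canonicalized with RDKit (isomeric SMILES,
aromatic lowercase, implicit hydrogens) and featurized as a graph
G = (V, E).  Atom features: atom-type one-hot over {C, N, O, S, P, F, Cl,
Br, I, other}, hybridization, formal charge, chiral tag, in-ring and
aromatic flags (26 columns).  Bond features: conjugation and ring flags plus
the stereo type (9 columns); each bond is stored as two directed edges.

The encoder is a Weisfeiler–Lehman-style message-passing network:

    h_v(0)  = ReLU(W_in h_v + b_in)
    m_uv    = ReLU(W_contact [h_u || e_uv] + b_contact)
    e_uv   <- m_uv
    h_v    <- ReLU(W_agg [h_v || Σ_{u∈N(v)} e_uv] + b_agg)

run for 4 rounds with weights shared across rounds, followed by a bias-free
gated readout

    h_v^fin = W_self h_v ⊙ Σ_{u∈N(v)} (W_bond e_uv ⊙ W_atom h_u)

and global attention pooling: a per-atom MLP (sigmoid after every linear
layer, including the scalar logit; batch normalization after the first two)
produces logits that a softmax over the molecule's atoms turns into pooling
weights; the representation is the weight-averaged sum of the final atom
vectors.  Raw bond features are first projected to the hidden width
(`W_bond_in`, ReLU) so the first message-passing round is shape-consistent;
this input projection is the one place the implementation adds a layer the
update equations leave implicit.  An isolated atom receives a zero neighbour
sum, which makes its gated readout exactly zero.

Applying sigmoid to the final attention logit *before* the softmax
compresses logits into (0, 1); it is implemented that way deliberately
(weights remain a valid probability vector; the compression only limits how
peaked the attention can be).

Two projection heads map a concatenated representation pair [E_q || E_r] to
similarity predictions: a rectifier expansion to 5x the pair width
(LeakyReLU + batch norm), concatenation with the original pair, then staged
reductions (24576 → 2048 → 512 → 512 → 512 at full scale) with SiLU between
linears and batch norm after the first two, ending in sigmoid outputs — 3
for the fingerprint head, 5 for the CSPS head.

**Profiles.**  The default configuration carries the published widths
(rep_dim 2048, attention MLP 6144/1024/128x3/1, head reductions
24576/2048/512x3).  The desk profile divides every width by 16
(rep_dim 128) so that all training loops run in minutes on one CPU; tests
that assert architecture widths always interrogate the full-scale default
config.  Initialization is Kaiming-uniform (fan-in) ahead of ReLU-family
activations and Xavier-uniform ahead of sigmoid layers, all seed-controlled.

## Similarity labels

Each molecule pair carries an 8-component label.

*Fingerprint components* (RDKit): ECFP4 Tanimoto, MACCS Tanimoto, AtomPairs
Tversky.  The Tversky asymmetry treats the reference molecule as the
prototype: alpha = 0.9 on query-unique bits, beta = 0.1 on reference-unique
bits (config-exposed; the asymmetry direction is a design choice).

*CSPS components*: conformational-space pharmacophore similarity at four
strain-energy windows plus a flexibility term.  Windows are
`max(n_rot x f_k, 0.1)` kcal/mol with f = (0.14806, 0.5060, 0.88836,
1.4806); the 0.1 kcal/mol floor keeps rigid-molecule ensembles non-empty.
Conformers come from ETKDGv3 embedding (default 50 embeddings) with MMFF94
minimization (UFF fallback), energy-sorted, de-duplicated at a 0.5 Å
symmetry-aware heavy-atom RMSD, and filtered into each window relative to
the global minimum — so ensembles are nested and the per-window similarity
maxima are non-decreasing by construction.  Every conformer pair at the
largest window is aligned with Open3DAlign (Crippen variant) and scored by
an analytic Gaussian-overlap Tanimoto: atom-centred kernels
exp(−0.3 d²) for shape, the same kernel on SMARTS-typed pharmacophore
features (donor, acceptor, aromatic, hydrophobe, positive, negative) for
chemistry, blended 50/50 and clamped to [0, 1].  Window component k is the
maximum score over pairs inside window k; component 5 is the max-window
minus min-window difference, clamped to [0, 1].  The window structure
(4 windows, max-over-pairs, difference augmentation) is the modelled
quantity; the conformer engine and overlay scorer are this package's open
substitutions for proprietary conformational-search and pharmacophore-shape
tooling.  50 embeddings per molecule is a deliberate desk-scale budget
relative to exhaustive Monte Carlo searches.

## Reconstruction module

A byte-pair tokenizer is learned from the training corpus: single characters
as base tokens plus up to `merge_budget` (default 16) most-frequent adjacent
merges, which lands a drug-like corpus near a ~43-token vocabulary.  Padding
is index 0; sequences are wrapped in start/end tokens; stereo tokens
("@", "/", "\\") are retained.  Sequences longer than `max_len`
(default 128) are rejected at load.

The decoder is a transformer (full scale: 4 layers, 32 heads, model width =
rep_dim = 2048; desk: width 128, 4 heads, and the memorization tests use a
2-layer desk stack) with causal self-attention, cross-attention onto a
single-position memory — the representation vector linearly projected to
model width — SiLU feed-forward blocks and post-residual layer norm.
Rotary positional encoding is applied to the embedded target tokens only
(not the memory).  The vocabulary head is a 3-layer MLP
(2048 → 4096 → 1024 → vocab at full scale).

Training is teacher-forced with frequency-weighted cross-entropy: token
weight w_i = min(N_total / f_i, 100) from batch frequencies, absent tokens
reset to weight 1, pad targets excluded, and the start token never appears
as a target; the weighted token losses are summed and divided by the number
of valid targets.  Because representation magnitudes differ by orders of
magnitude between encoders (the gated readout multiplies activations), the
decoder stores a calibrated memory scale — max |rep| over the training
representations, kept in the checkpoint — and divides incoming
representations by it.

Sampling is Gumbel-max: s = log softmax(y/T) + g with
g = −log(−log u + 1e-10), token = argmax s, which draws exactly from
softmax(y/T).  Decoding stops at the end token or max_len; validity means
RDKit sanitization (valence + aromaticity) succeeds.  Reconstruction quality
between two structures is the AtomPairs fingerprint Tanimoto, 0 by
convention for unparseable output.

## Property predictor

Dropout(0.5) on the input representation, linear expansion to 4x width with
sigmoid, concatenation with the input (10240 at full scale), two
full-width linears with LeakyReLU + batch norm, an element-wise residual
add, then linear + batch-norm + SiLU stages down to rep_dim/2 and a final
SiLU-terminated linear to the property dimension.  The same calibrated
input-scale buffer as the decoder is applied.  Because the output unit is
SiLU-terminated, the trainer maps labels affinely into (0.1, 0.9) and
inverts the map at prediction time, keeping the head inside its monotone
range.  Fine-tuning always deep-copies the encoder, so property training can
never invalidate the decoder that shares the original encoder's
representation space.

## Training protocol

All loops use AdamW (weight decay 0.01) with one schedule: linear warmup
from 10% of the base rate over `warmup_steps`, then a cosine oscillation
between the base rate and 50% of it with the configured period (similarity
10000, reconstruction 4000, property 2000/1000 by dataset size at full
scale).  The two phases join continuously.  Early stopping evaluates every
`eval_every` steps (default 200) and stops after `patience` (default 60)
evaluations without strict improvement — ties do not count — restoring the
best-validation parameters.  Batch size for property/reconstruction training
follows the dataset-size rule: 96 above 5000 samples, 64 above 1000, 48
otherwise.

Similarity pre-training samples a query x reference block per step (full scale
512 x 48; desk 16 x 8) and minimizes MSE over the 8 label components.
The `freeze_steps` window (full-scale default 2000) exists to protect
warm-started graph-network weights; the desk profile trains from random
initialization, so its default is 0.  Desk profiles raise the base rate to
1e-3 (2e-3 for the 50-molecule memorization run) with proportionally
shortened warmup/periods — at a few hundred steps, the full-scale 5e-5
cannot move a randomly initialized network measurably.

Splits are guarded: the maximum ECFP4 Tanimoto between any held-out molecule
and any training molecule must stay below 0.3, and violations are reported
pair by pair.

## Representation-space procedures

Similarity between representations is cosine throughout.  Screening takes,
per reference set, the maximum similarity over its references, resets scores
below 0.5 to zero, ranks by the sum over sets and flags the top 0.1%.
Early recognition is measured by BEDROC (Truchon–Bayly, default
alpha = 160.9, weighting approximately the top 1%), AUROC and enrichment
factors.

*Stochastic propagation* walks v ← E + 0.05 · n ⊙ σ ⊙ m (n standard normal,
m a Bernoulli(0.5) mask) where σ is the per-dimension standard deviation
over a reference representation set — by default the encoder's training
library; the set's identity is recorded in the trajectory header.  Each of
the 200 steps decodes at T = 0.30.

*Directed migration* runs AdamW on the representation only (600 steps,
lr 2e-5 at full scale, decode at T = 0.4) under
L = |J| · 0.2 · |sim_start − 0.8| + Σ_j |c_j − f_j(E)|; the |J| factor is
config-overridable, and the alternative reading in which 0.2 also scales the
property term is available behind a flag.  Scaffold-hop mode minimizes
1 − sim_target.  *Chemical fusion* (1000 steps, lr 3e-5) minimizes
min_r 1/(1 + 10000^(sim(E_r, E) − 0.6)); the power is evaluated in log space
for gradient stability and gradients flow through the hard argmin branch
(no soft-min).  Synthetic-objective tests use desk learning rates (2e-2 /
3e-2) because at unit coordinate scale the full-scale rates cannot traverse
the space within the stated step counts.  Ligand efficiency is
LE = ΔG / (1 + ln N_heavy).

## Synthetic data

The fixture generator assembles molecules from a fragment grammar — 12
ring-system templates in 6 chemotype families with 21 substituents —
keeping them small (≤ 24 heavy atoms) and fairly rigid (≤ 2 rotatable
bonds) so conformer ensembles stay cheap.  Whole scaffold families are
assigned to a single split and held-out molecules are rejection-filtered
against the training set at the 0.3 homology cutoff, so the split guard
passes by construction.  The default desk fixture is 120 train / 16
validation / 16 test with 8 training-set references for the similarity
matrix.

Synthetic property labels come from registered deterministic rules plus
optional Gaussian noise.  The default, `size_polarity` = 0.05 · MolWt +
heteroatom count, is continuous (atomic masses break ties), which keeps
rank-correlation recovery well-posed at 16 held-out molecules; purely
integer-valued rules remain registered but produce heavily tied labels.

What the fixtures do **not** emulate: real chemical diversity at library
scale, protonation/tautomer state enumeration, flexible macrocycles, and
label noise structure of experimental assays.  A passing desk suite
demonstrates that the architecture, losses, schedules and optimization
procedures behave as specified and that the pipelines generalize across
held-out chemotype families of the grammar — not that full-scale accuracy
transfers to real screening libraries.

## Numerical choices

- All tensors are float64; the autodiff engine is a small tape-based
  reverse-mode implementation with exactly the operations the models need.
- Softmax/log-softmax are max-shifted; the logistic clips its argument at
  ±700; the Gumbel epsilon is 1e-10.
- Batch normalization keeps running statistics (momentum 0.1) and uses them
  exclusively in evaluation mode, so inference is batch-independent.
- Conformer de-duplication keeps the lowest-energy member of each RMSD
  cluster; window membership uses a 1e-9 kcal/mol tolerance.
- Screening ranks ties stably (NumPy stable argsort), so equal totals keep
  library order.
- Seeds: every stochastic component (sampling, initialization, dropout,
  conformer embedding) takes an explicit seed or Generator; derived seeds
  stay below 2^31.

## Known limitations

- The CSPS surrogate's absolute values are not comparable to proprietary
  pharmacophore-shape scores; only the relative structure (window nesting,
  self-similarity, [0, 1] range) is contractual.
- Desk-scale models underfit chemistry that the 16x-wider full-scale
  architecture is designed for; reported desk metrics are scale-down
  surrogates, not reproductions of full-scale accuracy.
- The decoder recomputes the full prefix each generation step (no KV cache);
  at max_len 128 and desk widths this is deliberate simplicity, not a
  throughput path.
- Fine-tuning mode trains a cloned encoder jointly with the head but shares
  no gradient plumbing with similarity pre-training; resuming a similarity
  run from a fine-tuned clone is unsupported by design.
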