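"""Representation-space applications.

Everything here operates on encoded 1D representation vectors: cosine
similarity screening with early-recognition metrics, stochastic propagation
(seeded random walks that decode novel structures), directed migration
(gradient descent on a representation under property/similarity losses),
chemical fusion (descent toward the nearest of several reference
embeddings), and ligand efficiency.

Similarity between representation vectors is cosine throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .chemio import Vocabulary
from .decoder import Decoder, decode
from .nn import AdamW, Tensor
from .predictor import PropertyPredictor

MIGRATION_SIM_TARGET = 0.8        # anchor similarity kept during migration
SCREEN_FILTER_CUTOFF = 0.5        # per-reference-set scores below this reset to 0
FUSION_SIM_MIDPOINT = 0.6         # fusion loss half-maximum similarity
FUSION_BASE = 10_000.0
DEFAULT_BEDROC_ALPHA = 160.9      # early-recognition weight, ~EF at 1%


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def cosine_similarity_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    return (a / np.maximum(na, 1e-12)) @ (b / np.maximum(nb, 1e-12)).T


@dataclass
class ScreeningResult:
    per_set_scores: np.ndarray      # (n_library, n_sets) max-over-references
    filtered_scores: np.ndarray     # after the < cutoff -> 0 reset
    total_scores: np.ndarray        # sum over reference sets
    ranking: np.ndarray             # library indices, best first
    top_flagged: np.ndarray         # boolean, top `top_fraction` by total score


def screen(library_reps: np.ndarray,
           reference_sets: list[np.ndarray],
           cutoff: float = SCREEN_FILTER_CUTOFF,
           top_fraction: float = 0.001) -> ScreeningResult:
    """Cosine-similarity screening against one or more reference sets.

    Per set, a query's score is its maximum similarity over that set's
    references; scores below ``cutoff`` are reset to 0; the library is ranked
    by the sum of filtered per-set scores and the top ``top_fraction`` is
    flagged.
    """
    if not reference_sets or any(len(np.atleast_2d(r)) == 0 for r in reference_sets):
        raise ValueError("every reference set must contain at least one molecule")
    library_reps = np.atleast_2d(library_reps)
    per_set = np.stack([
        cosine_similarity_matrix(library_reps, refs).max(axis=1)
        for refs in reference_sets
    ], axis=1)
    filtered = np.where(per_set < cutoff, 0.0, per_set)
    total = filtered.sum(axis=1)
    ranking = np.argsort(-total, kind="stable")
    n_top = max(1, int(np.ceil(top_fraction * len(total))))
    flagged = np.zeros(len(total), dtype=bool)
    flagged[ranking[:n_top]] = True
    return ScreeningResult(per_set_scores=per_set, filtered_scores=filtered,
                           total_scores=total, ranking=ranking, top_flagged=flagged)


def apply_screen_filter(scores: np.ndarray,
                        cutoff: float = SCREEN_FILTER_CUTOFF) -> np.ndarray:
    """The post-filter alone: similarities below ``cutoff`` reset to 0."""
    scores = np.asarray(scores, dtype=np.float64)
    return np.where(scores < cutoff, 0.0, scores)


# ---------------------------------------------------------------------------
# Early-recognition metrics
# ---------------------------------------------------------------------------

def bedroc(scores: np.ndarray, labels: np.ndarray,
           alpha: float = DEFAULT_BEDROC_ALPHA) -> float:
    """Boltzmann-enhanced discrimination of ROC (Truchon & Bayly).

    ``labels`` are 1 for actives; higher ``scores`` rank earlier.  Returns a
    value in [0, 1]; 1 means all actives lead the ranking.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n = len(labels)
    n_act = int(labels.sum())
    if n_act == 0 or n_act == n:
        raise ValueError("need at least one active and one inactive")
    order = np.argsort(-scores, kind="stable")
    ranks = np.nonzero(labels[order])[0] + 1          # 1-based ranks of actives
    ra = n_act / n
    s = np.exp(-alpha * ranks / n).sum()
    rie_denom = ra * (1.0 - np.exp(-alpha)) / (np.exp(alpha / n) - 1.0)
    rie = s / rie_denom
    factor = ra * np.sinh(alpha / 2.0) / (
        np.cosh(alpha / 2.0) - np.cosh(alpha / 2.0 - alpha * ra))
    constant = 1.0 / (1.0 - np.exp(alpha * (1.0 - ra)))
    return float(rie * factor + constant)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("need at least one active and one inactive")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def enrichment_factor(scores: np.ndarray, labels: np.ndarray,
                      fraction: float = 0.01) -> float:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n = len(labels)
    if labels.sum() in (0, n):
        raise ValueError("need at least one active and one inactive")
    n_top = max(1, int(np.ceil(fraction * n)))
    order = np.argsort(-scores, kind="stable")
    hits = labels[order[:n_top]].sum()
    return float((hits / n_top) / (labels.sum() / n))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class RepresentationStatistics:
    """Per-dimension standard deviation over a reference representation set."""

    sigma: np.ndarray
    reference_set_id: str = ""

    @classmethod
    def from_representations(cls, reps: np.ndarray,
                             reference_set_id: str = "") -> "RepresentationStatistics":
        return cls(sigma=np.asarray(reps, dtype=np.float64).std(axis=0),
                   reference_set_id=reference_set_id)


@dataclass
class TrajectoryStep:
    step: int
    representation: np.ndarray
    smiles: str
    valid: bool
    losses: dict = field(default_factory=dict)
    similarities: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    steps: list[TrajectoryStep] = field(default_factory=list)
    header: dict = field(default_factory=dict)

    def novel_valid_smiles(self, exclude: set[str] | None = None) -> list[str]:
        """Deduplicated valid decodes, first-seen order, minus `exclude`."""
        exclude = exclude or set()
        seen = set(exclude)
        out = []
        for s in self.steps:
            if s.valid and s.smiles not in seen:
                seen.add(s.smiles)
                out.append(s.smiles)
        return out

    def write_jsonl(self, path: str | Path):
        with open(path, "w") as fh:
            fh.write(json.dumps({"header": self.header}) + "\n")
            for s in self.steps:
                fh.write(json.dumps({
                    "step": s.step, "smiles": s.smiles, "valid": s.valid,
                    "losses": s.losses, "similarities": s.similarities,
                }) + "\n")


def _cos(a: np.ndarray, b: np.ndarray) -> float:
    return float(cosine_similarity_matrix(a, b)[0, 0])


def _cos_tensor(e: Tensor, anchor: np.ndarray) -> Tensor:
    """Differentiable cosine similarity between (1, d) tensor and a vector."""
    a = Tensor(np.atleast_2d(anchor))
    num = (e * a).sum()
    den = ((e * e).sum() ** 0.5) * float(np.linalg.norm(anchor))
    return num * den ** -1.0


# ---------------------------------------------------------------------------
# Generation procedures
# ---------------------------------------------------------------------------

def stochastic_propagation(start_rep: np.ndarray,
                           stats: RepresentationStatistics,
                           decoder: Decoder, vocabulary: Vocabulary,
                           steps: int = 200, scale: float = 0.05,
                           mask_probability: float = 0.5,
                           temperature: float = 0.30,
                           seed: int = 0) -> Trajectory:
    """Random walk v <- E + scale * n ⊙ sigma ⊙ m, decoding at each step."""
    rng = np.random.default_rng(seed)
    e = np.asarray(start_rep, dtype=np.float64).copy()
    traj = Trajectory(header={
        "procedure": "stochastic_propagation", "steps": steps, "scale": scale,
        "mask_probability": mask_probability, "temperature": temperature,
        "seed": seed, "sigma_reference_set": stats.reference_set_id,
    })
    for step in range(steps):
        noise = rng.standard_normal(e.shape)
        mask = rng.random(e.shape) < mask_probability
        e = e + scale * noise * stats.sigma * mask
        smiles, valid = decode(decoder, vocabulary, e,
                               temperature=temperature, rng=rng)
        traj.steps.append(TrajectoryStep(
            step=step, representation=e.copy(), smiles=smiles, valid=valid,
            similarities={"to_start": _cos(e, start_rep)}))
    return traj


@dataclass
class ObjectiveSpec:
    """Targets and anchors for directed migration.

    ``mode``: "migrate" (property targets + 0.8 anchor similarity),
    "scaffold_hop" (pure 1 - sim_target pull toward a target representation),
    or "fuse".
    """

    mode: str = "migrate"
    property_targets: dict[str, float] = field(default_factory=dict)
    predictors: dict[str, tuple[PropertyPredictor, object]] = field(default_factory=dict)
    start_rep: np.ndarray | None = None
    target_rep: np.ndarray | None = None
    sim_weight_count: int | None = None   # override for the |J| factor
    scale_property_term: bool = False     # alternative precedence: the
    # |J| * 0.2 factor multiplies the property term as well

    def __post_init__(self):
        if self.mode == "migrate" and not self.property_targets:
            raise ValueError("migrate mode needs at least one property target")
        if self.mode == "scaffold_hop" and self.target_rep is None:
            raise ValueError("scaffold_hop mode needs a target representation")


def migration_similarity_loss(sim_start: float,
                              target: float = MIGRATION_SIM_TARGET) -> float:
    """L_sim = |sim_start - target|, minimized at the anchor similarity."""
    return abs(sim_start - target)


def migration_loss_terms(e: Tensor, objective: ObjectiveSpec) -> tuple[Tensor, dict]:
    if objective.mode == "scaffold_hop":
        loss = 1.0 - _cos_tensor(e, objective.target_rep)
        return loss, {"sim_target": 1.0 - float(loss.data)}

    sim = _cos_tensor(e, objective.start_rep)
    l_sim = (sim - MIGRATION_SIM_TARGET).abs()
    l_prop = Tensor(0.0)
    parts = {"sim_start": float(sim.data)}
    for name, target in objective.property_targets.items():
        predictor, scaler = objective.predictors[name]
        pred = predictor.forward(e)
        if scaler is not None:
            pred = (pred - 0.1) * (1.0 / 0.8) * (scaler.hi - scaler.lo) + scaler.lo
        term = (Tensor(float(target)) - pred.sum()).abs()
        l_prop = l_prop + term
        parts[f"prop_{name}"] = float(pred.data.sum())
    count_j = objective.sim_weight_count
    if count_j is None:
        count_j = len(objective.property_targets)
    if objective.scale_property_term:
        loss = count_j * 0.2 * (l_sim + l_prop)
    else:
        loss = count_j * 0.2 * l_sim + l_prop
    parts["l_sim"] = float(l_sim.data)
    parts["l_prop"] = float(l_prop.data)
    return loss, parts


def directed_migration(start_rep: np.ndarray, objective: ObjectiveSpec,
                       decoder: Decoder | None = None,
                       vocabulary: Vocabulary | None = None,
                       lr: float = 2e-5, steps: int = 600,
                       temperature: float = 0.4, seed: int = 0,
                       weight_decay: float = 0.0) -> Trajectory:
    """Gradient descent on the representation vector under the migration loss.

    Only the representation is optimized (AdamW); predictors and decoder stay
    frozen.  When a decoder is supplied, each step's representation is decoded
    at the given temperature and logged with its validity flag.
    """
    if objective.start_rep is None:
        objective.start_rep = np.asarray(start_rep, dtype=np.float64).copy()
    rng = np.random.default_rng(seed)
    e = Tensor(np.atleast_2d(np.asarray(start_rep, dtype=np.float64)).copy(),
               requires_grad=True)
    opt = AdamW([e], lr=lr, weight_decay=weight_decay)
    traj = Trajectory(header={"procedure": "directed_migration",
                              "mode": objective.mode, "lr": lr, "steps": steps,
                              "temperature": temperature, "seed": seed})
    for step in range(steps):
        loss, parts = migration_loss_terms(e, objective)
        if not np.isfinite(loss.data):
            traj.header["aborted"] = f"non-finite loss at step {step}"
            break
        opt.zero_grad()
        loss.backward()
        opt.step()
        smiles, valid = ("", False)
        if decoder is not None:
            smiles, valid = decode(decoder, vocabulary, e.data[0],
                                   temperature=temperature, rng=rng)
        traj.steps.append(TrajectoryStep(
            step=step, representation=e.data[0].copy(), smiles=smiles,
            valid=valid, losses={"total": float(loss.data), **parts},
            similarities={"to_start": _cos(e.data, start_rep)}))
    return traj


def fusion_loss(e: Tensor, reference_reps: np.ndarray) -> tuple[Tensor, int]:
    """min over references of 1 / (1 + 10000^(sim - 0.6)), with its argmin.

    The power is evaluated in log space; gradients flow through the argmin
    branch only (hard minimum with subgradient).
    """
    reference_reps = np.atleast_2d(reference_reps)
    sims = cosine_similarity_matrix(e.data, reference_reps)[0]
    log_base = np.log(FUSION_BASE)
    values = 1.0 / (1.0 + np.exp((sims - FUSION_SIM_MIDPOINT) * log_base))
    arg = int(np.argmin(values))
    sim = _cos_tensor(e, reference_reps[arg])
    term = 1.0 / (((sim - FUSION_SIM_MIDPOINT) * log_base).exp() + 1.0)
    return term, arg


def chemical_fusion(reference_reps: np.ndarray, start_rep: np.ndarray,
                    decoder: Decoder | None = None,
                    vocabulary: Vocabulary | None = None,
                    lr: float = 3e-5, steps: int = 1000,
                    temperature: float = 0.4, seed: int = 0) -> Trajectory:
    """Descend toward the nearest reference embedding to blend chemotypes."""
    reference_reps = np.atleast_2d(reference_reps)
    if len(reference_reps) < 2:
        raise ValueError("chemical fusion needs at least two reference molecules")
    rng = np.random.default_rng(seed)
    e = Tensor(np.atleast_2d(np.asarray(start_rep, dtype=np.float64)).copy(),
               requires_grad=True)
    opt = AdamW([e], lr=lr, weight_decay=0.0)
    traj = Trajectory(header={"procedure": "chemical_fusion", "lr": lr,
                              "steps": steps, "temperature": temperature,
                              "seed": seed, "n_references": len(reference_reps)})
    for step in range(steps):
        loss, arg = fusion_loss(e, reference_reps)
        if not np.isfinite(loss.data):
            traj.header["aborted"] = f"non-finite loss at step {step}"
            break
        opt.zero_grad()
        loss.backward()
        opt.step()
        smiles, valid = ("", False)
        if decoder is not None:
            smiles, valid = decode(decoder, vocabulary, e.data[0],
                                   temperature=temperature, rng=rng)
        sims = cosine_similarity_matrix(e.data, reference_reps)[0]
        traj.steps.append(TrajectoryStep(
            step=step, representation=e.data[0].copy(), smiles=smiles,
            valid=valid, losses={"total": float(loss.data)},
            similarities={"nearest_reference": int(arg),
                          "max_reference_sim": float(sims.max())}))
    return traj


def ligand_efficiency(dg: float, n_heavy: int) -> float:
    """LE = dG / (1 + ln N_heavy), kcal/mol per effective heavy atom."""
    if n_heavy < 1:
        raise ValueError("heavy-atom count must be at least 1")
    return float(dg / (1.0 + np.log(n_heavy)))
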