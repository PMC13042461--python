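"""Training loops, schedules, early stopping, split hygiene, checkpoints.

All three trainers (similarity pre-training, SMILES reconstruction, property
prediction) share one learning-rate policy: a linear warmup from 10% of the
base rate, then a cosine oscillation between the base rate and 50% of it.
Early stopping monitors a validation metric every ``eval_every`` steps and
terminates after ``patience`` evaluations without strict improvement,
restoring the best-validation parameters.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from scipy.stats import spearmanr

from .chemio import Molecule, TokenSequence, Vocabulary, featurize
from .decoder import Decoder, weighted_ce_loss
from .encoder import RepresentationModel
from .nn import AdamW, Module, Tensor, gather_rows
from .predictor import PropertyPredictor
from .simlabels import SimilarityMatrix

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


class SplitError(ValueError):
    def __init__(self, violations):
        self.violations = violations
        super().__init__(
            f"{len(violations)} cross-split pairs exceed the homology cutoff; "
            f"worst: {violations[0] if violations else None}")


class DivergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Schedules and rules
# ---------------------------------------------------------------------------

@dataclass
class ScheduleConfig:
    base_lr: float = 5e-5
    weight_decay: float = 0.01
    warmup_steps: int = 10_000
    warmup_start_fraction: float = 0.10
    cosine_min_fraction: float = 0.50
    cosine_period: int = 10_000

    def __post_init__(self):
        if not (0 < self.warmup_start_fraction <= 1 and 0 < self.cosine_min_fraction <= 1):
            raise ValueError("schedule fractions must lie in (0, 1]")
        if self.cosine_period < 1:
            raise ValueError("cosine period must be positive")


@dataclass
class EarlyStopConfig:
    eval_every: int = 200
    patience: int = 60

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be at least 1")


def lr_at(step: int, cfg: ScheduleConfig) -> float:
    """Learning rate at a global step: linear warmup, then cosine cycling.

    Warmup ramps from ``warmup_start_fraction * base_lr`` to ``base_lr`` over
    ``warmup_steps``; afterwards the rate oscillates between ``base_lr`` and
    ``cosine_min_fraction * base_lr`` with the configured period.  The two
    phases join continuously at ``step == warmup_steps``.
    """
    if step < 0:
        raise ValueError("step must be non-negative")
    base = cfg.base_lr
    if cfg.warmup_steps > 0 and step < cfg.warmup_steps:
        start = cfg.warmup_start_fraction * base
        return start + (base - start) * step / cfg.warmup_steps
    lo = cfg.cosine_min_fraction * base
    phase = 2.0 * np.pi * (step - cfg.warmup_steps) / cfg.cosine_period
    return lo + (base - lo) * 0.5 * (1.0 + np.cos(phase))


def batch_size_rule(n_train: int) -> int:
    """Training-set-size-dependent batch size: 96 / 64 / 48."""
    if n_train < 1:
        raise ValueError("training set must be non-empty")
    if n_train > 5000:
        return 96
    if n_train > 1000:
        return 64
    return 48


def split_guard(train: list[Molecule], valid: list[Molecule],
                test: list[Molecule], cutoff: float = 0.3) -> dict:
    """Assert that validation/test molecules are non-homologous to training.

    The maximum cross-split ECFP4 Tanimoto must stay below ``cutoff``;
    violations raise :class:`SplitError` listing the offending pairs.
    """
    if not train or not valid or not test:
        raise ValueError("all three splits must be non-empty")
    fp = {m.smiles: _MORGAN.GetFingerprint(m.to_rdkit())
          for m in train + valid + test}
    violations = []
    max_sim = 0.0
    for held in (valid, test):
        for hm in held:
            sims = DataStructs.BulkTanimotoSimilarity(
                fp[hm.smiles], [fp[tm.smiles] for tm in train])
            for tm, s in zip(train, sims):
                max_sim = max(max_sim, s)
                if s >= cutoff:
                    violations.append((hm.smiles, tm.smiles, round(s, 4)))
    if violations:
        violations.sort(key=lambda v: -v[2])
        raise SplitError(violations)
    return {"max_cross_split_tanimoto": max_sim, "cutoff": cutoff,
            "n_train": len(train), "n_valid": len(valid), "n_test": len(test)}


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: Module, config: dict,
                    optimizer: AdamW | None = None,
                    vocabulary: Vocabulary | None = None):
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "params.npz", **model.state_dict())
    (out / "config.json").write_text(json.dumps(config, indent=1, default=str))
    if optimizer is not None:
        np.savez(out / "optimizer.npz", **optimizer.state_dict())
    if vocabulary is not None:
        vocabulary.save(out / "vocabulary.json")


def load_checkpoint(path: str | Path, model: Module,
                    optimizer: AdamW | None = None) -> dict:
    out = Path(path)
    with np.load(out / "params.npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    if optimizer is not None and (out / "optimizer.npz").exists():
        with np.load(out / "optimizer.npz") as data:
            optimizer.load_state_dict({k: data[k] for k in data.files})
    return json.loads((out / "config.json").read_text())


# ---------------------------------------------------------------------------
# Shared loop plumbing
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    best_metric: float
    steps_run: int
    history: list[dict] = field(default_factory=list)

    def write_log(self, path: str | Path):
        with open(path, "w") as fh:
            for row in self.history:
                fh.write(json.dumps(row) + "\n")


class _EarlyStopper:
    """Strict-improvement early stopping with best-state restoration."""

    def __init__(self, cfg: EarlyStopConfig, mode: str):
        self.cfg = cfg
        self.sign = 1.0 if mode == "max" else -1.0
        self.best = -np.inf
        self.best_state = None
        self.stale = 0

    def update(self, metric: float, model: Module) -> bool:
        """Record an evaluation; returns True when training should stop."""
        if self.sign * metric > self.best:
            self.best = self.sign * metric
            self.best_state = copy.deepcopy(model.state_dict())
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.cfg.patience

    @property
    def best_metric(self) -> float:
        return self.sign * self.best


# ---------------------------------------------------------------------------
# Similarity pre-training
# ---------------------------------------------------------------------------

@dataclass
class SimilarityTrainConfig:
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    early_stop: EarlyStopConfig = field(default_factory=EarlyStopConfig)
    q_block: int = 512
    r_block: int = 48
    max_steps: int = 100_000
    freeze_steps: int = 2000     # graph-network warm-start freeze window
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0, max_steps: int = 3000) -> "SimilarityTrainConfig":
        # desk profile: small blocks, no pre-trained graph weights to protect
        return cls(
            schedule=ScheduleConfig(base_lr=1e-3, warmup_steps=100, cosine_period=500),
            early_stop=EarlyStopConfig(eval_every=50, patience=12),
            q_block=16, r_block=8, max_steps=max_steps, freeze_steps=0, seed=seed)


def _pairwise_predictions(model: RepresentationModel, q_reps: Tensor,
                          r_reps: Tensor) -> Tensor:
    nq, nr = q_reps.shape[0], r_reps.shape[0]
    qi = np.repeat(np.arange(nq), nr)
    ri = np.tile(np.arange(nr), nq)
    return model.projector(gather_rows(q_reps, qi), gather_rows(r_reps, ri))


def evaluate_similarity(model: RepresentationModel, matrix: SimilarityMatrix,
                        query_idx: np.ndarray,
                        components: slice = slice(None)) -> float:
    """Spearman correlation of predicted vs label similarities (eval mode)."""
    was_training = model.training
    model.eval()
    graphs = [featurize(matrix.queries[i]) for i in query_idx]
    q_reps = model.encoder.forward_graphs(graphs)
    r_reps = model.encoder.forward_graphs([featurize(r) for r in matrix.references])
    preds = _pairwise_predictions(model, q_reps, r_reps).data.reshape(
        len(query_idx), len(matrix.references), 8)
    if was_training:
        model.train()
    labels = matrix.values[query_idx]
    rho = spearmanr(preds[..., components].ravel(),
                    labels[..., components].ravel()).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def train_similarity(model: RepresentationModel, matrix: SimilarityMatrix,
                     train_query_idx, valid_query_idx,
                     cfg: SimilarityTrainConfig) -> TrainResult:
    """Similarity pre-training on sampled query x reference blocks.

    Each step draws ``q_block`` queries and ``r_block`` references, encodes
    them jointly, and minimizes the MSE between the projected 8-component
    block and the label matrix.  Graph-network (WLN) parameters are frozen
    for the first ``freeze_steps`` steps; early stopping monitors validation
    Spearman.
    """
    rng = np.random.default_rng(cfg.seed)
    train_query_idx = np.asarray(train_query_idx)
    valid_query_idx = np.asarray(valid_query_idx)
    graphs = {i: featurize(matrix.queries[i]) for i in train_query_idx}
    ref_graphs = [featurize(r) for r in matrix.references]

    opt = AdamW(model.parameters(), lr=cfg.schedule.base_lr,
                weight_decay=cfg.schedule.weight_decay)
    enc = model.encoder
    graph_params = [p for layer in (enc.atom_in, enc.bond_in, enc.contact,
                                    enc.aggregate, enc.gate_self, enc.gate_bond,
                                    enc.gate_atom)
                    for p in layer.parameters()]
    stopper = _EarlyStopper(cfg.early_stop, mode="max")
    result = TrainResult(best_metric=-np.inf, steps_run=0)
    model.train()

    for step in range(cfg.max_steps):
        opt.lr = lr_at(step, cfg.schedule)
        q_sel = rng.choice(train_query_idx, size=min(cfg.q_block, len(train_query_idx)),
                           replace=False)
        r_sel = rng.choice(len(matrix.references),
                           size=min(cfg.r_block, len(matrix.references)), replace=False)
        q_reps = enc.forward_graphs([graphs[i] for i in q_sel])
        r_reps = enc.forward_graphs([ref_graphs[i] for i in r_sel])
        preds = _pairwise_predictions(model, q_reps, r_reps)
        labels = matrix.values[np.ix_(q_sel, r_sel)].reshape(-1, 8)
        loss = ((preds - Tensor(labels)) ** 2.0).mean()
        if not np.isfinite(loss.data):
            raise DivergenceError(f"non-finite similarity loss at step {step}")
        opt.zero_grad()
        loss.backward()
        if step < cfg.freeze_steps:
            for p in graph_params:
                p.grad = None
        opt.step()
        result.history.append({"step": step, "lr": opt.lr, "loss": float(loss.data)})
        result.steps_run = step + 1

        if (step + 1) % cfg.early_stop.eval_every == 0:
            metric = evaluate_similarity(model, matrix, valid_query_idx)
            result.history[-1]["val_spearman"] = metric
            if stopper.update(metric, model):
                break

    if stopper.best_state is None and result.steps_run:
        stopper.update(evaluate_similarity(model, matrix, valid_query_idx), model)
    if stopper.best_state is not None:
        model.load_state_dict(stopper.best_state)
    result.best_metric = stopper.best_metric
    return result


# ---------------------------------------------------------------------------
# Reconstruction training
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionTrainConfig:
    schedule: ScheduleConfig = field(
        default_factory=lambda: ScheduleConfig(cosine_period=4000))
    early_stop: EarlyStopConfig = field(default_factory=EarlyStopConfig)
    max_steps: int = 100_000
    batch_size: int | None = None      # default: batch_size_rule(n_train)
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0, max_steps: int = 4000) -> "ReconstructionTrainConfig":
        return cls(
            schedule=ScheduleConfig(base_lr=1e-3, warmup_steps=100, cosine_period=1000),
            early_stop=EarlyStopConfig(eval_every=200, patience=8),
            max_steps=max_steps, seed=seed)


def pad_sequences(sequences: list[TokenSequence], pad_index: int = 0) -> np.ndarray:
    length = max(len(s) for s in sequences)
    out = np.full((len(sequences), length), pad_index, dtype=np.intp)
    for i, s in enumerate(sequences):
        out[i, :len(s)] = s.indices
    return out


def train_reconstruction(decoder: Decoder, reps: np.ndarray,
                         sequences: list[TokenSequence],
                         cfg: ReconstructionTrainConfig,
                         valid_reps: np.ndarray | None = None,
                         valid_sequences: list[TokenSequence] | None = None,
                         ) -> TrainResult:
    """Teacher-forced reconstruction training on precomputed representations.

    The encoder is frozen by construction (only representations enter); early
    stopping monitors validation weighted cross-entropy, falling back to the
    training loss when no validation set is supplied.
    """
    rng = np.random.default_rng(cfg.seed)
    padded = pad_sequences(sequences)
    reps = np.asarray(reps, dtype=np.float64)
    decoder.calibrate_memory_scale(reps)
    n = len(sequences)
    batch = cfg.batch_size or batch_size_rule(n)
    if valid_sequences is not None:
        val_padded = pad_sequences(valid_sequences)
        val_reps = np.asarray(valid_reps, dtype=np.float64)
    else:
        val_padded, val_reps = padded, reps

    opt = AdamW(decoder.parameters(), lr=cfg.schedule.base_lr,
                weight_decay=cfg.schedule.weight_decay)
    stopper = _EarlyStopper(cfg.early_stop, mode="min")
    result = TrainResult(best_metric=np.inf, steps_run=0)
    decoder.train()

    def eval_loss() -> float:
        decoder.eval()
        logits = decoder.forward_tokens(val_reps, val_padded[:, :-1])
        loss = weighted_ce_loss(logits, val_padded[:, 1:])
        decoder.train()
        return float(loss.data)

    for step in range(cfg.max_steps):
        opt.lr = lr_at(step, cfg.schedule)
        sel = rng.choice(n, size=min(batch, n), replace=False)
        logits = decoder.forward_tokens(reps[sel], padded[sel, :-1])
        loss = weighted_ce_loss(logits, padded[sel, 1:])
        if not np.isfinite(loss.data):
            raise DivergenceError(f"non-finite reconstruction loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        result.history.append({"step": step, "lr": opt.lr, "loss": float(loss.data)})
        result.steps_run = step + 1

        if (step + 1) % cfg.early_stop.eval_every == 0:
            metric = eval_loss()
            result.history[-1]["val_loss"] = metric
            if stopper.update(metric, decoder):
                break

    if stopper.best_state is None and result.steps_run:
        stopper.update(eval_loss(), decoder)
    if stopper.best_state is not None:
        decoder.load_state_dict(stopper.best_state)
    result.best_metric = stopper.best_metric
    return result


# ---------------------------------------------------------------------------
# Property training
# ---------------------------------------------------------------------------

@dataclass
class LabelScaler:
    """Affine map of raw labels into (0.1, 0.9) for the SiLU-terminated head."""

    lo: float
    hi: float

    @classmethod
    def fit(cls, labels: np.ndarray) -> "LabelScaler":
        lo, hi = float(np.min(labels)), float(np.max(labels))
        if hi == lo:
            hi = lo + 1.0
        return cls(lo=lo, hi=hi)

    def forward(self, labels: np.ndarray) -> np.ndarray:
        return 0.1 + 0.8 * (np.asarray(labels) - self.lo) / (self.hi - self.lo)

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return self.lo + (np.asarray(scaled) - 0.1) / 0.8 * (self.hi - self.lo)


@dataclass
class PredictorTrainConfig:
    schedule: ScheduleConfig = field(
        default_factory=lambda: ScheduleConfig(cosine_period=2000))
    early_stop: EarlyStopConfig = field(default_factory=EarlyStopConfig)
    max_steps: int = 50_000
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0, max_steps: int = 3000) -> "PredictorTrainConfig":
        return cls(
            schedule=ScheduleConfig(base_lr=1e-3, warmup_steps=100, cosine_period=1000),
            early_stop=EarlyStopConfig(eval_every=100, patience=10),
            max_steps=max_steps, seed=seed)


def train_predictor(predictor: PropertyPredictor, reps: np.ndarray,
                    labels: np.ndarray, valid_reps: np.ndarray,
                    valid_labels: np.ndarray,
                    cfg: PredictorTrainConfig) -> tuple[TrainResult, LabelScaler]:
    """MSE property training on fixed representations (projection mode).

    The cosine period follows the dataset-size rule (2000 steps above 5000
    training samples, 1000 below); batch size follows ``batch_size_rule``.
    Early stopping monitors validation Spearman.
    """
    rng = np.random.default_rng(cfg.seed)
    reps = np.asarray(reps, dtype=np.float64)
    predictor.calibrate_input_scale(reps)
    labels = np.asarray(labels, dtype=np.float64).reshape(len(reps), -1)
    scaler = LabelScaler.fit(labels)
    y = scaler.forward(labels)
    y_val = scaler.forward(np.asarray(valid_labels).reshape(len(valid_reps), -1))
    n = len(reps)
    batch = batch_size_rule(n)

    opt = AdamW(predictor.parameters(), lr=cfg.schedule.base_lr,
                weight_decay=cfg.schedule.weight_decay)
    stopper = _EarlyStopper(cfg.early_stop, mode="max")
    result = TrainResult(best_metric=-np.inf, steps_run=0)
    predictor.train()

    def val_spearman() -> float:
        preds = predictor.predict(valid_reps)
        rho = spearmanr(preds.ravel(), y_val.ravel()).statistic
        return float(rho) if np.isfinite(rho) else 0.0

    for step in range(cfg.max_steps):
        opt.lr = lr_at(step, cfg.schedule)
        sel = rng.choice(n, size=min(batch, n), replace=False)
        preds = predictor.forward(Tensor(reps[sel]))
        loss = ((preds - Tensor(y[sel])) ** 2.0).mean()
        if not np.isfinite(loss.data):
            raise DivergenceError(f"non-finite property loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        result.history.append({"step": step, "lr": opt.lr, "loss": float(loss.data)})
        result.steps_run = step + 1

        if (step + 1) % cfg.early_stop.eval_every == 0:
            metric = val_spearman()
            result.history[-1]["val_spearman"] = metric
            if stopper.update(metric, predictor):
                break

    if stopper.best_state is None and result.steps_run:
        stopper.update(val_spearman(), predictor)
    if stopper.best_state is not None:
        predictor.load_state_dict(stopper.best_state)
    result.best_metric = stopper.best_metric
    return result, scaler
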