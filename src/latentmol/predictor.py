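"""Property predictor heads over frozen (or fine-tuned) representations.

Architecture, at full scale (rep_dim 2048): dropout(0.5) on the input, a
linear expansion 2048 -> 8192 with sigmoid; concatenation with the original
representation (10240); two 10240 linears with LeakyReLU + batch norm
between them; an element-wise residual add of the block input; then
linear + batch norm + SiLU down to 1024, batch norm + SiLU, and a final
linear + SiLU to the property dimension.  The desk profile scales every
width by rep_dim / 2048.

Fine-tuning always operates on a deep copy of the encoder, so the shared
reconstruction-compatible encoder that the decoder depends on is never
mutated by property training.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .encoder import Encoder
from .nn import BatchNorm1d, Dropout, Linear, Module, Tensor, concat

FULL_REP_DIM = 2048


class OptimizationError(RuntimeError):
    pass


@dataclass
class PredictorConfig:
    rep_dim: int = FULL_REP_DIM
    output_dim: int = 1
    dropout: float = 0.5
    seed: int = 0

    @property
    def expansion_dim(self) -> int:
        return 4 * self.rep_dim            # 2048 -> 8192 at full scale

    @property
    def concat_dim(self) -> int:
        return self.expansion_dim + self.rep_dim   # 10240 at full scale

    @property
    def penultimate_dim(self) -> int:
        return self.rep_dim // 2           # 1024 at full scale

    def width_trace(self) -> tuple[int, ...]:
        return (self.expansion_dim, self.concat_dim, self.concat_dim,
                self.concat_dim, self.penultimate_dim, self.output_dim)


class PropertyPredictor(Module):
    def __init__(self, config: PredictorConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed + 303)
        self.dropout = Dropout(config.dropout, rng)
        # representation magnitudes differ by orders of magnitude between
        # encoders; inputs are divided by this calibrated scale so the sigmoid
        # expansion starts in its responsive range
        self._buffers = {"rep_scale": np.asarray(1.0)}
        self.expand = Linear(config.rep_dim, config.expansion_dim, rng, init="xavier")
        self.block1 = Linear(config.concat_dim, config.concat_dim, rng)
        self.block_norm = BatchNorm1d(config.concat_dim)
        self.block2 = Linear(config.concat_dim, config.concat_dim, rng)
        self.down = Linear(config.concat_dim, config.penultimate_dim, rng)
        self.down_norm1 = BatchNorm1d(config.penultimate_dim)
        self.down_norm2 = BatchNorm1d(config.penultimate_dim)
        self.out = Linear(config.penultimate_dim, config.output_dim, rng)

    def calibrate_input_scale(self, reps: np.ndarray):
        """Set input normalization from a set of training representations."""
        scale = float(np.abs(np.asarray(reps)).max())
        self._buffers["rep_scale"] = np.asarray(max(scale, 1e-8))

    def forward(self, reps: Tensor) -> Tensor:
        reps = reps * (1.0 / float(self._buffers["rep_scale"]))
        x = self.expand(self.dropout(reps)).sigmoid()
        x = concat([x, reps], axis=-1)
        block = self.block2(self.block_norm(self.block1(x).leaky_relu()))
        x = x + block                                   # residual add
        x = self.down_norm1(self.down(x)).silu()
        x = self.down_norm2(x).silu()
        return self.out(x).silu()

    def predict(self, reps: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode prediction for (n, rep_dim) input."""
        reps = np.atleast_2d(np.asarray(reps, dtype=np.float64))
        if reps.shape[1] != self.config.rep_dim:
            raise ValueError("representation length must equal rep_dim")
        was_training = self.training
        self.eval()
        out = self.forward(Tensor(reps)).data.copy()
        if was_training:
            self.train()
        return out


def gradient_wrt_representation(rep: np.ndarray, objective) -> np.ndarray:
    """Gradient of a scalar objective with respect to the representation.

    ``objective`` maps a requires-grad Tensor of shape (1, rep_dim) to a
    scalar Tensor; non-finite gradients raise :class:`OptimizationError`.
    """
    t = Tensor(np.atleast_2d(np.asarray(rep, dtype=np.float64)).copy(),
               requires_grad=True)
    loss = objective(t)
    loss.backward()
    grad = t.grad.ravel().copy()
    if not np.all(np.isfinite(grad)):
        raise OptimizationError("non-finite gradient with respect to representation")
    return grad


def clone_encoder_for_finetuning(encoder: Encoder) -> Encoder:
    """Deep-copy the encoder so fine-tuning cannot invalidate the decoder."""
    return copy.deepcopy(encoder)
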