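"""L1 training of the super-resolution network on fused-LR/HR cube pairs.

The optimizer is Adam with a step-decay learning-rate schedule: the rate
starts at ``lr_init`` and is halved every ``lr_halve_every`` iterations.
Cubes are sampled on the fly, uniformly with replacement, from the supplied
volume pairs, and each cube is flip-augmented along each axis independently
with probability 0.5.  Labels stay noise-free even when the inputs are
noisy.  Given a seed (and one device) the run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .degrade import TrainingPair, augment_flip, extract_training_cubes
from .network import SRNetwork
from .volume import Volume

__all__ = ["TrainConfig", "l1_loss", "lr_at", "train_model", "Adam"]


@dataclasses.dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults reproduce the full-scale recipe (4e5 iterations of batch-8
    24-cubes); scaled-down overrides are expected for CPU-sized runs.
    """

    batch_size: int = 8
    lr_init: float = 2e-4
    lr_halve_every: int = 100_000
    total_iters: int = 400_000
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    cube_size: int = 24
    seed: int = 0
    log_every: int = 10
    val_every: int = 5000

    def __post_init__(self) -> None:
        if min(self.batch_size, self.lr_halve_every, self.cube_size) < 1:
            raise ValueError("batch_size, lr_halve_every and cube_size must be >= 1")
        if self.total_iters < 0:
            raise ValueError("total_iters must be >= 0")
        if self.lr_init <= 0:
            raise ValueError("lr_init must be > 0")


def l1_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute voxel difference (mean over all voxels and batch)."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean(np.abs(pred.astype(np.float64) - target)))


def lr_at(iteration: int, cfg: TrainConfig) -> float:
    """Step-decay schedule: ``lr_init * 0.5 ** floor(iter / halve_every)``."""
    return cfg.lr_init * 0.5 ** (iteration // cfg.lr_halve_every)


class Adam:
    """Plain Adam over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(np.asarray(v, np.float64)) for k, v in params.items()}
        self.v = {k: np.zeros_like(np.asarray(v, np.float64)) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> dict[str, np.ndarray]:
        b1, b2, eps = self.cfg.adam_beta1, self.cfg.adam_beta2, self.cfg.adam_eps
        self.t += 1
        out = {}
        for k, p in params.items():
            g = np.asarray(grads[k], np.float64)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            upd = np.asarray(p, np.float64) - lr * mhat / (np.sqrt(vhat) + eps)
            out[k] = upd.astype(np.float32) if np.ndim(p) else np.float32(upd)
        return out


def _sample_batch(source, cfg: TrainConfig,
                  rng: np.random.Generator) -> list[TrainingPair]:
    if source and isinstance(source[0], TrainingPair):
        idx = rng.integers(0, len(source), size=cfg.batch_size)
        pairs = [source[i] for i in idx]
    else:
        pairs = []
        for _ in range(cfg.batch_size):
            x, y = source[int(rng.integers(0, len(source)))]
            pairs.extend(extract_training_cubes(x, y, cfg.cube_size, n=1, rng=rng))
    return [augment_flip(p, tuple(rng.random(3) < 0.5)) for p in pairs]


def train_model(model: SRNetwork, source, cfg: TrainConfig | None = None,
                val_fn=None):
    """Run ``cfg.total_iters`` Adam steps of L1 training.

    ``source`` is either a list of ``(fused_lr, hr)`` :class:`Volume` pairs
    (cubes are sampled on the fly) or a list of pre-extracted
    :class:`TrainingPair`.  ``val_fn(model, iteration)``, when given, is
    called every ``cfg.val_every`` iterations and its result logged.

    Returns ``(model, log)`` where ``log`` is a list of dicts with keys
    ``iter``, ``loss``, ``lr`` (and ``val`` on validation rows).  Raises
    ``RuntimeError`` naming the iteration if the loss goes non-finite.
    """
    cfg = cfg or TrainConfig()
    if not source:
        raise ValueError("empty training source")
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    opt = Adam(params, cfg)
    log: list[dict] = []
    for it in range(cfg.total_iters):
        batch = _sample_batch(source, cfg, rng)
        xb = np.stack([p.lr_cube for p in batch])
        yb = np.stack([p.hr_cube for p in batch]).astype(np.float32)

        def grad_fn(y):
            diff = y - yb
            loss = float(np.abs(diff, dtype=np.float64).mean())
            return loss, np.sign(diff, dtype=np.float32) / diff.size

        _, loss, grads = model.forward_backward(xb, grad_fn)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at iteration {it}")
        params = opt.step(params, grads, lr_at(it, cfg))
        model.set_parameters(params)
        if it % cfg.log_every == 0 or it == cfg.total_iters - 1:
            log.append({"iter": it, "loss": loss, "lr": lr_at(it, cfg)})
        if val_fn is not None and (it + 1) % cfg.val_every == 0:
            log.append({"iter": it + 1, "val": val_fn(model, it + 1)})
    return model, log
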