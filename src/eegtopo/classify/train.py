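"""Adam training loop with per-epoch history and validation-based selection."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from eegtopo.classify.layers import DTYPE, Param
from eegtopo.classify.network import HybridNet

__all__ = ["TrainConfig", "Adam", "train", "evaluate"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 32
    dropout: float = 0.5
    epochs: int = 30
    seed: int = 0
    # stop early once validation accuracy reaches this level (None = never)
    early_stop_val_acc: Optional[float] = None
    # give up after this many epochs if validation accuracy never exceeded
    # plateau_abort_acc (lets a restart harness retry cheaply; None = never)
    plateau_abort_epoch: Optional[int] = None
    plateau_abort_acc: float = 0.62

    def __post_init__(self) -> None:
        for name in ("learning_rate", "beta1", "beta2", "eps", "batch_size", "epochs"):
            if getattr(self, name) < 0 or (name not in ("epochs",) and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class Adam:
    def __init__(self, params: List[Param], cfg: TrainConfig) -> None:
        self.params = params
        self.cfg = cfg
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        c = self.cfg
        b1t = 1.0 - c.beta1**self.t
        b2t = 1.0 - c.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= c.beta1
            m += (1.0 - c.beta1) * g
            v *= c.beta2
            v += (1.0 - c.beta2) * g * g
            p.value -= DTYPE(c.learning_rate) * (m / b1t) / (np.sqrt(v / b2t) + c.eps)


def evaluate(model: HybridNet, x: np.ndarray, y: np.ndarray, batch_size: int = 64):
    """(mean cross-entropy loss, accuracy) without gradient bookkeeping."""
    probs = model.predict_proba(x, batch_size)
    eps = 1e-12
    loss = float(-np.log(probs[np.arange(len(y)), y] + eps).mean())
    acc = float((probs.argmax(axis=1) == y).mean())
    return loss, acc


def train(
    model: HybridNet,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    x_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
) -> Dict[str, List[float]]:
    """Train in place; returns per-epoch history.

    When a validation set is given, the parameters with the best validation
    accuracy are restored at the end (model selection on validation).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least two classes")
    history: Dict[str, List[float]] = {
        "train_loss": [],
        "train_acc": [],
        "val_loss": [],
        "val_acc": [],
    }
    if cfg.epochs == 0:
        return history
    rng = np.random.default_rng(cfg.seed)
    model.reseed_dropout(cfg.seed + 0x9E3779B9)
    optimizer = Adam(model.parameters(), cfg)
    best_val = -1.0
    best_state = None
    n = len(x)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            model.zero_grad()
            loss, probs = model.loss_and_grad(x[idx], y[idx])
            optimizer.step()
            losses.append(loss * len(idx))
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        history["train_loss"].append(float(np.sum(losses) / n))
        history["train_acc"].append(correct / n)
        if x_val is not None:
            val_loss, val_acc = evaluate(model, x_val, y_val)
            history["val_loss"].append(val_loss)
            history["val_acc"].append(val_acc)
            if val_acc >= best_val:  # ties -> latest (more trained) state
                best_val = val_acc
                best_state = model.get_state()
            if cfg.early_stop_val_acc is not None and val_acc >= cfg.early_stop_val_acc:
                break
            if (
                cfg.plateau_abort_epoch is not None
                and _epoch + 1 >= cfg.plateau_abort_epoch
                and best_val <= cfg.plateau_abort_acc
            ):
                break
    if best_state is not None:
        model.set_state(best_state)
    return history
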