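"""Optimiser, learning-rate schedule, early stopping and the Siamese loss.

The training protocol shared by all networks in this package:

* Adam, base learning rate 1e-3, batch size 32;
* exponential step decay — every 10 epochs the learning rate is multiplied
  by 0.992, i.e. ``lr(epoch) = lr0 * 0.992 ** (epoch // 10)`` exactly;
* early stopping on validation accuracy with a patience counter: training
  halts once no improvement has been seen for ``patience`` epochs, and the
  best-validation checkpoint is restored.

The Siamese (few-shot) objective is a cosine-similarity contrastive loss:
for a sample embedding ``f`` with class ``y`` and per-class reference
vectors ``r_c``,

    loss = (1 - cos(f, r_y)) + (1/(C-1)) * sum_{c != y} max(0, cos(f, r_c) - m)

averaged over the batch, with margin ``m`` (default 0): same-class pairs
are pulled to cosine 1, other-class pairs pushed below the margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .autograd import Tensor
from .modules import Module


@dataclass
class TrainConfig:
    """Shared training hyperparameters."""
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 150
    scheduler_step: int = 10
    scheduler_gamma: float = 0.992
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.scheduler_gamma <= 1:
            raise ValueError("scheduler gamma must be in (0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def scheduled_lr(lr0: float, epoch: int, step: int, gamma: float) -> float:
    """Learning rate at a (0-based) epoch: lr0 * gamma ** (epoch // step)."""
    return lr0 * gamma ** (epoch // step)


class Adam:
    """Adaptive-moment gradient descent over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_similarity_matrix(emb: Tensor, refs: Tensor,
                             eps: float = 1e-12) -> Tensor:
    """(B, C) cosine similarities between row embeddings and references."""
    f = emb * ((emb ** 2.0).sum(axis=1, keepdims=True) + eps) ** -0.5
    r = refs * ((refs ** 2.0).sum(axis=1, keepdims=True) + eps) ** -0.5
    return f @ _t(r)


def _t(x: Tensor) -> Tensor:
    # 2-D transpose via reshape-free matmul trick is not possible; use data move
    out = Tensor(x.data.T, requires_grad=x.requires_grad, parents=(x,))
    out._backward = lambda g: x._accum(g.T)
    return out


def siamese_cosine_loss(emb: Tensor, refs: Tensor, y_idx: np.ndarray,
                        margin: float = 0.0) -> Tensor:
    """Mean contrastive cosine loss of a batch against class references."""
    B, C = emb.shape[0], refs.shape[0]
    cos = cosine_similarity_matrix(emb, refs)
    onehot = np.zeros((B, C))
    onehot[np.arange(B), y_idx] = 1.0
    pull = ((1.0 - cos) * Tensor(onehot)).sum() * (1.0 / B)
    if C > 1:
        push = ((cos - margin).relu() * Tensor(1.0 - onehot)).sum() \
            * (1.0 / (B * (C - 1)))
        return pull + push
    return pull


@dataclass
class TrainHistory:
    """Per-epoch record of one training run."""
    lr: list[float]
    train_loss: list[float]
    val_accuracy: list[float]
    best_epoch: int
    stopped_epoch: int


def fit_loop(model: Module,
             loss_fn: Callable[[np.ndarray], Tensor],
             val_fn: Callable[[], float],
             n_train: int,
             config: TrainConfig) -> TrainHistory:
    """Generic mini-batch training with the package's shared protocol.

    ``loss_fn`` maps a batch index array to a scalar loss tensor (it closes
    over the training data); ``val_fn`` returns the current validation
    accuracy.  The model is left at its best-validation checkpoint.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF17]))
    opt = Adam(model.parameters(), lr=config.lr)
    best_acc = -np.inf
    best_epoch = -1
    best_state = model.get_state()
    hist = TrainHistory(lr=[], train_loss=[], val_accuracy=[],
                        best_epoch=-1, stopped_epoch=-1)
    for epoch in range(config.max_epochs):
        opt.lr = scheduled_lr(config.lr, epoch, config.scheduler_step,
                              config.scheduler_gamma)
        model.train()
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue  # batchnorm needs > 1 sample
            model.zero_grad()
            loss = loss_fn(idx)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss {loss.data} at epoch {epoch}; "
                    "training diverged")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        acc = float(val_fn())
        hist.lr.append(opt.lr)
        hist.train_loss.append(float(np.mean(losses)) if losses else np.nan)
        hist.val_accuracy.append(acc)
        if acc > best_acc:
            best_acc = acc
            best_epoch = epoch
            best_state = model.get_state()
        if epoch - best_epoch >= config.patience:
            break
    model.set_state(best_state)
    model.eval()
    hist.best_epoch = best_epoch
    hist.stopped_epoch = len(hist.val_accuracy) - 1
    return hist
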