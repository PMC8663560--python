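"""Training loop, multi-task loss, Adam, checkpoint selection, inference.

The loss is an equally weighted (configurable) sum over the eight heads:
softmax cross-entropy for the four binary tasks, mean absolute error on the
[0, 1]-normalized labels for the four regression tasks.  A per-head mask
excludes subjects with a missing label from that head's loss only, so one
missing value does not discard the scan for the other tasks.

The learning rate follows a cyclic, exponentially decaying schedule:
``lr(e) = init_lr * decay**e * (0.75 + 0.25 * cos(2*pi*e / cycle_len))``,
i.e. the raised-cosine cycle is rescaled into [0.5, 1] and multiplied onto
an exponential envelope; at epoch 0 the rate equals ``init_lr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .densenet import ALL_HEADS, CLASSIFICATION_HEADS, REGRESSION_HEADS, DenseNet3D, ModelConfig


def cyclic_exp_lr(epoch: int, cfg: ModelConfig) -> float:
    cyc = 0.75 + 0.25 * np.cos(2 * np.pi * epoch / cfg.lr_cycle_len)
    return float(cfg.init_lr * cfg.lr_decay**epoch * cyc)


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params  # list of (layer, name)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[n]) for layer, n in params]
        self.v = [np.zeros_like(layer.params[n]) for layer, n in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (layer, n) in enumerate(self.params):
            g = layer.grads[n]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            layer.params[n] -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def multitask_loss(
    logits: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
    masks: dict[str, np.ndarray] | None = None,
    weights: dict[str, float] | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Return (scalar loss, gradient dict w.r.t. head outputs).

    ``labels``: per classification head an int array in {0, 1}; per
    regression head a float array on the normalized scale.  ``masks``: per
    head a boolean array, True where the label is observed.
    """
    n = next(iter(labels.values())).shape[0]
    masks = masks or {}
    weights = weights or {}
    loss = 0.0
    grads: dict[str, np.ndarray] = {}
    for head in CLASSIFICATION_HEADS:
        if head not in labels:
            continue
        w = weights.get(head, 1.0)
        z = logits[head]
        m = masks.get(head, np.ones(n, dtype=bool)).astype(np.float32)
        denom = max(m.sum(), 1.0)
        zs = z - z.max(axis=1, keepdims=True)
        logp = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
        y = labels[head].astype(int)
        loss += w * float(-(m * logp[np.arange(n), y]).sum() / denom)
        p = np.exp(logp)
        g = p.copy()
        g[np.arange(n), y] -= 1.0
        grads[head] = w * g * (m / denom)[:, None]
    for head in REGRESSION_HEADS:
        if head not in labels:
            continue
        w = weights.get(head, 1.0)
        pred = logits[head][:, 0]
        m = masks.get(head, np.ones(n, dtype=bool)).astype(np.float32)
        denom = max(m.sum(), 1.0)
        r = pred - labels[head]
        loss += w * float((m * np.abs(r)).sum() / denom)
        grads[head] = (w * np.sign(r) * m / denom)[:, None].astype(np.float32)
    return loss, grads


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    val_metrics: list[dict[str, float]] = field(default_factory=list)
    checkpoints: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, e in enumerate(self.epochs):
            row = {"epoch": e, "train_loss": self.train_loss[i], "lr": self.lr[i]}
            row.update(self.val_metrics[i])
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate_heads(
    net: DenseNet3D, x: np.ndarray, labels: dict[str, np.ndarray], masks: dict[str, np.ndarray] | None = None,
    batch_size: int = 16,
) -> dict[str, float]:
    """Validation metrics: AUROC per binary head, normalized MAE per regression head."""
    preds = infer(net, x, batch_size=batch_size)
    masks = masks or {}
    out: dict[str, float] = {}
    n = x.shape[0]
    for head in CLASSIFICATION_HEADS:
        if head not in labels:
            continue
        m = masks.get(head, np.ones(n, dtype=bool))
        y = labels[head][m].astype(int)
        if len(np.unique(y)) < 2:
            out[f"auroc_{head}"] = float("nan")
        else:
            out[f"auroc_{head}"] = float(roc_auc_score(y, preds[head][m, 1]))
    for head in REGRESSION_HEADS:
        if head not in labels:
            continue
        m = masks.get(head, np.ones(n, dtype=bool))
        out[f"mae_{head}"] = float(np.mean(np.abs(preds[head][m] - labels[head][m])))
    return out


def train_model(
    net: DenseNet3D,
    train_data: tuple[np.ndarray, dict, dict | None],
    val_data: tuple[np.ndarray, dict, dict | None],
    cfg: ModelConfig | None = None,
    epochs: int | None = None,
    seed: int = 0,
    augment_fn=None,
    verbose: bool = False,
) -> TrainingHistory:
    """Train with Adam under the cyclic exponentially decaying schedule.

    ``augment_fn(batch, rng) -> batch`` is applied to training batches only;
    validation volumes are used as given (callers center them beforehand).
    Checkpoints (full parameter snapshots) are stored once per epoch together
    with the validation metrics.
    """
    cfg = cfg or net.cfg
    xtr, ytr, mtr = train_data
    xval, yval, mval = val_data
    if xtr.shape[0] == 0 or xval.shape[0] == 0:
        raise ValueError("training and validation folds must be nonempty")
    n_epochs = epochs if epochs is not None else cfg.max_epochs
    rng = np.random.default_rng(seed)
    opt = Adam(net.parameters(), lr=cfg.init_lr)
    hist = TrainingHistory()
    n = xtr.shape[0]
    for epoch in range(n_epochs):
        opt.lr = cyclic_exp_lr(epoch, cfg)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = xtr[idx]
            if augment_fn is not None:
                xb = augment_fn(xb, rng)
            logits = net.forward(xb, train=True)
            yb = {h: ytr[h][idx] for h in ytr}
            mb = {h: mtr[h][idx] for h in mtr} if mtr else None
            loss, dlogits = multitask_loss(logits, yb, mb, cfg.loss_weights)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch} (loss={loss})")
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        metrics = evaluate_heads(net, xval, yval, mval)
        hist.epochs.append(epoch)
        hist.train_loss.append(float(np.mean(losses)))
        hist.lr.append(opt.lr)
        hist.val_metrics.append(metrics)
        hist.checkpoints.append(net.snapshot())
        if verbose:
            print(f"epoch {epoch}: loss={hist.train_loss[-1]:.4f} " +
                  " ".join(f"{k}={v:.3f}" for k, v in metrics.items()))
    return hist


def select_checkpoint(history: TrainingHistory, metric: str = "auroc_diabetes") -> tuple[int, dict]:
    """Pick the checkpoint with the highest validation diabetes AUROC.

    Ties are broken in favour of the earliest epoch. Returns (epoch, state).
    """
    if not history.checkpoints:
        raise ValueError("history contains no evaluated checkpoints")
    scores = np.array([m.get(metric, np.nan) for m in history.val_metrics], dtype=float)
    if np.all(np.isnan(scores)):
        raise ValueError(f"metric {metric!r} was never evaluated")
    best = int(np.nanargmax(scores))
    return history.epochs[best], history.checkpoints[best]


def infer(net: DenseNet3D, volumes: np.ndarray, batch_size: int = 16) -> dict[str, np.ndarray]:
    """Eval-mode predictions for a stack of volumes (N, D, H, W)."""
    if volumes.shape[1:] != net.input_dims:
        raise ValueError(f"volume dims {volumes.shape[1:]} != network input {net.input_dims}")
    parts: list[dict[str, np.ndarray]] = []
    for start in range(0, volumes.shape[0], batch_size):
        parts.append(net.predict(volumes[start : start + batch_size]))
    return {k: np.concatenate([p[k] for p in parts], axis=0) for k in parts[0]}
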