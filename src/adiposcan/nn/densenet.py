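"""Multi-task 3D DenseNet built from the NumPy layers.

Architecture: initial 5x5x5 convolution -> batch normalization -> max
pooling -> [dense block -> transition] x 3 -> flatten -> FC 512 -> FC 256 ->
FC 128 (the embedding) -> one output head per task.  Dense blocks use the
pre-activation composite (BN -> ELU -> conv3) and concatenative growth:
every layer appends ``growth_factor`` feature maps to the running feature
stack.  Transitions compress channels with a 1x1x1 convolution and halve
each spatial axis with average pooling.

Heads: binary tasks end in a 2-node softmax pair; regression tasks in a
single linear node (the only non-ELU activations in the network).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .layers import (
    ELU,
    AvgPool3d,
    BatchNorm1d,
    BatchNorm3d,
    Conv3d,
    Dropout,
    Flatten,
    Layer,
    Linear,
    MaxPool3d,
)

CLASSIFICATION_HEADS = ("sex", "diabetes", "prediabetes", "diabetes_ext")
REGRESSION_HEADS = ("age", "bmi", "insulin_sensitivity", "hba1c")
ALL_HEADS = CLASSIFICATION_HEADS + REGRESSION_HEADS


@dataclass
class ModelConfig:
    """Network and training hyperparameters.

    ``init_filters`` defaults to 8 initial activation maps; 4 is the other
    commonly quoted value for this architecture family and both are valid.
    """

    growth_factor: int = 18
    init_kernel: int = 5
    init_filters: int = 8
    dense_blocks: int = 3
    layers_per_block: int = 4
    compression: float = 0.5
    fc_widths: tuple[int, int, int] = (512, 256, 128)
    dropout_rate: float = 0.2
    batch_size: int = 8
    init_lr: float = 1e-4
    lr_decay: float = 0.98
    lr_cycle_len: int = 20
    max_epochs: int = 250
    loss_weights: dict = field(default_factory=dict)  # head -> weight, default 1.0

    def __post_init__(self) -> None:
        if self.growth_factor <= 0:
            raise ValueError("growth_factor must be positive")
        w = tuple(self.fc_widths)
        if not (w[0] > w[1] > w[2]):
            raise ValueError("fc_widths must be strictly decreasing")
        self.fc_widths = w

    @property
    def embedding_dim(self) -> int:
        return self.fc_widths[-1]


class _DenseBlock:
    """Concatenative block: layer i maps all accumulated features to k new maps."""

    def __init__(self, in_ch: int, n_layers: int, growth: int, rng: np.random.Generator):
        self.layers: list[list[Layer]] = []
        ch = in_ch
        for _ in range(n_layers):
            self.layers.append([BatchNorm3d(ch), ELU(), Conv3d(ch, growth, 3, rng)])
            ch += growth
        self.out_ch = ch

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        feats = [x]
        self._widths = [x.shape[1]]
        for comp in self.layers:
            h = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
            for layer in comp:
                h = layer.forward(h, train)
            feats.append(h)
            self._widths.append(h.shape[1])
        return np.concatenate(feats, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # split the incoming gradient along the concatenation boundaries
        bounds = np.cumsum(self._widths)[:-1]
        dfeats = list(np.split(dout, bounds, axis=1))
        for i in range(len(self.layers) - 1, -1, -1):
            g = dfeats.pop(i + 1)
            for layer in reversed(self.layers[i]):
                g = layer.backward(g)
            # g is the gradient w.r.t. concat(feats[0..i]); fold back in
            pieces = np.split(g, np.cumsum(self._widths[: i + 1])[:-1], axis=1)
            for j, piece in enumerate(pieces):
                dfeats[j] = dfeats[j] + piece
        return dfeats[0]

    def iter_layers(self):
        for comp in self.layers:
            yield from comp


class DenseNet3D:
    """The full network. ``forward`` returns logits per head plus the embedding."""

    def __init__(self, cfg: ModelConfig, input_dims: tuple[int, int, int], seed: int = 0):
        if any(d <= 0 for d in input_dims):
            raise ValueError("input_dims must be positive")
        self.cfg = cfg
        self.input_dims = tuple(input_dims)
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

        self.stem: list[Layer] = [
            Conv3d(1, cfg.init_filters, cfg.init_kernel, rng),
            BatchNorm3d(cfg.init_filters),
            ELU(),
            MaxPool3d(),
        ]
        dims = [max(1, (d + 1) // 2) for d in input_dims]
        ch = cfg.init_filters
        self.blocks: list[_DenseBlock] = []
        self.transitions: list[list[Layer]] = []
        for _ in range(cfg.dense_blocks):
            blk = _DenseBlock(ch, cfg.layers_per_block, cfg.growth_factor, rng)
            self.blocks.append(blk)
            ch = blk.out_ch
            out_ch = max(1, int(ch * cfg.compression))
            self.transitions.append([BatchNorm3d(ch), ELU(), Conv3d(ch, out_ch, 1, rng), AvgPool3d()])
            ch = out_ch
            dims = [max(1, (d + 1) // 2) for d in dims]
            if any(d < 1 for d in dims):
                raise ValueError("input_dims too small for the configured pooling depth")
        flat = ch * int(np.prod(dims))
        self.flatten = Flatten()
        w1, w2, w3 = cfg.fc_widths
        self.fc: list[Layer] = [
            Linear(flat, w1, rng), BatchNorm1d(w1), ELU(), Dropout(cfg.dropout_rate),
            Linear(w1, w2, rng), BatchNorm1d(w2), ELU(), Dropout(cfg.dropout_rate),
            Linear(w2, w3, rng), ELU(), Dropout(cfg.dropout_rate),
        ]
        self.heads: dict[str, Linear] = {}
        for name in CLASSIFICATION_HEADS:
            self.heads[name] = Linear(w3, 2, rng)
        for name in REGRESSION_HEADS:
            self.heads[name] = Linear(w3, 1, rng)
        for layer in self._all_layers():
            if isinstance(layer, Dropout):
                layer.rng = self._dropout_rng

    # ---- structure -------------------------------------------------------
    def _trunk(self):
        yield from self.stem
        for blk, tr in zip(self.blocks, self.transitions):
            yield blk
            yield from tr
        yield self.flatten
        yield from self.fc

    def _all_layers(self):
        for item in self._trunk():
            if isinstance(item, _DenseBlock):
                yield from item.iter_layers()
            else:
                yield item
        yield from self.heads.values()

    def parameters(self) -> list[tuple[Layer, str]]:
        out = []
        for layer in self._all_layers():
            for name in layer.params:
                out.append((layer, name))
        return out

    def n_parameters(self) -> int:
        return int(sum(layer.params[n].size for layer, n in self.parameters()))

    def block_channel_counts(self) -> list[tuple[int, int]]:
        """(channels entering, channels leaving) for each dense block."""
        out = []
        for blk in self.blocks:
            first = blk.layers[0][2]
            out.append((first.in_ch, blk.out_ch))
        return out

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self._all_layers()):
            for name, val in layer.params.items():
                state[f"{i}.{name}"] = val.copy()
            if isinstance(layer, (BatchNorm3d, BatchNorm1d)):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self._all_layers()):
            for name in layer.params:
                layer.params[name] = state[f"{i}.{name}"].copy()
            if isinstance(layer, (BatchNorm3d, BatchNorm1d)):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()

    def snapshot(self) -> dict:
        return copy.deepcopy(self.state_dict())

    # ---- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> dict[str, np.ndarray]:
        """x: (N, D, H, W) or (N, 1, D, H, W). Returns logits + embedding."""
        if x.ndim == 4:
            x = x[:, None]
        h = x.astype(np.float32)
        for item in self._trunk():
            h = item.forward(h, train)
        out = {"embedding": h}
        for name, head in self.heads.items():
            out[name] = head.forward(h, train)
        return out

    def backward(self, dout: dict[str, np.ndarray]) -> np.ndarray:
        """Accumulate head gradients and propagate to the input volume."""
        demb = dout.get("embedding", 0.0)
        for name, head in self.heads.items():
            if name in dout:
                demb = demb + head.backward(dout[name].astype(np.float32))
            else:
                head.grads = {k: np.zeros_like(v) for k, v in head.params.items()}
        g = np.asarray(demb, dtype=np.float32)
        for item in reversed(list(self._trunk())):
            g = item.backward(g)
        return g[:, 0]  # drop the channel axis

    def predict(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Eval-mode predictions: class probabilities, regression values, embedding."""
        out = self.forward(x, train=False)
        res = {"embedding": out["embedding"]}
        for name in CLASSIFICATION_HEADS:
            z = out[name] - out[name].max(axis=1, keepdims=True)
            e = np.exp(z)
            res[name] = e / e.sum(axis=1, keepdims=True)
        for name in REGRESSION_HEADS:
            res[name] = out[name][:, 0]
        return res
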