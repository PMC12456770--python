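"""The parallel temporal network: build, forward/backward, predict, save.

The data flow is::

    input [N, T, C]
      -> batch norm
      -> MST block 1                      -> MST blocks 2..B (pool at output)
           \\-> avg pool (skip) -> 1x1 conv ------------------+
                                                              |
      channel concat(main, skip) -> GAP -> dense -> softmax [N, K]

Within each block, every dilation level runs three LSTC heads of different
kernel sizes in parallel and merges them with a 1x1 residual projection by
element-wise addition.  The model is built deterministically from a
:class:`~lightptnet.specs.NetworkSpec` and a seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .specs import (LSTCHeadSpec, MSTBlockSpec, NetworkSpec, TrainConfig)

__all__ = [
    "LightPTNet",
    "build_network",
    "predict",
    "softmax",
    "receptive_field",
    "conv_chain_receptive_field",
    "save_checkpoint",
    "load_checkpoint",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _LSTCHead:
    """Two units of (conv -> BN -> ReLU -> dropout)."""

    def __init__(self, cin: int, spec: LSTCHeadSpec, rng, dropout_rng):
        def conv(ci):
            if spec.conv_kind == "separable":
                return nn.SeparableConv1d(ci, spec.filters, spec.kernel_size,
                                          spec.dilation, spec.padding, rng)
            return nn.StandardConv1d(ci, spec.filters, spec.kernel_size,
                                     spec.dilation, spec.padding, rng)

        self.layers = []
        for ci in (cin, spec.filters):
            self.layers += [conv(ci),
                            nn.BatchNorm(spec.filters),
                            nn.ReLU(),
                            nn.Dropout(spec.dropout_rate, dropout_rng)]

    def params(self):
        out = []
        for l in self.layers:
            out += l.params()
        return out

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class _DilationLevel:
    """heads summed element-wise with the 1x1 residual projection."""

    def __init__(self, cin: int, head_specs: list[LSTCHeadSpec], rng, dropout_rng):
        self.heads = [_LSTCHead(cin, hs, rng, dropout_rng) for hs in head_specs]
        self.residual = nn.PointwiseConv1d(cin, head_specs[0].filters, rng)

    def params(self):
        out = []
        for h in self.heads:
            out += h.params()
        return out + self.residual.params()

    def forward(self, x, training):
        outs = [h.forward(x, training) for h in self.heads]
        res = self.residual.forward(x, training)
        return sum(outs) + res

    def backward(self, g):
        gx = self.residual.backward(g)
        for h in self.heads:
            gx = gx + h.backward(g)
        return gx


class _MSTBlock:
    def __init__(self, cin: int, spec: MSTBlockSpec, rng, dropout_rng):
        self.levels = []
        ci = cin
        for lv in spec.levels:
            self.levels.append(_DilationLevel(ci, lv.heads, rng, dropout_rng))
            ci = lv.filters
        self.pool = nn.AvgPool1d(2) if spec.pool_after else None

    def params(self):
        out = []
        for lv in self.levels:
            out += lv.params()
        return out

    def forward(self, x, training):
        for lv in self.levels:
            x = lv.forward(x, training)
        if self.pool is not None:
            x = self.pool.forward(x, training)
        return x

    def forward_prepool(self, x, training=False):
        """Block output before the optional pooling (for probing tests)."""
        for lv in self.levels:
            x = lv.forward(x, training)
        return x

    def backward(self, g):
        if self.pool is not None:
            g = self.pool.backward(g)
        for lv in reversed(self.levels):
            g = lv.backward(g)
        return g


class LightPTNet:
    """The model object; construct via :func:`build_network` or directly.

    ``fit`` / ``predict`` / ``evaluate`` make this usable like an estimator:
    ``build_network(spec).fit(train, val, config)`` returns a
    :class:`~lightptnet.training.TrainingResults`.
    """

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        T, C = spec.input_shape
        F = spec.blocks[0].filters

        self.input_bn = nn.BatchNorm(C)
        self.blocks = []
        cin = C
        for b in spec.blocks:
            self.blocks.append(_MSTBlock(cin, b, self.rng, self.rng))
            cin = b.filters
        self.skip_pool = nn.AvgPool1d(spec.skip_pool_size)
        self.skip_conv = nn.PointwiseConv1d(F, F, self.rng)

        main_T, skip_T = self._branch_lengths(T)
        if main_T != skip_T:
            raise ValueError(
                "temporal lengths differ at the concatenation point: "
                f"main branch {main_T}, skip branch {skip_T}")
        concat_channels = spec.blocks[-1].filters + F
        if spec.classifier == "gap_softmax":
            self.gap = nn.GlobalAvgPool()
            self.dense = nn.Dense(concat_channels, spec.n_classes, self.rng)
            self.flatten = None
        else:
            self.gap = None
            self.flatten = nn.Flatten()
            self.dense = nn.Dense(main_T * concat_channels, spec.n_classes,
                                  self.rng)

    # -- structure --------------------------------------------------------
    def _branch_lengths(self, T: int) -> tuple[int, int]:
        main_T = T
        for b, bs in zip(self.blocks, self.spec.blocks):
            if bs.pool_after:
                main_T //= 2
        skip_T = T // self.spec.skip_pool_size
        return main_T, skip_T

    def params(self) -> list[nn.Parameter]:
        out = self.input_bn.params()
        for b in self.blocks:
            out += b.params()
        out += self.skip_conv.params() + self.dense.params()
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward ----------------------------------------------
    def forward(self, x, training: bool = False) -> np.ndarray:
        """Logits for windows ``x`` of shape [N, T, C] (any valid T)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[2] != self.spec.input_shape[1]:
            raise ValueError(
                f"expected input [N, T, {self.spec.input_shape[1]}], "
                f"got {x.shape}")
        h = self.input_bn.forward(x, training)
        h = self.blocks[0].forward(h, training)
        skip = self.skip_pool.forward(h, training)
        skip = self.skip_conv.forward(skip, training)
        main = h
        for b in self.blocks[1:]:
            main = b.forward(main, training)
        if main.shape[1] != skip.shape[1]:
            raise ValueError(
                "temporal lengths differ at the concatenation point: "
                f"main branch {main.shape[1]}, skip branch {skip.shape[1]}")
        self._split = main.shape[2]
        z = np.concatenate([main, skip], axis=2)
        if self.gap is not None:
            z = self.gap.forward(z, training)
        else:
            z = self.flatten.forward(z, training)
        return self.dense.forward(z, training)

    def backward(self, grad_logits) -> None:
        g = self.dense.backward(grad_logits)
        g = (self.gap if self.gap is not None else self.flatten).backward(g)
        gmain, gskip = g[..., : self._split], g[..., self._split:]
        for b in reversed(self.blocks[1:]):
            gmain = b.backward(gmain)
        gskip = self.skip_conv.backward(gskip)
        gskip = self.skip_pool.backward(gskip)
        g1 = gmain + gskip
        g1 = self.blocks[0].backward(g1)
        self.input_bn.backward(g1)

    # -- inference --------------------------------------------------------
    def predict_proba(self, windows, batch_size: int = 256) -> np.ndarray:
        windows = np.asarray(windows, dtype=np.float32)
        out = [softmax(self.forward(windows[i: i + batch_size], training=False))
               for i in range(0, len(windows), batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, windows, batch_size: int = 256):
        """(probabilities [n, K], labels [n]); ties break to the lowest index."""
        p = self.predict_proba(windows, batch_size=batch_size)
        return p, p.argmax(axis=1)

    # -- training / evaluation shortcuts ----------------------------------
    def fit(self, train_set, val_set, config: TrainConfig | None = None,
            verbose: bool = False):
        from .training import train
        return train(self, train_set, val_set, config or TrainConfig(),
                     verbose=verbose)

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"param_{i:04d}"] = p.value
        bns = [self.input_bn]
        for b in self.blocks:
            for lv in b.levels:
                for h in lv.heads:
                    bns += [l for l in h.layers if isinstance(l, nn.BatchNorm)]
        for i, bn in enumerate(bns):
            state[f"bn_{i:04d}_mean"] = bn.running_mean
            state[f"bn_{i:04d}_var"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            val = np.asarray(state[f"param_{i:04d}"])
            if val.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint/spec mismatch at parameter {i}: checkpoint "
                    f"shape {val.shape}, spec expects {p.value.shape}")
            p.value = val.astype(np.float32)
        bns = [self.input_bn]
        for b in self.blocks:
            for lv in b.levels:
                for h in lv.heads:
                    bns += [l for l in h.layers if isinstance(l, nn.BatchNorm)]
        for i, bn in enumerate(bns):
            bn.running_mean = np.asarray(state[f"bn_{i:04d}_mean"], np.float32)
            bn.running_var = np.asarray(state[f"bn_{i:04d}_var"], np.float32)


def build_network(spec: NetworkSpec) -> LightPTNet:
    """Build the model from its declarative spec (seeded, deterministic)."""
    return LightPTNet(spec)


def predict(model: LightPTNet, windows):
    """Functional alias for :meth:`LightPTNet.predict`."""
    return model.predict(windows)


# ---------------------------------------------------------------------------
# Receptive field
# ---------------------------------------------------------------------------

def conv_chain_receptive_field(convs, pools=()) -> int:
    """Receptive field of a chain of dilated convs and pooling stages.

    ``convs``: sequence of ``(kernel, dilation)`` in network order; ``pools``
    is a sequence of ``(position, stride)`` where ``position`` is the number
    of convs applied before the pool.  Each conv contributes
    ``(k - 1) * d`` input samples, scaled by the product of pool strides in
    front of it; each pool contributes ``(stride - 1)`` at its own scale.
    """
    rf = 1
    scale = 1
    pool_iter = sorted(pools)
    pi = 0
    for i, (k, d) in enumerate(convs):
        while pi < len(pool_iter) and pool_iter[pi][0] <= i:
            stride = pool_iter[pi][1]
            rf += (stride - 1) * scale
            scale *= stride
            pi += 1
        rf += (k - 1) * d * scale
    for pos, stride in pool_iter[pi:]:
        rf += (stride - 1) * scale
        scale *= stride
    return rf


def receptive_field(spec: NetworkSpec) -> int:
    """Analytic receptive field of the main branch.

    Heads are parallel, so each dilation level contributes through its
    largest kernel; each head stacks two convolutions.
    """
    convs = []
    pools = []
    n = 0
    for b in spec.blocks:
        for lv in b.levels:
            kmax = max(h.kernel_size for h in lv.heads)
            convs += [(kmax, lv.dilation)] * 2
            n += 2
        if b.pool_after:
            pools.append((n, 2))
    return conv_chain_receptive_field(convs, pools)


# ---------------------------------------------------------------------------
# Checkpoints (npz weights + JSON spec sidecar)
# ---------------------------------------------------------------------------

def save_checkpoint(model: LightPTNet, path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_arrays())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"network_spec": model.spec.to_dict()},
                                  indent=2))


def load_checkpoint(path) -> LightPTNet:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing checkpoint sidecar {sidecar}")
    spec = NetworkSpec.from_dict(
        json.loads(sidecar.read_text())["network_spec"])
    model = LightPTNet(spec)
    with np.load(path.with_suffix(".npz")) as state:
        model.load_state_arrays(dict(state))
    return model
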