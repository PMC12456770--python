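"""Declarative architecture and training configuration.

A network is described entirely by nested dataclasses:

* :class:`LSTCHeadSpec` — one Light Spatial-Temporal Convolutional head
  (two units of separable dilated conv -> batch norm -> ReLU -> dropout,
  all with one kernel size).
* :class:`DilationLevelSpec` — three parallel heads of increasing kernel
  size sharing a dilation rate, merged by element-wise sum with a 1x1
  residual projection.
* :class:`MSTBlockSpec` — sequential dilation levels with doubling rates
  (1, 2, 4, ...), optionally followed by average pooling.
* :class:`NetworkSpec` — input batch norm, the block stack, the parallel
  average-pool + 1x1 skip branch taken from the first block's output, the
  channel concatenation of both branches, and the classifier head.

Specs serialise to/from plain dictionaries and YAML, and the shipped
presets (``ucihar``, ``wisdm``, ``unimib``) carry the hyperparameters the
reference experiments used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = [
    "LSTCHeadSpec",
    "DilationLevelSpec",
    "MSTBlockSpec",
    "NetworkSpec",
    "TrainConfig",
    "load_preset",
    "preset_names",
    "network_spec_from_hyperparameters",
]


@dataclass
class LSTCHeadSpec:
    """One multiscale head: two (conv -> BN -> ReLU -> dropout) units."""

    kernel_size: int
    dilation: int
    filters: int
    dropout_rate: float = 0.05
    padding: str = "same"          # "same" | "causal"
    conv_kind: str = "separable"   # "separable" | "standard"

    def __post_init__(self):
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.filters < 1:
            raise ValueError("filters must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.padding not in ("same", "causal"):
            raise ValueError(f"unknown padding {self.padding!r}")
        if self.conv_kind not in ("separable", "standard"):
            raise ValueError(f"unknown conv_kind {self.conv_kind!r}")


@dataclass
class DilationLevelSpec:
    """Three parallel heads plus a 1x1 residual, merged element-wise."""

    heads: list[LSTCHeadSpec]

    def __post_init__(self):
        if len(self.heads) != 3:
            raise ValueError("a dilation level holds exactly 3 LSTC heads")
        dil = {h.dilation for h in self.heads}
        filt = {h.filters for h in self.heads}
        if len(dil) != 1 or len(filt) != 1:
            raise ValueError("heads of one level must share dilation and filters")
        ks = [h.kernel_size for h in self.heads]
        if sorted(ks) != ks or len(set(ks)) != 3:
            raise ValueError("kernel sizes must be strictly increasing")

    @property
    def dilation(self) -> int:
        return self.heads[0].dilation

    @property
    def filters(self) -> int:
        return self.heads[0].filters


@dataclass
class MSTBlockSpec:
    """Sequential dilation levels with doubling rates; optional avg pool."""

    levels: list[DilationLevelSpec]
    pool_after: bool = False

    def __post_init__(self):
        rates = [lv.dilation for lv in self.levels]
        if rates != [2 ** i for i in range(len(rates))]:
            raise ValueError(
                f"dilation rates must double from 1 (1, 2, 4, ...), got {rates}")

    @property
    def filters(self) -> int:
        return self.levels[0].filters


@dataclass
class NetworkSpec:
    """Complete architecture description; see module docstring."""

    input_shape: tuple[int, int]   # (T, C)
    blocks: list[MSTBlockSpec]
    skip_pool_size: int
    n_classes: int
    classifier: str = "gap_softmax"   # "gap_softmax" | "flatten_dense"
    seed: int = 0

    def __post_init__(self):
        self.input_shape = tuple(self.input_shape)
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not self.blocks:
            raise ValueError("at least one MST block is required")
        if self.classifier not in ("gap_softmax", "flatten_dense"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.skip_pool_size < 1:
            raise ValueError("skip_pool_size must be >= 1")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_shape"] = list(self.input_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        blocks = [
            MSTBlockSpec(
                levels=[DilationLevelSpec(heads=[LSTCHeadSpec(**h)
                                                 for h in lv["heads"]])
                        for lv in b["levels"]],
                pool_after=b["pool_after"],
            )
            for b in d["blocks"]
        ]
        return cls(input_shape=tuple(d["input_shape"]), blocks=blocks,
                   skip_pool_size=d["skip_pool_size"],
                   n_classes=d["n_classes"],
                   classifier=d.get("classifier", "gap_softmax"),
                   seed=d.get("seed", 0))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def network_spec_from_hyperparameters(
    input_shape: tuple[int, int],
    n_blocks: int,
    filters: int,
    kernel_sizes: list[int],
    dilations: list[int],
    dropout: float,
    n_classes: int,
    padding: str = "same",
    conv_kind: str = "separable",
    classifier: str = "gap_softmax",
    pooling: str = "all_but_first",   # "none" | "all" | "all_but_first"
    seed: int = 0,
) -> NetworkSpec:
    """Expand a flat hyperparameter table into a full :class:`NetworkSpec`.

    Average pooling follows ``pooling``: by default every block except the
    first pools its output (size 2, stride 2).  The skip branch pools the
    first block's output by ``prod of main-branch pool strides`` so the two
    branches have equal temporal length at the concatenation point.
    """
    if len(kernel_sizes) != 3:
        raise ValueError("exactly 3 kernel sizes are required (3 heads/level)")

    def block(pool_after: bool) -> MSTBlockSpec:
        levels = [
            DilationLevelSpec(heads=[
                LSTCHeadSpec(kernel_size=k, dilation=d, filters=filters,
                             dropout_rate=dropout, padding=padding,
                             conv_kind=conv_kind)
                for k in kernel_sizes
            ])
            for d in dilations
        ]
        return MSTBlockSpec(levels=levels, pool_after=pool_after)

    def pools(i: int) -> bool:
        if pooling == "none":
            return False
        if pooling == "all":
            return True
        if pooling == "all_but_first":
            return i > 0
        raise ValueError(f"unknown pooling mode {pooling!r}")

    blocks = [block(pools(i)) for i in range(n_blocks)]
    skip_pool = 1
    for b in blocks:
        if b.pool_after:
            skip_pool *= 2
    return NetworkSpec(input_shape=tuple(input_shape), blocks=blocks,
                       skip_pool_size=max(skip_pool, 1), n_classes=n_classes,
                       classifier=classifier, seed=seed)


@dataclass
class TrainConfig:
    """Optimiser / schedule settings (Adam + plateau learning-rate decay)."""

    batch_size: int = 32
    epochs: int = 100
    initial_lr: float = 1e-3
    min_lr: float = 1e-4
    plateau_patience: int = 3
    plateau_factor: float = 0.1
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.min_lr <= self.initial_lr:
            raise ValueError("require 0 < min_lr <= initial_lr")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# Shipped presets
# ---------------------------------------------------------------------------

def preset_names() -> list[str]:
    return ["ucihar", "wisdm", "unimib"]


def load_preset(name: str, seed: int = 0) -> dict:
    """Load a shipped preset.

    Returns ``{"name", "network": NetworkSpec, "training": TrainConfig,
    "data": dict}`` where ``data`` carries the dataset-protocol constants
    (window length, channel count, class count, subject split sizes).
    """
    if name not in preset_names():
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}")
    ref = resources.files("lightptnet.presets") / f"{name}.yaml"
    raw = yaml.safe_load(ref.read_text())
    net = raw["network"]
    spec = network_spec_from_hyperparameters(
        input_shape=tuple(net["input_shape"]),
        n_blocks=net["n_blocks"],
        filters=net["filters"],
        kernel_sizes=net["kernel_sizes"],
        dilations=net["dilations"],
        dropout=net["dropout"],
        n_classes=net["n_classes"],
        padding=net.get("padding", "same"),
        conv_kind=net.get("conv_kind", "separable"),
        classifier=net.get("classifier", "gap_softmax"),
        seed=seed,
    )
    cfg = TrainConfig(seed=seed, **raw["training"])
    return {"name": name, "network": spec, "training": cfg,
            "data": raw.get("data", {})}
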