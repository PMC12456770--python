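"""Analytic cost model and exact trainable-parameter accounting.

The cost model counts multiply-accumulate operations of a convolution from
its shape alone:

* standard convolution:  ``Hk * Wk * In * Out * Ho * Wo``
* separable convolution: ``Hk * Wk * In * Ho * Wo  +  In * Out * Ho * Wo``
  (depthwise term plus pointwise term)

Their ratio collapses to the exact rational identity
``1/Out + 1/(Hk * Wk)``, which is what makes separable convolutions cheap
whenever the output-channel count and the kernel extent are both large.

``count_parameters`` enumerates the trainable weights of a
:class:`~lightptnet.specs.NetworkSpec` layer by layer, using the same
conventions as the built network: convolutions carry no bias (batch
normalisation's shift subsumes it, and the 1x1 projections are merged into
residual sums), batch normalisation contributes 2 trainable parameters per
channel, and only the final dense layer has a bias.  The total is asserted
elsewhere to equal the built model's parameter count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .specs import NetworkSpec

__all__ = [
    "ConvShape",
    "CostReport",
    "conv_cost",
    "sepconv_cost",
    "cost_reduction",
    "layer_cost_report",
    "count_parameters",
    "millions",
]


@dataclass(frozen=True)
class ConvShape:
    """Shape of one convolution: kernel HkxWk, In->Out channels, output HoxWo."""

    Hk: int
    Wk: int
    In: int
    Out: int
    Ho: int
    Wo: int

    def __post_init__(self):
        for name in ("Hk", "Wk", "In", "Out", "Ho", "Wo"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


@dataclass(frozen=True)
class CostReport:
    standard_cost: int
    separable_cost: int
    reduction: Fraction


def conv_cost(s: ConvShape) -> int:
    """Multiply-accumulate count of a standard convolution."""
    return s.Hk * s.Wk * s.In * s.Out * s.Ho * s.Wo


def sepconv_cost(s: ConvShape) -> int:
    """Multiply-accumulate count of a separable convolution
    (depthwise term + pointwise term)."""
    return s.Hk * s.Wk * s.In * s.Ho * s.Wo + s.In * s.Out * s.Ho * s.Wo


def cost_reduction(s: ConvShape) -> Fraction:
    """Exact cost ratio separable/standard, ``1/Out + 1/(Hk*Wk)``."""
    return Fraction(1, s.Out) + Fraction(1, s.Hk * s.Wk)


def layer_cost_report(s: ConvShape) -> CostReport:
    return CostReport(standard_cost=conv_cost(s),
                      separable_cost=sepconv_cost(s),
                      reduction=cost_reduction(s))


# ---------------------------------------------------------------------------
# Parameter accounting
# ---------------------------------------------------------------------------

def _head_rows(cin: int, head, prefix: str) -> list[dict]:
    rows = []
    F = head.filters
    k = head.kernel_size
    for unit, ci in (("1", cin), ("2", F)):
        if head.conv_kind == "separable":
            rows.append({"layer": f"{prefix}/conv{unit}/depthwise",
                         "params": k * ci})
            rows.append({"layer": f"{prefix}/conv{unit}/pointwise",
                         "params": ci * F})
        else:
            rows.append({"layer": f"{prefix}/conv{unit}", "params": k * ci * F})
        rows.append({"layer": f"{prefix}/bn{unit}", "params": 2 * F})
    return rows


def count_parameters(spec: NetworkSpec) -> tuple[int, pd.DataFrame]:
    """Exact trainable-parameter enumeration of a network spec.

    Returns ``(total, per_layer_table)`` where the table has one row per
    weight-bearing layer with columns ``layer`` and ``params``.
    """
    T, C = spec.input_shape
    rows = [{"layer": "input_bn", "params": 2 * C}]
    cin = C
    for bi, block in enumerate(spec.blocks, start=1):
        for li, level in enumerate(block.levels, start=1):
            F = level.filters
            for hi, head in enumerate(level.heads, start=1):
                rows += _head_rows(cin, head,
                                   f"block{bi}/level{li}/head{hi}")
            rows.append({"layer": f"block{bi}/level{li}/residual_1x1",
                         "params": cin * F})
            cin = F
    F1 = spec.blocks[0].filters
    rows.append({"layer": "skip_1x1", "params": F1 * F1})
    concat = spec.blocks[-1].filters + F1
    if spec.classifier == "gap_softmax":
        rows.append({"layer": "dense",
                     "params": concat * spec.n_classes + spec.n_classes})
    else:
        main_T = T
        for b in spec.blocks:
            if b.pool_after:
                main_T //= 2
        rows.append({"layer": "dense",
                     "params": main_T * concat * spec.n_classes
                     + spec.n_classes})
    table = pd.DataFrame(rows)
    return int(table["params"].sum()), table


def millions(total: int, decimals: int = 3) -> float:
    """Parameter total in millions, rounded the way results tables print it."""
    return round(total / 1e6, decimals)
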