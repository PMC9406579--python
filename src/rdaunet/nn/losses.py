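"""Segmentation losses on probability maps.

The training objective is not pinned down by the published protocol, so
three standard choices ship: pixelwise binary cross-entropy (default), soft
Dice, and their sum.  All take probabilities in (0,1) (the network head is a
sigmoid) and a hard {0,1} target, and return a scalar tensor.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["bce_loss", "dice_loss", "bce_dice_loss", "get_loss"]

_EPS = 1e-7


def bce_loss(prob: Tensor, target: np.ndarray | Tensor) -> Tensor:
    y = target.data if isinstance(target, Tensor) else np.asarray(target, dtype=np.float64)
    p = prob.clip(_EPS, 1.0 - _EPS)
    ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -ll.mean()

def dice_loss(prob: Tensor, target: np.ndarray | Tensor, smooth: float = 1.0) -> Tensor:
    """1 - soft Dice; ``smooth`` keeps the ratio defined on empty masks."""
    y = target.data if isinstance(target, Tensor) else np.asarray(target, dtype=np.float64)
    inter = (prob * Tensor(y)).sum()
    denom = prob.sum() + Tensor(y).sum()
    return 1.0 - (inter * 2.0 + smooth) / (denom + smooth)


def bce_dice_loss(prob: Tensor, target: np.ndarray | Tensor) -> Tensor:
    return bce_loss(prob, target) + dice_loss(prob, target)


_LOSSES = {"bce": bce_loss, "dice": dice_loss, "bce_dice": bce_dice_loss}


def get_loss(name: str):
    try:
        return _LOSSES[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; choose from {sorted(_LOSSES)}") from None
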