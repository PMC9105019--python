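"""The full loss system of the translation model.

Least-squares adversarial terms with two-channel, mask-supervised targets:
for each pyramid level l the critic output is penalized by the squared
error against the target map m_i^l = [i * ones, downsampled breast mask],
with i = 1 for real patches and i = 0 for synthesized ones.  Per level the
squared error is averaged over pixels and both channels, then the three
levels are summed (the mean-then-sum reduction keeps the cycle weight
comparable across patch sizes).

Discriminator loss (one kernel serves both critics):

    L(D) = sum_l [ mse(D^l(real^l), m_1^l) + mse(D^l(fake^l), m_0^l) ]

Generator adversarial term (the generator tries to make the critic emit
the *real* target on its fakes):

    L_adv(G) = sum_l mse(D^l(fake^l), m_1^l)

Cycle consistency is the mean absolute error between a patch and its
round-trip reconstruction, and the generator total is
L_adv + lambda * L_cyc with lambda = 10 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .patching import make_target_map

ArrayOrTensor = Union[np.ndarray, Tensor]


@dataclass(frozen=True)
class LossBreakdown:
    l_gan: float
    l_cyc: float
    total: float
    lambda_weight: float

    def __post_init__(self):
        if self.l_gan < 0 or self.l_cyc < 0:
            raise ValueError("loss components must be nonnegative")
        if not (self.lambda_weight > 0):
            raise ValueError("lambda_weight must be positive")
        if abs(self.total - (self.l_gan + self.lambda_weight * self.l_cyc)) > 1e-9:
            raise ValueError("total inconsistent with components")


# ---------------------------------------------------------------------------
# kernels on Tensors (shared by the training loop)

def _as_batched_tensor(m: ArrayOrTensor) -> Tensor:
    t = m if isinstance(m, Tensor) else Tensor(np.asarray(m, dtype=np.float64))
    if t.data.ndim == 3:                       # (2,h,w) -> (1,2,h,w)
        t = Tensor(t.data[None], t.requires_grad, (t,),
                   (lambda g, _t=t: _t._accum(g[0])) if t.requires_grad else None)
    if t.data.ndim != 4 or t.data.shape[1] != 2:
        raise ValueError("critic maps must be (2,h,w) or (N,2,h,w)")
    return t


def _batched_masks(mask: np.ndarray, n: int) -> np.ndarray:
    m = np.asarray(mask, dtype=np.float64)
    if m.ndim == 2:
        m = np.broadcast_to(m, (n,) + m.shape)
    if m.shape[0] != n:
        raise ValueError("mask batch size mismatch")
    return m


def target_stack(i: int, masks: np.ndarray, level: int, out_shape) -> np.ndarray:
    """Batched two-channel targets m_i^l, shape (N, 2, h, w)."""
    return np.stack([make_target_map(i, m, level, out_shape).stacked()
                     for m in masks])


def scale_mse_vs_target(outs: Sequence[Tensor], i: int, mask: np.ndarray
                        ) -> Tensor:
    """sum_l mse(out_l, m_i^l): mean per level over pixels+channels."""
    if len(outs) != 3:
        raise ValueError("expected 3 per-scale critic maps")
    total = None
    for level, out in enumerate(outs, start=1):
        out = _as_batched_tensor(out)
        n, _, h, w = out.data.shape
        tgt = target_stack(i, _batched_masks(mask, n), level, (h, w))
        term = ad.mse(out, tgt.astype(out.data.dtype, copy=False))
        total = term if total is None else ad.add(total, term)
    return total


# ---------------------------------------------------------------------------
# public value-level API

def loss_discriminator(disc_out_real, disc_out_fake, mask_real, mask_fake
                       ) -> float:
    """Two-channel least-squares critic loss, summed over the 3 scales.

    ``mask_fake`` is the breast mask of the patch that generated the fake.
    """
    real = [_as_batched_tensor(m) for m in disc_out_real]
    fake = [_as_batched_tensor(m) for m in disc_out_fake]
    val = (scale_mse_vs_target(real, 1, mask_real).data
           + scale_mse_vs_target(fake, 0, mask_fake).data)
    return float(val)


def loss_gan_generator(disc_out_fake, mask_fake) -> float:
    """Adversarial generator term: critic-on-fake vs the REAL target m_1."""
    fake = [_as_batched_tensor(m) for m in disc_out_fake]
    return float(scale_mse_vs_target(fake, 1, mask_fake).data)


def loss_cycle(reconstructed: np.ndarray, original: np.ndarray) -> float:
    """Mean absolute difference between a patch and its reconstruction."""
    a = np.asarray(reconstructed, dtype=np.float64)
    b = np.asarray(original, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def loss_generator_total(l_gan: float, l_cyc: float,
                         lambda_weight: float = 10.0) -> LossBreakdown:
    """L = L_adv + lambda * L_cyc with lambda = 10 by default."""
    if l_gan < 0 or l_cyc < 0:
        raise ValueError("loss components must be nonnegative")
    if not (lambda_weight > 0):
        raise ValueError("lambda_weight must be positive")
    return LossBreakdown(float(l_gan), float(l_cyc),
                         float(l_gan + lambda_weight * l_cyc),
                         float(lambda_weight))
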