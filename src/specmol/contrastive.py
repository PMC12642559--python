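"""Multiview contrastive objective (InfoNCE over all view pairs).

The discriminator is h(vp, vq) = exp(cos(vp, vq) / tau). For a batch of B
aligned items, the directed loss from view p to view q is the mean over
anchors i of -log[ h(vp_i, vq_i) / sum_j h(vp_i, vq_j) ], with the other
B - 1 in-batch items of view q acting as negatives. A view pair contributes
the sum of both directions, and the total loss sums over all unordered
pairs of active views (six pairs, twelve directed terms, when all four
views are active).

Because h depends only on cosine similarity, the loss is invariant to
positive rescaling of any embedding, and permuting the batch identically in
all views leaves it unchanged.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .config import LossConfig
from .nn.autodiff import Tensor, logsumexp_last


def discriminator_h(vp: np.ndarray, vq: np.ndarray, tau: float) -> float:
    """exp(cosine(vp, vq) / tau); errors on zero-norm inputs."""
    vp = np.asarray(vp, dtype=np.float64)
    vq = np.asarray(vq, dtype=np.float64)
    np_, nq = np.linalg.norm(vp), np.linalg.norm(vq)
    if np_ == 0 or nq == 0:
        raise ValueError("discriminator_h requires nonzero-norm vectors")
    return float(np.exp(vp @ vq / (np_ * nq) / tau))


def _normalize_rows(Z: Tensor) -> Tensor:
    return Z * ((Z * Z).sum(axis=1, keepdims=True) ** -0.5)


def directed_pair_loss_tensor(Zp: Tensor, Zq: Tensor, tau: float) -> Tensor:
    """Differentiable directed InfoNCE term (anchors from view p)."""
    B = Zp.shape[0]
    if B < 2:
        raise ValueError("directed_pair_loss requires batch size >= 2 (no negatives)")
    if Zq.shape[0] != B:
        raise ValueError("anchor and contrast batches must be aligned")
    if np.any(np.linalg.norm(Zp.data, axis=1) == 0) or np.any(
        np.linalg.norm(Zq.data, axis=1) == 0
    ):
        raise ValueError("zero-norm embedding in batch")
    S = (_normalize_rows(Zp) @ _normalize_rows(Zq).swapaxes(0, 1)) * (1.0 / tau)
    return (logsumexp_last(S) - S.diag()).mean()


def directed_pair_loss(anchors: np.ndarray, contrasts: np.ndarray, tau: float) -> float:
    return float(directed_pair_loss_tensor(Tensor(anchors), Tensor(contrasts), tau).data)


def pair_loss_tensor(Zp: Tensor, Zq: Tensor, tau: float) -> Tensor:
    """Symmetric pair loss: both directed terms."""
    return directed_pair_loss_tensor(Zp, Zq, tau) + directed_pair_loss_tensor(Zq, Zp, tau)


def pair_loss(Vp: np.ndarray, Vq: np.ndarray, tau: float) -> float:
    return float(pair_loss_tensor(Tensor(Vp), Tensor(Vq), tau).data)


def total_loss_tensor(embeddings: dict[str, Tensor], config: LossConfig) -> Tensor:
    """Sum of symmetric pair losses over all unordered active-view pairs."""
    missing = [v for v in config.active_views if v not in embeddings]
    if missing:
        raise ValueError(f"missing embeddings for active views {missing}")
    total: Tensor | None = None
    for vp, vq in combinations(config.active_views, 2):
        term = pair_loss_tensor(embeddings[vp], embeddings[vq], config.temperature)
        total = term if total is None else total + term
    return total


def total_loss(
    Zmol: np.ndarray | None = None,
    Zfp: np.ndarray | None = None,
    Zs: np.ndarray | None = None,
    Zcs: np.ndarray | None = None,
    config: LossConfig | None = None,
) -> float:
    """Total multiview contrastive loss on numpy embedding batches."""
    config = config or LossConfig()
    arrays = {"mol": Zmol, "fp": Zfp, "s": Zs, "cs": Zcs}
    tensors = {
        v: Tensor(arrays[v]) for v in config.active_views if arrays[v] is not None
    }
    return float(total_loss_tensor(tensors, config).data)
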