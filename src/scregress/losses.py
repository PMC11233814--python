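"""Supervised contrastive loss over L2-normalized embeddings.

With R the combined batch (originals and corrupted copies), P(r) the
positives of anchor r and A(r) = R \\ {r}, the loss is

    L = sum_r L_r,
    L_r = -(1/|P(r)|) sum_{p in P(r)} log[ exp(z_r.z_p / tau)
                                           / sum_{a in A(r)} exp(z_r.z_a / tau) ].

Anchors with an empty positives set contribute 0 (that can only happen when
augmentation is disabled, since a corrupted twin shares its anchor's label).
Each summand is -log of a ratio <= 1, so L >= 0. The loss is summed over
anchors, following the printed formulation; pass ``reduction="mean"`` for a
batch-size-independent value when logging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pairing import PairMask


@dataclass
class LossConfig:
    """Temperature tau > 0 dividing the embedding dot products."""

    temperature: float = 1.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")


def l2_normalize(vectors: np.ndarray) -> np.ndarray:
    """Row-normalize to unit Euclidean norm."""
    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot normalize a zero embedding vector")
    return vectors / norms


def supcon_loss(
    embeddings: np.ndarray,
    mask: PairMask,
    config: LossConfig | None = None,
    reduction: str = "sum",
) -> float:
    """Supervised contrastive loss for a batch of unit-norm embeddings.

    ``embeddings`` is M x e with unit rows (checked to 1e-6); ``mask`` holds
    the M x M positive-pair structure. Stabilized by subtracting the
    per-anchor maximum logit, which leaves the value unchanged analytically.
    """
    if config is None:
        config = LossConfig()
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2:
        raise ValueError("embeddings must be 2-D")
    norms = np.linalg.norm(embeddings, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("embeddings must be L2-normalized (unit rows within 1e-6)")
    if mask.positives.shape[0] != embeddings.shape[0]:
        raise ValueError(
            f"mask dimension {mask.positives.shape[0]} != batch size {embeddings.shape[0]}"
        )
    loss, _ = _supcon_value_and_grad(
        embeddings, mask.positives, config.temperature, want_grad=False
    )
    if reduction == "mean":
        return loss / embeddings.shape[0]
    if reduction != "sum":
        raise ValueError("reduction must be 'sum' or 'mean'")
    return loss


def _supcon_value_and_grad(
    z: np.ndarray,
    positives: np.ndarray,
    temperature: float,
    want_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Loss value and gradient w.r.t. the normalized embeddings ``z``.

    dL/dS has entries softmax_a(s_r.) - P[r,a]/|P(r)| for anchors with
    positives (zero rows otherwise, zero diagonal); since s_ra = z_r.z_a/tau
    is symmetric in its arguments, dL/dZ = (G + G^T) Z / tau.
    """
    m = z.shape[0]
    s = (z @ z.T) / temperature
    # logits over A(r) = everything but the anchor itself
    np.fill_diagonal(s, -np.inf)
    row_max = s.max(axis=1, keepdims=True)
    exp_s = np.exp(s - row_max)
    denom = exp_s.sum(axis=1, keepdims=True)
    log_prob = (s - row_max) - np.log(denom)

    pos = positives.astype(float)
    n_pos = pos.sum(axis=1)
    has_pos = n_pos > 0
    safe_n = np.where(has_pos, n_pos, 1.0)
    per_anchor = -(pos * np.where(np.isfinite(log_prob), log_prob, 0.0)).sum(axis=1) / safe_n
    per_anchor = np.where(has_pos, per_anchor, 0.0)
    loss = float(per_anchor.sum())

    if not want_grad:
        return loss, None
    softmax = exp_s / denom
    g = (softmax - pos / safe_n[:, None]) * has_pos[:, None]
    np.fill_diagonal(g, 0.0)
    grad = ((g + g.T) @ z) / temperature
    return loss, grad
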