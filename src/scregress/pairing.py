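"""Positive/negative pair determination from continuous labels.

Two samples form a positive pair when the absolute difference of their
regression labels is strictly below the threshold theta; otherwise they are
a negative pair. The threshold is the key hyperparameter that adapts
supervised contrastive learning to regression: with labels spanning roughly
[-3, 3] the default is theta = 0.35, and results are robust over roughly
0.1-0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_THETA = 0.35


@dataclass
class PairMask:
    """Boolean positive-pair structure over a combined batch of M samples.

    ``positives[i, j]`` is True iff ``|labels[i] - labels[j]| < theta`` and
    ``i != j``. Symmetric with a False diagonal: a sample is not its own pair.
    """

    positives: np.ndarray
    labels: np.ndarray
    theta: float

    @property
    def n(self) -> int:
        return self.positives.shape[0]


def build_pair_mask(labels: np.ndarray, theta: float = DEFAULT_THETA) -> PairMask:
    """Build the pair mask for a batch of labels (originals + corrupted copies).

    Strict inequality at the threshold: ``|dy| == theta`` is a negative pair.
    An original and its corrupted copy share a label (|dy| = 0) and are
    therefore always positive.
    """
    labels = np.asarray(labels, dtype=float).ravel()
    if len(labels) < 2:
        raise ValueError("need at least 2 samples to form pairs")
    if not theta > 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if not np.all(np.isfinite(labels)):
        raise ValueError("non-finite label")
    diff = np.abs(labels[:, None] - labels[None, :])
    positives = diff < theta
    np.fill_diagonal(positives, False)
    return PairMask(positives=positives, labels=labels, theta=float(theta))
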