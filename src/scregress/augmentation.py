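"""Random feature corruption: the augmentation used during contrastive pretraining.

For each sample in a mini-batch, a fixed-size random subset of feature
positions is overwritten with the value another (random) sample in the same
batch holds at that position. The corrupted copy keeps the original sample's
regression label, so an original and its corrupted twin are always a
positive pair downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CorruptionConfig:
    """Corruption rate ``c`` in [0, 1] and the seed of the draw."""

    rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"corruption rate must be in [0, 1], got {self.rate}")


def corrupt_batch(
    batch: np.ndarray,
    config: CorruptionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Return a corrupted copy of ``batch`` (m x d).

    Each row independently has ``round(c * d)`` positions selected uniformly
    without replacement; each selected position j is replaced by the value at
    column j of a uniformly random *other* row. Unselected positions are
    unchanged. A replacement may coincidentally equal the original value; no
    resampling forces a change.

    Pass either ``config`` (seeded draw) or an existing ``rng`` (streaming use
    inside a training loop).
    """
    batch = np.asarray(batch)
    if batch.ndim != 2:
        raise ValueError("batch must be 2-D")
    if config is None:
        config = CorruptionConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m, d = batch.shape
    n_corrupt = int(round(config.rate * d))
    if n_corrupt == 0:
        return batch.copy()
    if m < 2:
        raise ValueError("need at least 2 samples to draw replacement values from")

    out = batch.copy()
    # per-row subset of positions, independent across rows
    order = np.argsort(rng.random((m, d)), axis=1)
    cols = order[:, :n_corrupt]
    # donor row per corrupted cell, uniform among rows != self
    donors = rng.integers(0, m - 1, size=(m, n_corrupt))
    rows = np.arange(m)[:, None]
    donors = donors + (donors >= rows)
    out[rows, cols] = batch[donors, cols]
    return out
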