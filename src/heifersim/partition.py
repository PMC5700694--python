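"""Stratified train/test splitting and bootstrap resampling.

The split samples, within each outcome class, exactly
``ceil(proportion * n_class)`` records into the training set so that the
training conception rate matches the full-data rate to the resolution
forced by rounding.  With the study's 1,549 positive / 444 negative
services at 70% this yields the 1,396 / 597 partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import StratificationError


@dataclass(frozen=True)
class SplitResult:
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    proportion: float


def stratified_split(outcomes, proportion: float, seed: int) -> SplitResult:
    """Outcome-stratified random partition into train and test indices."""
    y = np.asarray(outcomes).astype(int)
    if not 0.0 < proportion < 1.0:
        raise ValueError(f"proportion must lie in (0, 1), got {proportion}")
    rng = np.random.default_rng(seed)
    train: list[np.ndarray] = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size == 0:
            raise StratificationError(f"outcome class {cls} has no records")
        n_train = math.ceil(proportion * idx.size)
        train.append(rng.choice(idx, size=n_train, replace=False))
    train_idx = np.sort(np.concatenate(train))
    mask = np.ones(y.size, dtype=bool)
    mask[train_idx] = False
    return SplitResult(
        train_indices=train_idx,
        test_indices=np.flatnonzero(mask),
        seed=seed,
        proportion=proportion,
    )


def bootstrap_indices(n: int, n_resamples: int = 2000, seed: int = 0) -> np.ndarray:
    """``n_resamples`` draws of ``n`` indices with replacement from 0..n-1."""
    if n < 1 or n_resamples < 1:
        raise ValueError("n and n_resamples must be positive")
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(n_resamples, n))
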