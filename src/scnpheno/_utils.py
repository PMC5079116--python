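"""Small shared helpers: seeding, partition agreement, warnings."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import comb


def rng_from_seed(seed) -> np.random.Generator:
    """Return a Generator from an int seed or pass an existing Generator through."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    Computed from the contingency table of the two labelings; 1.0 means the
    partitions are identical up to label permutation, 0.0 is the expectation
    for independent labelings.
    """
    a = pd.Categorical(np.asarray(labels_a)).codes
    b = pd.Categorical(np.asarray(labels_b)).codes
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty label vectors")
    table = pd.crosstab(a, b).to_numpy()
    sum_comb = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} labels: {dupes}")
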