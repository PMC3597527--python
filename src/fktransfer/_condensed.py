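"""Condensed (upper-triangle) indexing for unordered gene pairs.

All large pairwise structures store one value per unordered pair {i, j},
i < j, in the scipy ``squareform`` ordering: index(i, j) =
i*(2n-i-1)/2 + (j-i-1) for an n-gene universe.
"""
from __future__ import annotations

import numpy as np


def n_pairs(n: int) -> int:
    return n * (n - 1) // 2


def pair_index(i, j, n: int):
    """Condensed index of pair {i, j} in an n-gene universe (vectorized)."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    if np.any(lo == hi):
        raise ValueError("self-pairs have no condensed index")
    return lo * (2 * n - lo - 1) // 2 + (hi - lo - 1)


def pairs_within(members, n: int):
    """Condensed indices of all pairs among ``members`` (integer gene indices)."""
    m = np.asarray(members, dtype=np.int64)
    if len(m) < 2:
        return np.empty(0, dtype=np.int64)
    ii, jj = np.triu_indices(len(m), k=1)
    return pair_index(m[ii], m[jj], n)


def pair_arrays(n: int):
    """Row/column integer indices (i, j), i<j, aligned with condensed order."""
    return np.triu_indices(n, k=1)
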